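"""Tab-separated interchange formats.

The canonical dialect is TSV (header row, UTF-8, '.' decimal, floats at
10 significant digits).  Cohorts are written as a dosage table
(individual_id, family_id, role, one column per SNP) plus FAM-style
pedigree (family, individual, father, mother, sex, phenotype) and
BIM-style SNP (snp_id, effect_allele, other_allele, maf) text tables.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .data import FamilyCohort, SNPPanel, SummaryStats, WeightSet

FLOAT_FMT = "%.10g"


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_cohort(cohort: FamilyCohort, panel: SNPPanel | None, prefix: str | Path) -> None:
    """Write <prefix>.dosage.tsv, <prefix>.fam.tsv and (with a panel)
    <prefix>.bim.tsv."""
    prefix = Path(prefix)
    write_tsv(cohort.to_frame(), prefix.with_suffix(".dosage.tsv"))

    fam = pd.DataFrame(
        {
            "family_id": cohort.family_id,
            "individual_id": cohort.individual_id,
            "father_id": "0",
            "mother_id": "0",
            "sex": 0,
            "phenotype": -9,
        }
    )
    # link children to in-cohort parents where present
    ids = pd.DataFrame(
        {"family_id": cohort.family_id, "individual_id": cohort.individual_id,
         "role": cohort.role}
    )
    fa = ids[ids["role"] == "father"].set_index("family_id")["individual_id"]
    mo = ids[ids["role"] == "mother"].set_index("family_id")["individual_id"]
    child = np.isin(cohort.role, ("proband", "sibling"))
    fam.loc[child, "father_id"] = (
        pd.Series(cohort.family_id[child]).map(fa).fillna("0").to_numpy()
    )
    fam.loc[child, "mother_id"] = (
        pd.Series(cohort.family_id[child]).map(mo).fillna("0").to_numpy()
    )
    fam.loc[cohort.role == "father", "sex"] = 1
    fam.loc[cohort.role == "mother", "sex"] = 2
    write_tsv(fam, prefix.with_suffix(".fam.tsv"))

    if panel is not None:
        bim = pd.DataFrame(
            {
                "snp_id": panel.snp_id,
                "effect_allele": panel.effect_allele,
                "other_allele": panel.other_allele,
                "maf": panel.maf,
            }
        )
        write_tsv(bim, prefix.with_suffix(".bim.tsv"))


def read_cohort(prefix: str | Path) -> FamilyCohort:
    prefix = Path(prefix)
    df = read_tsv(prefix.with_suffix(".dosage.tsv"))
    meta = ["individual_id", "family_id", "role"]
    snps = [c for c in df.columns if c not in meta]
    return FamilyCohort(
        individual_id=df["individual_id"].to_numpy(dtype=object),
        family_id=df["family_id"].to_numpy(dtype=object),
        role=df["role"].to_numpy(dtype=object),
        dosage=df[snps].to_numpy(dtype=np.int8),
        snp_id=np.asarray(snps, dtype=object),
    )


def write_weights(weights: WeightSet, path: str | Path) -> None:
    write_tsv(weights.to_frame(), path)


def read_weights(path: str | Path) -> WeightSet:
    df = read_tsv(path)
    return WeightSet(
        snp_id=df["snp_id"].to_numpy(dtype=object),
        effect_allele=df["effect_allele"].to_numpy(dtype=object),
        other_allele=df["other_allele"].to_numpy(dtype=object),
        weight=df["weight"].to_numpy(dtype=float),
    )


def write_sumstats(ss: SummaryStats, path: str | Path) -> None:
    write_tsv(ss.to_frame(), path)


def read_sumstats(path: str | Path) -> SummaryStats:
    df = read_tsv(path)
    return SummaryStats(
        snp_id=df["snp_id"].to_numpy(dtype=object),
        effect_allele=df["effect_allele"].to_numpy(dtype=object),
        other_allele=df["other_allele"].to_numpy(dtype=object),
        beta_hat=df["beta"].to_numpy(dtype=float),
        se=df["se"].to_numpy(dtype=float),
        maf=df["maf"].to_numpy(dtype=float),
        n=df["n"].to_numpy(),
    )
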