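"""PGI construction: allele alignment, scoring, standardization.

A PGI is the weighted sum of effect-allele dosages, standardized to mean 0
and variance 1 within a declared reference sample.  The module also
computes the diagnostic correlation between the causal additive SNP
factor (x gamma) and the associational one (x mu), the numerator of the
proportional-bias factor.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .data import FamilyCohort, SNPPanel, WeightSet

log = logging.getLogger(__name__)


def align_weights(
    cohort_snp_id: np.ndarray,
    cohort_effect_allele: np.ndarray,
    cohort_other_allele: np.ndarray,
    weights: WeightSet,
) -> tuple[np.ndarray, np.ndarray]:
    """Match weights to cohort SNP columns, flipping sign on swapped alleles.

    Returns (cohort column indices, oriented weights).  SNPs whose allele
    pair matches neither orientation are dropped with a logged count.
    """
    wtab = {
        s: (ea, oa, w)
        for s, ea, oa, w in zip(
            weights.snp_id, weights.effect_allele, weights.other_allele, weights.weight
        )
    }
    cols, ws, mismatched = [], [], 0
    for j, (s, ea, oa) in enumerate(
        zip(cohort_snp_id, cohort_effect_allele, cohort_other_allele)
    ):
        if s not in wtab:
            continue
        wea, woa, w = wtab[s]
        if (wea, woa) == (ea, oa):
            cols.append(j)
            ws.append(w)
        elif (wea, woa) == (oa, ea):
            cols.append(j)
            ws.append(-w)
        else:
            mismatched += 1
    if mismatched:
        log.warning("dropped %d SNPs with mismatched allele pairs", mismatched)
    if not cols:
        raise ValueError("no SNP overlap between dosage and weights after alignment")
    return np.asarray(cols), np.asarray(ws, dtype=float)


def raw_score(
    cohort: FamilyCohort,
    weights: WeightSet,
    effect_allele: np.ndarray | None = None,
    other_allele: np.ndarray | None = None,
) -> np.ndarray:
    """Unstandardized weighted allele-count sum per individual."""
    ea = effect_allele if effect_allele is not None else np.full(
        cohort.n_snps, "A", dtype=object
    )
    oa = other_allele if other_allele is not None else np.full(
        cohort.n_snps, "G", dtype=object
    )
    cols, w = align_weights(cohort.snp_id, ea, oa, weights)
    return cohort.dosage[:, cols].astype(np.float64) @ w


def standardize(score: np.ndarray, reference: np.ndarray | None = None) -> np.ndarray:
    """Center and scale by the reference sample's mean and (population) sd."""
    ref = score if reference is None else reference
    sd = ref.std()
    if sd == 0:
        raise ValueError("zero score variance in the standardization sample")
    return (score - ref.mean()) / sd


def compute_pgi(
    cohort: FamilyCohort,
    weights: WeightSet,
    standardize_in: np.ndarray | None = None,
) -> pd.DataFrame:
    """Standardized proband/parental PGIs for a fully genotyped cohort.

    ``standardize_in`` selects the rows defining the standardization
    sample; by default the offspring rows (the analysis sample), falling
    back to all rows for cohorts without offspring.  The same affine
    transform is applied to parental scores so Mendelian relations
    between proband and parental PGIs are preserved.
    """
    score = raw_score(cohort, weights)
    if standardize_in is None:
        kids = np.isin(cohort.role, ("proband", "sibling"))
        ref = score[kids] if kids.any() else score
    else:
        ref = score[standardize_in]
    z = standardize(score, ref)
    df = pd.DataFrame(
        {
            "individual_id": cohort.individual_id,
            "family_id": cohort.family_id,
            "role": cohort.role,
            "pgi": z,
        }
    )
    # attach parental PGIs to child rows where parents are genotyped
    fa = df[df["role"] == "father"].set_index("family_id")["pgi"]
    mo = df[df["role"] == "mother"].set_index("family_id")["pgi"]
    child = df[df["role"].isin(["proband", "sibling"])].copy()
    child = child.rename(columns={"pgi": "pgi_proband"})
    child["pgi_father"] = child["family_id"].map(fa)
    child["pgi_mother"] = child["family_id"].map(mo)
    child["source_father"] = np.where(child["pgi_father"].notna(), "observed", "")
    child["source_mother"] = np.where(child["pgi_mother"].notna(), "observed", "")
    return child.drop(columns="role").reset_index(drop=True)


def snp_factor_correlation(panel: SNPPanel, cohort: FamilyCohort) -> float:
    """Sample correlation between x gamma and x mu.

    Equals 1 when theta = 0 or theta is proportional to gamma (then mu is
    a positive multiple of gamma); strictly below 1 when the parental
    effects point elsewhere in effect space.
    """
    X = cohort.dosage.astype(np.float64)
    g = X @ panel.gamma
    m = X @ panel.mu
    if g.std() == 0 or m.std() == 0:
        raise ValueError("a SNP factor has zero variance in this sample")
    return float(np.corrcoef(g, m)[0, 1])
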