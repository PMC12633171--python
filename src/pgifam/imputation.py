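"""Mendelian imputation of unobserved parental genotypes.

For each family the unobserved parental genotypes are treated as latent
variables with Hardy-Weinberg priors at the (estimated or supplied)
effect-allele frequency.  Enumerating all parental genotype pairs
(g_m, g_f) in {0,1,2}^2 and multiplying by the exact Mendelian
transmission likelihood of the observed offspring genotypes — conditioning
on the sibling IBD state when available — yields the exact posterior mean
E[g_m + g_f | data] per SNP.  Parental PGIs are these posterior means
pushed through the weight vector.

Designs covered: trio (nothing to impute), one observed parent plus
offspring, sibling pair (separate parents are not identifiable, so a
single combined parental expectation is returned), and singleton
offspring.  Unphased genotypes only.  No assortative-mating adjustment is
applied to the imputed parental PGIs (flagged in the output metadata).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .data import FamilyCohort, ImputationResult, MendelInconsistencyError, WeightSet
from .scoring import align_weights, standardize

log = logging.getLogger(__name__)

# T[g, a]: probability a parent with genotype g transmits allele a
_T = np.array([[1.0, 0.0], [0.5, 0.5], [0.0, 1.0]])

# _PAIR[g, sigma, a1, a2]: joint transmitted alleles to two children given
# whether they inherited the same parental haplotype (sigma=1) or not
_PAIR = np.zeros((3, 2, 2, 2))
for _g in range(3):
    haps = {0: (0, 0), 1: (0, 1), 2: (1, 1)}[_g]
    for _a1 in range(2):
        for _a2 in range(2):
            # sigma = 0: children receive the two distinct haplotypes
            _PAIR[_g, 0, _a1, _a2] = 0.5 * (
                ((_a1, _a2) == haps) + ((_a2, _a1) == haps)
            )
            # sigma = 1: same haplotype, hence identical transmitted allele
            if _a1 == _a2:
                _PAIR[_g, 1, _a1, _a2] = _T[_g, _a1]

# _L1[gm, gf, c]: one child's genotype given both parental genotypes
_L1 = np.zeros((3, 3, 3))
for _gm in range(3):
    for _gf in range(3):
        for _am in range(2):
            for _af in range(2):
                _L1[_gm, _gf, _am + _af] += _T[_gm, _am] * _T[_gf, _af]

# _L2[s, gm, gf, c1, c2]: sib-pair genotypes given parents and IBD state s,
# averaging over which parent contributes the shared haplotype when s == 1
_L2 = np.zeros((3, 3, 3, 3, 3))
for _s in range(3):
    sigmas = {0: [(0, 0)], 1: [(0, 1), (1, 0)], 2: [(1, 1)]}[_s]
    for _gm in range(3):
        for _gf in range(3):
            for _sm, _sf in sigmas:
                for _am1 in range(2):
                    for _am2 in range(2):
                        for _af1 in range(2):
                            for _af2 in range(2):
                                _L2[_s, _gm, _gf, _am1 + _af1, _am2 + _af2] += (
                                    _PAIR[_gm, _sm, _am1, _am2]
                                    * _PAIR[_gf, _sf, _af1, _af2]
                                    / len(sigmas)
                                )


def _hwe_prior(freq: np.ndarray) -> np.ndarray:
    """Genotype probabilities (3, ...) at effect-allele frequency ``freq``."""
    return np.stack([(1 - freq) ** 2, 2 * freq * (1 - freq), freq**2])


def parental_posterior_mean(
    child_dosages: list[int] | np.ndarray,
    observed_parent: int | None = None,
    ibd: int | None = None,
    maf: float = 0.5,
) -> float:
    """E[g_m + g_f | observations] at a single SNP by exact enumeration.

    ``child_dosages`` holds one or two offspring genotypes.  With two
    offspring and ``ibd`` given, the IBD-aware transmission likelihood is
    used; with ``ibd=None`` the IBD state is marginalized (independent
    transmissions).  ``observed_parent`` conditions on one known parental
    genotype and is included in the returned sum.
    """
    kids = np.asarray(child_dosages, dtype=int)
    if np.any((kids < 0) | (kids > 2)):
        raise ValueError("child dosages must lie in {0,1,2}")
    if not 0 < maf < 1:
        raise ValueError("maf must lie in (0, 1)")
    prior = _hwe_prior(np.asarray(maf))

    def child_lik(gm: int, gf: int) -> float:
        if len(kids) == 1:
            return _L1[gm, gf, kids[0]]
        if len(kids) == 2 and ibd is not None:
            return _L2[ibd, gm, gf, kids[0], kids[1]]
        return float(np.prod([_L1[gm, gf, c] for c in kids]))

    num = den = 0.0
    if observed_parent is not None:
        go = int(observed_parent)
        if go not in (0, 1, 2):
            raise ValueError("observed parent genotype must lie in {0,1,2}")
        for gx in range(3):
            w = prior[gx] * child_lik(gx, go)
            num += gx * w
            den += w
        if den == 0:
            raise MendelInconsistencyError(
                "offspring genotypes impossible given the observed parent"
            )
        return float(go + num / den)

    for gm in range(3):
        for gf in range(3):
            w = prior[gm] * prior[gf] * child_lik(gm, gf)
            num += (gm + gf) * w
            den += w
    if den == 0:
        raise MendelInconsistencyError("offspring genotypes are Mendel-inconsistent")
    return float(num / den)


def _family_table(cohort: FamilyCohort) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "row": np.arange(cohort.n_individuals),
            "family_id": cohort.family_id,
            "role": cohort.role,
        }
    )
    if cohort.parent_observed is not None:
        obs = cohort.parent_observed.set_index("family_id")
        df["father_obs"] = df["family_id"].map(obs["father"]).fillna(False)
        df["mother_obs"] = df["family_id"].map(obs["mother"]).fillna(False)
    else:
        df["father_obs"] = df["role"].eq("father").groupby(df["family_id"]).transform("any")
        df["mother_obs"] = df["role"].eq("mother").groupby(df["family_id"]).transform("any")
    return df


def impute_parental_sums(
    cohort: FamilyCohort, freq: np.ndarray | None = None
) -> list[ImputationResult]:
    """Per-family expected parental genotype sums across all SNPs.

    ``freq`` overrides the cohort-estimated effect-allele frequency used
    for the HWE prior.
    """
    if freq is None:
        freq = cohort.dosage.mean(axis=0) / 2.0
    freq = np.clip(np.asarray(freq, dtype=float), 1e-6, 1 - 1e-6)
    prior = _hwe_prior(freq)  # (3, m)

    fams = _family_table(cohort)
    ibd_of_pair = {}
    if cohort.sib_pairs is not None and cohort.ibd_state is not None:
        for pair, ibd in zip(cohort.sib_pairs, cohort.ibd_state):
            ibd_of_pair[frozenset(pair.tolist())] = ibd

    results: list[ImputationResult] = []
    for fid, grp in fams.groupby("family_id", sort=False):
        fa_rows = grp.loc[grp["role"] == "father", "row"].to_numpy()
        mo_rows = grp.loc[grp["role"] == "mother", "row"].to_numpy()
        kid_rows = grp.loc[grp["role"].isin(["proband", "sibling"]), "row"].to_numpy()
        fa_obs = bool(grp["father_obs"].iloc[0]) and len(fa_rows) == 1
        mo_obs = bool(grp["mother_obs"].iloc[0]) and len(mo_rows) == 1

        if len(kid_rows) == 0 and not (fa_obs or mo_obs):
            log.warning("family %s has no usable members; skipped", fid)
            continue

        if fa_obs and mo_obs:
            total = cohort.dosage[fa_rows[0]].astype(float) + cohort.dosage[mo_rows[0]]
            results.append(ImputationResult(fid, total, "trio", False))
            continue

        kids = cohort.dosage[kid_rows]  # (k, m)
        if fa_obs or mo_obs:
            gobs = cohort.dosage[fa_rows[0] if fa_obs else mo_rows[0]].astype(int)
            num = np.zeros(cohort.n_snps)
            den = np.zeros(cohort.n_snps)
            for gx in range(3):
                lik = np.ones(cohort.n_snps)
                for c in kids:
                    lik = lik * _L1[gx, gobs, c]
                w = prior[gx] * lik
                num += gx * w
                den += w
            if np.any(den == 0):
                raise MendelInconsistencyError(
                    f"family {fid}: offspring inconsistent with the observed parent"
                )
            results.append(
                ImputationResult(fid, gobs + num / den, "one_parent", False)
            )
            continue

        # no observed parent: sib pair (IBD-aware if known) or singleton(s)
        ibd = None
        if len(kid_rows) == 2:
            ibd = ibd_of_pair.get(frozenset(kid_rows.tolist()))
        num = np.zeros(cohort.n_snps)
        den = np.zeros(cohort.n_snps)
        for gm in range(3):
            for gf in range(3):
                if len(kid_rows) == 2 and ibd is not None:
                    lik = _L2[ibd, gm, gf, kids[0], kids[1]]
                else:
                    lik = np.ones(cohort.n_snps)
                    for c in kids:
                        lik = lik * _L1[gm, gf, c]
                w = prior[gm] * prior[gf] * lik
                num += (gm + gf) * w
                den += w
        if np.any(den == 0):
            raise MendelInconsistencyError(f"family {fid}: Mendel-inconsistent sibs")
        design = "sib_pair" if len(kid_rows) >= 2 else "singleton"
        results.append(ImputationResult(fid, num / den, design, True))
    return results


def impute_parental_pgi(
    cohort: FamilyCohort,
    weights: WeightSet,
    freq: np.ndarray | None = None,
) -> pd.DataFrame:
    """Proband and (observed or imputed) parental PGIs per child.

    Families with both parents genotyped get separate father/mother PGIs
    flagged ``observed``; one-parent families get the observed parent's
    PGI plus the missing parent's imputed PGI; families with only
    genotyped offspring get a single combined parental PGI (maternal and
    paternal expectations are not separately identified from siblings).
    The proband PGI uses the same aligned SNP set as the parental PGIs.
    All populated columns are standardized within the output sample.
    Output ``.attrs``: per-design counts and the assortative-mating
    adjustment flag (always False: not applied).
    """
    cols, w = align_weights(
        cohort.snp_id,
        np.full(cohort.n_snps, "A", dtype=object),
        np.full(cohort.n_snps, "G", dtype=object),
        weights,
    )
    sums = impute_parental_sums(cohort, freq=freq)
    by_fam = {r.family_id: r for r in sums}

    fams = _family_table(cohort)
    rows = []
    counts: dict[str, int] = {}
    for fid, grp in fams.groupby("family_id", sort=False):
        if fid not in by_fam:
            continue
        res = by_fam[fid]
        counts[res.design] = counts.get(res.design, 0) + 1
        parental_score = float(res.expected_parental_sum[cols] @ w)
        fa_rows = grp.loc[grp["role"] == "father", "row"].to_numpy()
        mo_rows = grp.loc[grp["role"] == "mother", "row"].to_numpy()
        kid_rows = grp.loc[grp["role"].isin(["proband", "sibling"]), "row"].to_numpy()
        fa_obs = bool(grp["father_obs"].iloc[0]) and len(fa_rows) == 1
        mo_obs = bool(grp["mother_obs"].iloc[0]) and len(mo_rows) == 1
        for k in kid_rows:
            rec = {
                "individual_id": cohort.individual_id[k],
                "family_id": fid,
                "design": res.design,
                "pgi_proband": float(
                    cohort.dosage[k, cols].astype(float) @ w
                ),
                "pgi_father": np.nan,
                "pgi_mother": np.nan,
                "pgi_parental_combined": np.nan,
                "source_father": "",
                "source_mother": "",
                "source_parental": "",
            }
            if res.design in ("trio", "one_parent"):
                if fa_obs:
                    rec["pgi_father"] = float(
                        cohort.dosage[fa_rows[0], cols].astype(float) @ w
                    )
                    rec["source_father"] = "observed"
                if mo_obs:
                    rec["pgi_mother"] = float(
                        cohort.dosage[mo_rows[0], cols].astype(float) @ w
                    )
                    rec["source_mother"] = "observed"
                if not fa_obs:
                    rec["pgi_father"] = parental_score - rec["pgi_mother"]
                    rec["source_father"] = "imputed"
                if not mo_obs:
                    rec["pgi_mother"] = parental_score - rec["pgi_father"]
                    rec["source_mother"] = "imputed"
            else:
                rec["pgi_parental_combined"] = parental_score
                rec["source_parental"] = "imputed"
            rows.append(rec)

    out = pd.DataFrame(rows)
    for col in ("pgi_proband", "pgi_father", "pgi_mother", "pgi_parental_combined"):
        vals = out[col]
        if vals.notna().any() and vals.std(ddof=0) > 0:
            mask = vals.notna()
            out.loc[mask, col] = standardize(vals[mask].to_numpy())
    out.attrs["design_counts"] = counts
    out.attrs["assortative_mating_adjustment"] = False
    return out
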