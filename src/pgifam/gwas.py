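"""Finite-sample population GWAS and weight construction.

With unlinked SNPs, single-variant least squares on an unrelated sample is
an unbiased (and noisy) estimator of the associational effect
mu_j = gamma_j + theta_j per SNP — exactly the kind of weight vector whose
estimation error the attenuation parameter rho quantifies.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .data import FamilyCohort, SummaryStats, WeightSet


def _residualize(y: np.ndarray, covariates: pd.DataFrame | None) -> np.ndarray:
    if covariates is None or covariates.shape[1] == 0:
        return y - y.mean()
    X = sm.add_constant(np.asarray(covariates, dtype=float))
    return np.asarray(sm.OLS(y, X).fit().resid)


def run_population_gwas(
    cohort: FamilyCohort,
    phen: pd.DataFrame,
    covariates: list[str] | None = None,
    rows: np.ndarray | None = None,
) -> SummaryStats:
    """Per-SNP OLS of the (residualized) phenotype on dosage.

    ``phen`` must contain ``individual_id`` and ``y``; individuals are
    matched to cohort rows by id.  ``rows``, if given, restricts the
    cohort rows considered (e.g. one child per family).  Monomorphic SNPs
    in the sample are excluded and reported in ``SummaryStats.excluded``.
    """
    idx = pd.Index(cohort.individual_id)
    keep = phen["individual_id"].isin(idx)
    phen = phen.loc[keep]
    row_of = pd.Series(np.arange(cohort.n_individuals), index=idx)
    sample = row_of[phen["individual_id"]].to_numpy()
    if rows is not None:
        mask = np.isin(sample, rows)
        sample = sample[mask]
        phen = phen.loc[np.asarray(mask)]

    y = _residualize(
        phen["y"].to_numpy(dtype=float),
        phen[covariates] if covariates else None,
    )
    X = cohort.dosage[sample]
    n = len(y)
    if n < 3:
        raise ValueError("too few phenotyped individuals for GWAS")

    xm = X.mean(axis=0)
    # centered cross-products without materializing a centered float copy
    sxy = X.T.astype(np.float64) @ y - n * xm * y.mean()
    sxx = np.einsum("ij,ij->j", X, X, dtype=np.float64) - n * xm**2
    poly = sxx > 0
    beta = np.full(cohort.n_snps, np.nan)
    se = np.full(cohort.n_snps, np.nan)
    beta[poly] = sxy[poly] / sxx[poly]
    syy = float(y @ y)
    rss = syy - beta[poly] ** 2 * sxx[poly]
    rss = np.maximum(rss, 0.0)
    se[poly] = np.sqrt(rss / (n - 2) / sxx[poly])
    # a numerically perfect fit yields se == 0; keep it representable
    se[poly] = np.maximum(se[poly], 1e-16)
    freq = xm / 2.0
    maf = np.minimum(freq, 1 - freq)

    se_ok = poly
    return SummaryStats(
        snp_id=cohort.snp_id[se_ok],
        effect_allele=np.full(se_ok.sum(), "A", dtype=object),
        other_allele=np.full(se_ok.sum(), "G", dtype=object),
        beta_hat=beta[se_ok],
        se=se[se_ok],
        maf=maf[se_ok],
        n=np.full(se_ok.sum(), n),
        excluded=cohort.snp_id[~se_ok],
    )


def make_weightset(
    sumstats: SummaryStats,
    shrink: float | None = 1.0,
    grid: tuple[float, ...] = (0.25, 0.5, 1.0),
    holdout: tuple[np.ndarray, np.ndarray] | None = None,
) -> WeightSet:
    """Scale the GWAS betas into PGI weights.

    ``shrink`` is a scalar multiplier in (0, 1]; pass ``None`` together
    with ``holdout = (dosage, y)`` to pick the grid value maximizing
    held-out R^2.  Since the PGI is standardized downstream a global
    scalar cannot change predictions — the grid search exists for parity
    with shrinkage-estimator workflows and for unstandardized use.
    """
    if shrink is None:
        if holdout is None:
            raise ValueError("grid selection needs a holdout (dosage, y)")
        dos, y = holdout
        best, best_r2 = grid[0], -np.inf
        for s in grid:
            score = dos @ (sumstats.beta_hat * s)
            if score.std() == 0:
                continue
            r = np.corrcoef(score, y)[0, 1]
            r2 = r * r
            if r2 > best_r2:
                best, best_r2 = s, r2
        shrink = best
    if not 0 < shrink <= 1:
        raise ValueError("shrink must lie in (0, 1]")
    return WeightSet(
        snp_id=sumstats.snp_id,
        effect_allele=sumstats.effect_allele,
        other_allele=sumstats.other_allele,
        weight=sumstats.beta_hat * shrink,
    )
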