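"""Subgroup heterogeneity of PGI effects.

Interaction models estimate the PGI effect in a baseline subgroup (psi,
or delta with parental-PGI controls) and its shift lambda in the
comparison subgroup, with the full two-way interaction set between the
PGI / subgroup indicator and the covariates so that lambda is not
contaminated by covariate-by-group differences.  Heterogeneity is judged
on the ratio psi/(psi+lambda) (resp. delta/(delta+lambda)) with a
delta-method SE, and on per-group incremental R^2 with family-bootstrap
confidence intervals.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .data import HeteroResult, RatioEstimate
from .famfit import _merge, _standardized


def median_split(values: np.ndarray) -> np.ndarray:
    """Binary indicator for 'above the median'; ties go to the lower group."""
    v = np.asarray(values, dtype=float)
    return (v > np.median(v)).astype(int)


def _build_design(
    df: pd.DataFrame,
    covariates: list[str],
    with_parents: bool,
) -> tuple[pd.DataFrame, list[str]]:
    X = pd.DataFrame(index=df.index)
    X["pgi"] = _standardized(df["pgi_proband"])
    X["M"] = df["subgroup"].astype(float)
    if X["M"].nunique() < 2:
        raise ValueError("subgroup indicator is constant")
    X["pgi_x_M"] = X["pgi"] * X["M"]
    for c in covariates:
        cc = df[c].astype(float)
        X[c] = cc - cc.mean()  # mean-centered covariates
        X[f"pgi_x_{c}"] = X["pgi"] * X[c]
        X[f"M_x_{c}"] = X["M"] * X[c]
    parent_cols = []
    if with_parents:
        if "pgi_father" in df and df["pgi_father"].notna().all():
            parent_cols = ["pgi_father", "pgi_mother"]
        elif "pgi_parental_combined" in df and df["pgi_parental_combined"].notna().all():
            parent_cols = ["pgi_parental_combined"]
        else:
            raise ValueError("with_parents requested but no parental PGI columns")
        for p in parent_cols:
            X[p] = _standardized(df[p])
            X[f"{p}_x_pgi"] = X[p] * X["pgi"]
            X[f"{p}_x_M"] = X[p] * X["M"]
    return X, parent_cols


def _fit_lm(y: np.ndarray, X: pd.DataFrame, groups: np.ndarray):
    """Family-random-intercept fit, reducing to OLS for singleton families."""
    if pd.Series(groups).duplicated().any():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.MixedLM(y, sm.add_constant(X), groups=groups).fit(reml=True)
        return fit, "linear_mixed"
    return sm.OLS(y, sm.add_constant(X)).fit(), "linear"


def fit_interaction(
    phen: pd.DataFrame,
    pgi: pd.DataFrame,
    covariates: list[str] | None = None,
    with_parents: bool = False,
    subgroup_col: str = "subgroup",
    standardize_y: bool = True,
) -> HeteroResult:
    """PGI x subgroup interaction model.

    By default the phenotype is standardized within each subgroup before
    fitting, so base and interaction are standardized coefficients; pass
    ``standardize_y=False`` for raw-scale coefficients (e.g. to compare
    against a generator that scales effects on the raw phenotype).
    Returns the baseline PGI effect, the interaction coefficient and
    their joint 2x2 covariance.
    """
    df = _merge(phen, pgi).dropna(subset=["y", "pgi_proband"])
    df = df.rename(columns={subgroup_col: "subgroup"}) if subgroup_col != "subgroup" else df
    y = df["y"].to_numpy(dtype=float).copy()
    for g in (0, 1):
        mask = df["subgroup"].to_numpy() == g
        if mask.sum() < 2 or y[mask].std() == 0:
            raise ValueError("degenerate subgroup")
        if standardize_y:
            y[mask] = (y[mask] - y[mask].mean()) / y[mask].std()
    X, _ = _build_design(df, covariates or [], with_parents)
    rank = np.linalg.matrix_rank(sm.add_constant(X).to_numpy())
    if rank < X.shape[1] + 1:
        raise ValueError("collinear interaction block")
    fit, model = _fit_lm(y, X, df["family_id"].to_numpy())
    names = list(fit.params.index)
    i_psi, i_lam = names.index("pgi"), names.index("pgi_x_M")
    cov = np.asarray(fit.cov_params())[np.ix_([i_psi, i_lam], [i_psi, i_lam])]
    return HeteroResult(
        base_effect=float(fit.params["pgi"]),
        interaction=float(fit.params["pgi_x_M"]),
        vcov=cov,
        n=len(df),
        model=model,
        with_parents=with_parents,
    )


def subgroup_ratio(res: HeteroResult) -> RatioEstimate:
    """base/(base+interaction) with delta-method SE from the joint vcov.

    Gradient of r(psi, lambda) = psi/(psi+lambda):
    dr/dpsi = lambda/(psi+lambda)^2, dr/dlambda = -psi/(psi+lambda)^2.
    """
    b, lam = res.base_effect, res.interaction
    denom = b + lam
    if abs(denom) < 5 * np.sqrt(res.vcov[0, 0] + res.vcov[1, 1] + 2 * res.vcov[0, 1]):
        warnings.warn("subgroup-1 effect near zero; refusing delta-method SE")
        raise ZeroDivisionError("denominator effect too close to zero")
    ratio = b / denom
    grad = np.array([lam / denom**2, -b / denom**2])
    se = float(np.sqrt(grad @ res.vcov @ grad))
    if se == 0:
        return RatioEstimate(ratio, 1e-300, ratio, ratio, "delta")
    return RatioEstimate(
        ratio=float(ratio),
        se=se,
        ci_low=float(ratio - 1.96 * se),
        ci_high=float(ratio + 1.96 * se),
        method="delta",
    )


def incremental_r2(
    phen: pd.DataFrame,
    pgi: pd.DataFrame,
    covariates: list[str] | None = None,
    with_parents: bool = False,
) -> float:
    """R^2 gain from adding the PGI to the covariate(+parental-PGI) model.

    R^2 is computed on the fixed-effect predictions of each fit, so mixed
    and plain fits are compared on the same footing.
    """
    df = _merge(phen, pgi).dropna(subset=["y", "pgi_proband"])
    y = df["y"].to_numpy(dtype=float)
    base_cols = {}
    for c in covariates or []:
        base_cols[c] = df[c].astype(float)
    if with_parents:
        if "pgi_father" in df and df["pgi_father"].notna().all():
            pcols = ["pgi_father", "pgi_mother"]
        elif "pgi_parental_combined" in df and df["pgi_parental_combined"].notna().all():
            pcols = ["pgi_parental_combined"]
        else:
            raise ValueError("with_parents requested but no parental PGI columns")
        for p in pcols:
            base_cols[p] = _standardized(df[p])
    reduced = pd.DataFrame(base_cols, index=df.index) if base_cols else pd.DataFrame(
        index=df.index
    )
    full = reduced.copy()
    full["pgi"] = _standardized(df["pgi_proband"])

    def r2(X: pd.DataFrame) -> float:
        Xc = sm.add_constant(X) if X.shape[1] else np.ones((len(y), 1))
        fit = sm.OLS(y, Xc).fit()
        pred = np.asarray(fit.fittedvalues)
        ss_res = float(np.sum((y - pred) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        return 1.0 - ss_res / ss_tot

    return r2(full) - r2(reduced)


def incremental_r2_by_group(
    phen: pd.DataFrame,
    pgi: pd.DataFrame,
    covariates: list[str] | None = None,
    with_parents: bool = False,
    subgroup_col: str = "subgroup",
) -> dict[int, float]:
    out = {}
    for g in (0, 1):
        sub = phen[phen[subgroup_col] == g]
        out[g] = incremental_r2(sub, pgi, covariates, with_parents)
    return out


def bootstrap_families(
    phen: pd.DataFrame,
    pgi: pd.DataFrame,
    reps: int,
    seed: int,
    covariates: list[str] | None = None,
    with_parents: bool = False,
    subgroup_col: str = "subgroup",
) -> dict:
    """Family-level bootstrap CIs for per-group incremental R^2.

    Whole families are resampled with replacement within each subgroup
    stratum (a family is assigned to the stratum of its first member);
    percentile 95% CIs are reported per group along with the CI for the
    group-0/group-1 ratio of incremental R^2.
    """
    if reps < 100:
        raise ValueError("reps must be at least 100")
    rng = np.random.default_rng(seed)
    df = _merge(phen, pgi).dropna(subset=["y", "pgi_proband"])
    fam_group = df.groupby("family_id")[subgroup_col].first()
    strata = {g: fam_group.index[fam_group == g].to_numpy() for g in (0, 1)}
    for g, fams in strata.items():
        if len(fams) < 20:
            warnings.warn(f"fewer than 20 families in subgroup {g}")
    by_fam = dict(tuple(df.groupby("family_id")))

    point = incremental_r2_by_group(
        df, pgi, covariates, with_parents, subgroup_col=subgroup_col
    )
    draws = {0: [], 1: [], "ratio": []}
    for _ in range(reps):
        pieces = []
        for g in (0, 1):
            pick = rng.choice(strata[g], size=len(strata[g]), replace=True)
            pieces.extend(by_fam[f] for f in pick)
        boot = pd.concat(pieces, ignore_index=True)
        r2s = {
            g: incremental_r2(
                boot[boot[subgroup_col] == g], pgi, covariates, with_parents
            )
            for g in (0, 1)
        }
        draws[0].append(r2s[0])
        draws[1].append(r2s[1])
        if r2s[1] != 0:
            draws["ratio"].append(r2s[0] / r2s[1])

    def ci(v):
        return (float(np.percentile(v, 2.5)), float(np.percentile(v, 97.5)))

    return {
        "point": point,
        "ci_group0": ci(draws[0]),
        "ci_group1": ci(draws[1]),
        "ci_ratio": ci(draws["ratio"]) if draws["ratio"] else (np.nan, np.nan),
    }
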