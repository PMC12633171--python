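"""Population-association and direct-effect estimation for PGIs.

The population association psi is the coefficient on an individual's
standardized PGI in a regression without parental controls, fit in a
sample of unrelated individuals.  The direct ("causal") effect delta adds
the parental PGIs as controls — separate paternal and maternal PGIs when
available, otherwise their imputed sum — and is fit with a family random
intercept when families contribute multiple offspring.  Because the two
estimates come from disjoint samples, the ratio delta/psi gets a
delta-method standard error with no covariance term.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM
from statsmodels.stats.multitest import multipletests

from .data import AssocResult, RatioEstimate


def residualize_phenotype(
    phen: pd.DataFrame,
    covariates: list[str],
    wave_col: str | None = None,
    binary: bool = False,
) -> pd.DataFrame:
    """Residualize a quantitative phenotype on covariates, per wave.

    Quantitative: OLS residuals within each wave, averaged across waves
    per individual.  Binary: the maximum across waves is taken and
    residualization is deferred to the model covariates.
    """
    for c in covariates:
        if phen[c].isna().all():
            raise ValueError(f"covariate {c} is entirely missing")
    if binary:
        keep = [c for c in phen.columns if c not in ("y",)]
        out = phen.groupby("individual_id", as_index=False).agg(
            {**{c: "first" for c in keep if c != "individual_id"}, }
        )
        ymax = phen.groupby("individual_id")["y"].max().rename("y")
        return out.merge(ymax, on="individual_id")

    waves = [phen] if wave_col is None else [g for _, g in phen.groupby(wave_col)]
    pieces = []
    for wave in waves:
        X = sm.add_constant(wave[covariates].to_numpy(dtype=float))
        resid = sm.OLS(wave["y"].to_numpy(dtype=float), X).fit().resid
        pieces.append(
            pd.DataFrame({"individual_id": wave["individual_id"], "y": resid})
        )
    resid_mean = (
        pd.concat(pieces).groupby("individual_id", as_index=False)["y"].mean()
    )
    keep = phen.drop(columns=["y"] + ([wave_col] if wave_col else []))
    keep = keep.groupby("individual_id", as_index=False).first()
    return keep.merge(resid_mean, on="individual_id")


def _standardized(x: pd.Series) -> np.ndarray:
    v = x.to_numpy(dtype=float)
    sd = v.std()
    if sd == 0:
        raise ValueError("zero-variance PGI in the estimation sample")
    return (v - v.mean()) / sd


def _merge(phen: pd.DataFrame, pgi: pd.DataFrame) -> pd.DataFrame:
    df = phen.merge(pgi, on="individual_id", suffixes=("", "_pgi"))
    if "family_id_pgi" in df:
        df["family_id"] = df["family_id"].fillna(df["family_id_pgi"])
        df = df.drop(columns="family_id_pgi")
    return df


def fit_population_association(
    phen: pd.DataFrame,
    pgi: pd.DataFrame,
    covariates: list[str] | None = None,
    binary: bool = False,
    allow_related: bool = False,
    standardize_pgi: bool = True,
) -> AssocResult:
    """psi: the coefficient on the standardized proband PGI, no parental
    controls.  Pass ``standardize_pgi=False`` when the PGI column is
    already on a common (externally fixed) scale."""
    df = _merge(phen, pgi).dropna(subset=["y", "pgi_proband"])
    if not allow_related and df["family_id"].duplicated().any():
        raise ValueError(
            "sample contains relatives; pass allow_related=True to override"
        )
    z = (
        _standardized(df["pgi_proband"])
        if standardize_pgi
        else df["pgi_proband"].to_numpy(dtype=float)
    )
    X = pd.DataFrame({"pgi": z}, index=df.index)
    for c in covariates or []:
        X[c] = df[c].astype(float)
    Xc = sm.add_constant(X)
    y = df["y"].to_numpy(dtype=float)
    if binary:
        fit = sm.Logit(y, Xc).fit(disp=0)
        model, scale = "logistic", "log_odds"
    else:
        fit = sm.OLS(y, Xc).fit()
        model, scale = "linear", "raw"
    return AssocResult(
        estimate=float(fit.params["pgi"]),
        se=float(fit.bse["pgi"]),
        n=len(df),
        model=model,
        scale=scale,
    )


def fit_causal_effect(
    phen: pd.DataFrame,
    pgi: pd.DataFrame,
    covariates: list[str] | None = None,
    binary: bool = False,
    standardize_pgi: bool = True,
) -> AssocResult:
    """delta: coefficient on the proband PGI controlling for parental PGIs.

    Uses separate father/mother PGI controls where both are populated,
    otherwise the combined parental PGI.  A family random intercept is
    included whenever any family contributes more than one phenotyped
    offspring (linear mixed model via REML; binary via a variational-Bayes
    logistic mixed model, recorded in ``model``); single-offspring data
    reduce to OLS/logistic.
    """
    df = _merge(phen, pgi).dropna(subset=["y", "pgi_proband"])
    sep = (
        "pgi_father" in df
        and "pgi_mother" in df
        and df["pgi_father"].notna().any()
        and df["pgi_mother"].notna().any()
    )
    if sep:
        df = df.dropna(subset=["pgi_father", "pgi_mother"])
        parents = ["pgi_father", "pgi_mother"]
        pnames = {"pgi_father": "alpha_p", "pgi_mother": "alpha_m"}
    elif "pgi_parental_combined" in df and df["pgi_parental_combined"].notna().any():
        df = df.dropna(subset=["pgi_parental_combined"])
        parents = ["pgi_parental_combined"]
        pnames = {"pgi_parental_combined": "alpha"}
    else:
        raise ValueError("no parental PGI columns available")

    if standardize_pgi:
        X = pd.DataFrame({"pgi": _standardized(df["pgi_proband"])}, index=df.index)
        for p in parents:
            X[p] = _standardized(df[p])
    else:
        X = pd.DataFrame(
            {"pgi": df["pgi_proband"].to_numpy(dtype=float)}, index=df.index
        )
        for p in parents:
            X[p] = df[p].to_numpy(dtype=float)
    for c in covariates or []:
        X[c] = df[c].astype(float)
    y = df["y"].to_numpy(dtype=float)
    groups = df["family_id"].to_numpy()
    multi = pd.Series(groups).duplicated().any()

    if not multi:
        return _plain_fit(y, X, binary, pnames, n=len(df))

    if binary:
        exog_vc = pd.get_dummies(pd.Series(groups), sparse=True).to_numpy(float)
        md = BinomialBayesMixedGLM(
            y, sm.add_constant(X).to_numpy(), exog_vc, ident=np.zeros(exog_vc.shape[1], dtype=int)
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = md.fit_vb()
        names = ["const"] + list(X.columns)
        est = dict(zip(names, fit.fe_mean))
        se = dict(zip(names, fit.fe_sd))
        return AssocResult(
            estimate=float(est["pgi"]),
            se=float(se["pgi"]),
            n=len(df),
            model="logistic_mixed_vb",
            scale="log_odds",
            parental_coefs={pnames[p]: (float(est[p]), float(se[p])) for p in parents},
        )

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        md = sm.MixedLM(y, sm.add_constant(X), groups=groups)
        fit = md.fit(reml=True)
    return AssocResult(
        estimate=float(fit.params["pgi"]),
        se=float(fit.bse["pgi"]),
        n=len(df),
        model="linear_mixed",
        scale="raw",
        parental_coefs={
            pnames[p]: (float(fit.params[p]), float(fit.bse[p])) for p in parents
        },
    )


def _plain_fit(y, X, binary, pnames, n):
    Xc = sm.add_constant(X)
    if binary:
        fit = sm.Logit(y, Xc).fit(disp=0)
        model, scale = "logistic", "log_odds"
    else:
        fit = sm.OLS(y, Xc).fit()
        model, scale = "linear", "raw"
    return AssocResult(
        estimate=float(fit.params["pgi"]),
        se=float(fit.bse["pgi"]),
        n=n,
        model=model,
        scale=scale,
        parental_coefs={
            v: (float(fit.params[k]), float(fit.bse[k])) for k, v in pnames.items()
        },
    )


def sibling_difference_effect(
    phen: pd.DataFrame, pgi: pd.DataFrame
) -> AssocResult:
    """Sibling fixed-effects estimator: regress within-pair phenotype
    differences on within-pair PGI differences (no intercept).

    The comparison benchmark for imputed-parental-control estimation: both
    identify the direct effect from within-family variation, but the
    difference estimator discards the between-family half of the
    Mendelian variance.
    """
    df = _merge(phen, pgi).dropna(subset=["y", "pgi_proband"])
    z = _standardized(df["pgi_proband"])
    df = df.assign(_z=z)
    dy, dz = [], []
    for _, grp in df.groupby("family_id"):
        if len(grp) >= 2:
            g = grp.iloc[:2]
            dy.append(g["y"].iloc[0] - g["y"].iloc[1])
            dz.append(g["_z"].iloc[0] - g["_z"].iloc[1])
    if len(dy) < 3:
        raise ValueError("need at least three sibling pairs")
    fit = sm.OLS(np.asarray(dy), np.asarray(dz)[:, None]).fit()
    return AssocResult(
        estimate=float(fit.params[0]),
        se=float(fit.bse[0]),
        n=len(dy),
        model="linear",
        scale="raw",
    )


def ratio_with_delta_se(delta: AssocResult, psi: AssocResult) -> RatioEstimate:
    """delta/psi with the independent-samples delta-method SE.

    SE = sqrt(SE(delta)^2/psi^2 + delta^2 SE(psi)^2 / psi^4); the
    covariance term vanishes because the two coefficients are estimated
    in disjoint samples.  A warning is raised when |psi|/SE(psi) < 5,
    where the normal approximation to a ratio is unreliable.
    """
    if psi.estimate == 0:
        raise ZeroDivisionError("psi estimate is zero; ratio undefined")
    if abs(psi.estimate) / psi.se < 5:
        warnings.warn("psi is weakly identified; the ratio SE may be unreliable")
    ratio = delta.estimate / psi.estimate
    se = np.sqrt(
        delta.se**2 / psi.estimate**2
        + delta.estimate**2 * psi.se**2 / psi.estimate**4
    )
    return RatioEstimate(
        ratio=float(ratio),
        se=float(se),
        ci_low=float(ratio - 1.96 * se),
        ci_high=float(ratio + 1.96 * se),
        method="delta",
    )


def diff_test(delta: AssocResult, psi: AssocResult) -> tuple[float, float]:
    """z and two-sided p for H0: psi - delta = 0 (independent samples)."""
    z = (psi.estimate - delta.estimate) / np.sqrt(psi.se**2 + delta.se**2)
    p = 2 * stats.norm.sf(abs(z))
    return float(z), float(p)


def bh_fdr(pvalues: list[float] | np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection flags at FDR level q."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


def ivw_meta(estimates: list[AssocResult]) -> AssocResult:
    """Inverse-variance-weighted fixed-effect pooling.

    A single input passes through unchanged (pooled estimate equals the
    single-cohort estimate).  Mixing raw and log-odds scales is refused.
    """
    if not estimates:
        raise ValueError("need at least one estimate")
    scales = {e.scale for e in estimates}
    if len(scales) > 1:
        raise ValueError(f"incommensurable scales: {scales}")
    w = np.array([1.0 / e.se**2 for e in estimates])
    est = np.array([e.estimate for e in estimates])
    pooled = float(np.sum(w * est) / np.sum(w))
    se = float(np.sqrt(1.0 / np.sum(w)))
    return AssocResult(
        estimate=pooled,
        se=se,
        n=int(sum(e.n for e in estimates)),
        model="ivw_meta" if len(estimates) > 1 else estimates[0].model,
        scale=scales.pop(),
    )
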