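"""Attenuation theory for PGI coefficients.

A PGI built from finite-sample population-GWAS weights measures the
causal additive SNP factor with two kinds of error: sampling noise in the
weights (quantified by rho = sqrt(h2_mu / R2) >= 1) and the divergence of
the associational weights mu = gamma + theta from the causal weights
gamma (quantified by Corr(x gamma, x mu) <= 1).  Under random mating both
the coefficient on the PGI and each PGI-by-environment interaction in a
parental-PGI-controlled regression are attenuated by the single factor

    bias = Corr(x gamma, x mu) / rho,

and the OLS standard errors shrink by the same factor, so dividing an
estimate and its SE by the factor de-attenuates both.  The module also
provides the expected out-of-sample predictive power
R2 = h2^2 / (h2 + M/N) with M = 60,000 effective independent SNPs, the
per-SNP effective sample size 1/(2 SE^2 MAF (1-MAF)) with its
0.8 x median filter, and a renderer for the full attenuation accounting
across phenotypes.
"""

from __future__ import annotations

import numpy as np

from .data import AttenuationReport, SummaryStats

M_EFF_DEFAULT = 60_000

# Printed inputs of the worked attenuation example: per phenotype, the
# GWAS-equivalent sample size, associational SNP heritability (SE), and the
# estimated correlation between causal and associational SNP factors (SE).
TABLE3_INPUTS = [
    {"phenotype": "Educational Attainment", "n": 2_155_939, "h2": 0.133, "se_h2": 0.003, "corr": 0.859, "se_corr": 0.028},
    {"phenotype": "Ever-smoker", "n": 1_150_055, "h2": 0.085, "se_h2": 0.006, "corr": 0.974, "se_corr": 0.019},
    {"phenotype": "Height", "n": 3_839_667, "h2": 0.231, "se_h2": 0.011, "corr": 0.970, "se_corr": 0.005},
    {"phenotype": "BMI", "n": 582_457, "h2": 0.247, "se_h2": 0.009, "corr": 1.000, "se_corr": 0.008},
    {"phenotype": "Age at first birth (women)", "n": 181_585, "h2": 0.169, "se_h2": 0.007, "corr": 0.881, "se_corr": 0.067},
    {"phenotype": "Cognitive performance", "n": 222_914, "h2": 0.232, "se_h2": 0.008, "corr": 0.975, "se_corr": 0.045},
    {"phenotype": "Non-HDL cholesterol", "n": 926_571, "h2": 0.102, "se_h2": 0.018, "corr": 0.959, "se_corr": 0.030},
    {"phenotype": "Asthma", "n": 353_336, "h2": 0.135, "se_h2": 0.011, "corr": 0.963, "se_corr": 0.035},
]


def _round_half_up(x: float, digits: int) -> float:
    scale = 10.0**digits
    return np.floor(x * scale + 0.5) / scale


def expected_r2(h2: float, n: float, m: float = M_EFF_DEFAULT) -> float:
    """Expected out-of-sample predictive power h2^2 / (h2 + M/N)."""
    if not 0 < h2 <= 1:
        raise ValueError("h2 must lie in (0, 1]")
    if n <= 0 or m <= 0:
        raise ValueError("n and m must be positive")
    return h2 * h2 / (h2 + m / n)


def effective_n(se: np.ndarray | float, maf: np.ndarray | float) -> np.ndarray | float:
    """Per-SNP effective sample size 1 / (2 SE^2 MAF (1-MAF))."""
    se = np.asarray(se, dtype=float)
    maf = np.asarray(maf, dtype=float)
    if np.any(se <= 0):
        raise ValueError("se must be positive")
    if np.any((maf <= 0) | (maf >= 1)):
        raise ValueError("maf must lie strictly in (0, 1)")
    out = 1.0 / (2.0 * se**2 * maf * (1.0 - maf))
    return float(out) if out.ndim == 0 else out


def filter_by_neff(sumstats: SummaryStats, fraction: float = 0.8) -> SummaryStats:
    """Drop SNPs with Neff strictly below ``fraction`` x median(Neff)."""
    if sumstats.n_snps == 0:
        raise ValueError("empty summary statistics")
    neff = effective_n(sumstats.se, sumstats.maf)
    keep = neff >= fraction * np.median(neff)  # boundary value retained
    if not np.any(keep):
        raise ValueError("no SNPs survive the effective-sample-size filter")
    return SummaryStats(
        snp_id=sumstats.snp_id[keep],
        effect_allele=sumstats.effect_allele[keep],
        other_allele=sumstats.other_allele[keep],
        beta_hat=sumstats.beta_hat[keep],
        se=sumstats.se[keep],
        maf=sumstats.maf[keep],
        n=sumstats.n[keep],
        excluded=np.concatenate([sumstats.excluded, sumstats.snp_id[~keep]]),
    )


def rho(h2: float, r2: float, se_h2: float = 0.0) -> tuple[float, float]:
    """Attenuation parameter rho = sqrt(h2 / R2) and its delta-method SE.

    The SE treats R2 as a known constant (the convention that reproduces
    the worked example's printed SEs): SE(rho) = SE(h2) / (2 rho R2).
    """
    if not 0 < r2 <= h2:
        raise ValueError("need 0 < r2 <= h2")
    r = np.sqrt(h2 / r2)
    se = se_h2 / (2.0 * r * r2)
    return float(r), float(se)


def rho_full_propagation(
    h2: float, n: float, se_h2: float, m: float = M_EFF_DEFAULT
) -> tuple[float, float]:
    """rho with SE(h2) propagated through R2 as well (numeric gradient).

    Alternative to :func:`rho`'s fixed-R2 convention; since R2 is itself
    a function of h2, the full gradient d rho / d h2 is used.
    """
    def f(h):
        return np.sqrt(h / expected_r2(h, n, m))

    eps = 1e-7
    grad = (f(h2 + eps) - f(h2 - eps)) / (2 * eps)
    return float(f(h2)), float(abs(grad) * se_h2)


def bias_factor(
    corr: float, se_corr: float, rho_val: float, se_rho: float
) -> tuple[float, float]:
    """Proportional bias Corr(x gamma, x mu) / rho with delta-method SE.

    Treats the correlation and rho estimates as independent:
    SE^2 = SE(corr)^2 / rho^2 + corr^2 SE(rho)^2 / rho^4.
    """
    if not 0 < corr <= 1:
        raise ValueError("corr must lie in (0, 1]")
    if rho_val < 1:
        raise ValueError("rho must be >= 1")
    factor = corr / rho_val
    se = np.sqrt(se_corr**2 / rho_val**2 + corr**2 * se_rho**2 / rho_val**4)
    return float(factor), float(se)


def correct_coefficients(
    beta_hat: float, se: float, factor: float
) -> tuple[float, float]:
    """De-attenuate a coefficient and its SE by the proportional-bias factor.

    Both the estimate and its OLS standard error are attenuated by the
    same factor, so both are divided by it.
    """
    if not 0 < factor <= 1:
        raise ValueError("factor must lie in (0, 1]")
    return beta_hat / factor, se / factor


def attenuation_row(
    phenotype: str,
    h2: float,
    se_h2: float,
    n: float,
    corr: float,
    se_corr: float,
    m: float = M_EFF_DEFAULT,
    round_columns: int | None = 3,
) -> AttenuationReport:
    """One phenotype's full attenuation accounting.

    With ``round_columns`` set (default 3 decimal places, half-up), each
    derived column is computed by plugging in the previous column at its
    printed precision — the convention under which the published worked
    example is self-consistent.  Pass ``None`` for full-precision
    propagation.
    """
    r2 = expected_r2(h2, n, m)
    if round_columns is not None:
        r2 = _round_half_up(r2, round_columns)
    rho_val, se_rho = rho(h2, r2, se_h2)
    if round_columns is not None:
        rho_val_c = _round_half_up(rho_val, round_columns)
        se_rho_c = _round_half_up(se_rho, round_columns)
    else:
        rho_val_c, se_rho_c = rho_val, se_rho
    factor, se_factor = bias_factor(corr, se_corr, rho_val_c, se_rho_c)
    return AttenuationReport(
        phenotype=phenotype,
        n_gwas=n,
        h2_mu=h2,
        se_h2=se_h2,
        r2_theory=r2,
        rho=rho_val_c,
        se_rho=se_rho_c,
        corr_gm=corr,
        se_corr=se_corr,
        bias_factor=factor,
        se_bias_factor=se_factor,
        m_eff=int(m),
    )


def table3_report(
    rows: list[dict] | None = None, round_columns: int | None = 3
) -> list[AttenuationReport]:
    """Attenuation accounting for a list of input rows (builtin by default)."""
    if rows is None:
        rows = TABLE3_INPUTS
    return [
        attenuation_row(
            r.get("phenotype", f"row{i}"),
            r["h2"],
            r["se_h2"],
            r["n"],
            r["corr"],
            r["se_corr"],
            m=r.get("m", M_EFF_DEFAULT),
            round_columns=round_columns,
        )
        for i, r in enumerate(rows)
    ]


def render_report(reports: list[AttenuationReport]) -> str:
    """Fixed-width text table of the attenuation accounting."""
    hdr = f"{'Phenotype':<28}{'N':>12}{'h2':>8}{'R2':>8}{'rho':>14}{'Corr':>14}{'Corr/rho':>16}"
    lines = [hdr, "-" * len(hdr)]
    for r in reports:
        lines.append(
            f"{r.phenotype:<28}{int(r.n_gwas):>12,}{r.h2_mu:>8.3f}{r.r2_theory:>8.3f}"
            f"{r.rho:>7.3f} ({r.se_rho:.3f}){r.corr_gm:>7.3f} ({r.se_corr:.3f})"
            f"{r.bias_factor:>9.3f} ({r.se_bias_factor:.3f})"
        )
    return "\n".join(lines)
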