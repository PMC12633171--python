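"""Forward simulation of family cohorts with direct and parental genetic effects.

The generator produces two-generation pedigrees: founders drawn under
Hardy-Weinberg equilibrium, mate pairs formed at random or by noisy
rank-matching on a mating phenotype (assortative mating), and offspring
produced by Mendelian transmission with per-SNP identity-by-descent
bookkeeping for sibling pairs.  Phenotypes follow

    y_i = x_i gamma + x_p,i theta + eps_i,

where ``x_p,i`` is the sum of the two parental dosage vectors, so that a
population regression of y on x recovers mu = gamma + theta per SNP while
the within-family (parental-PGI-controlled) regression recovers gamma.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import FamilyCohort, SNPPanel


def random_panel(
    n_snps: int,
    seed: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
    h2_gamma: float = 1.0,
    theta_mode: str = "zero",
    theta_scale: float = 0.0,
) -> SNPPanel:
    """Draw a panel of unlinked biallelic SNPs with Gaussian effects.

    gamma is scaled so that the theoretical Var(x gamma) equals ``h2_gamma``
    (the phenotype generator then sets the noise variance to hit the
    requested heritability exactly).  ``theta_mode`` controls the parental
    effects: "zero", "proportional" (theta = theta_scale * gamma) or
    "mixed" (theta = theta_scale * gamma plus an orthogonal Gaussian
    component of the same magnitude).
    """
    rng = np.random.default_rng(seed)
    maf = rng.uniform(*maf_range, size=n_snps)
    gamma = rng.normal(size=n_snps)
    var_g = float(np.sum(2 * maf * (1 - maf) * gamma**2))
    gamma *= np.sqrt(h2_gamma / var_g)
    if theta_mode == "zero":
        theta = np.zeros(n_snps)
    elif theta_mode == "proportional":
        theta = theta_scale * gamma
    elif theta_mode == "mixed":
        extra = rng.normal(size=n_snps)
        # project out gamma so the second component is orthogonal in effect space
        extra -= gamma * (extra @ gamma) / (gamma @ gamma)
        extra *= np.sqrt(np.sum(gamma**2) / np.sum(extra**2))
        theta = theta_scale * (gamma + extra)
    else:
        raise ValueError(f"unknown theta_mode {theta_mode}")
    snp_id = np.array([f"rs{j + 1}" for j in range(n_snps)], dtype=object)
    eff = np.array(["A"] * n_snps, dtype=object)
    oth = np.array(["G"] * n_snps, dtype=object)
    return SNPPanel(snp_id, eff, oth, maf, gamma, theta)


def simulate_founders(n: int, panel: SNPPanel, seed: int) -> FamilyCohort:
    """Unrelated individuals with HWE genotypes (two Bernoulli(maf) draws)."""
    if n < 2:
        raise ValueError("need at least two founders")
    rng = np.random.default_rng(seed)
    # two Bernoulli(maf) draws per genotype; chunked float32 uniforms keep
    # this fast without transient gigabyte-scale buffers
    m = panel.n_snps
    maf32 = panel.maf.astype(np.float32)
    dosage = np.empty((n, m), dtype=np.int8)
    chunk = max(1, int(64e6) // max(m, 1))
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        u = rng.random((hi - lo, m), dtype=np.float32)
        block = (u < maf32).astype(np.int8)
        rng.random((hi - lo, m), dtype=np.float32, out=u)
        block += u < maf32
        dosage[lo:hi] = block
    ids = np.array([f"I{i:07d}" for i in range(n)], dtype=object)
    fam = np.array([f"U{i:07d}" for i in range(n)], dtype=object)
    role = np.full(n, "unrelated", dtype=object)
    return FamilyCohort(ids, fam, role, dosage, panel.snp_id, seed=seed)


@dataclass
class MatePairs:
    """Mate assignment over a founder cohort (row indices)."""

    founders: FamilyCohort
    father_rows: np.ndarray
    mother_rows: np.ndarray
    realized_corr: float
    target_corr: float


def mating_phenotype(
    founders: FamilyCohort, panel: SNPPanel, h2: float, seed: int
) -> np.ndarray:
    """Founder phenotype for mate matching: direct effects plus noise only."""
    g = founders.dosage.astype(np.float32) @ panel.gamma.astype(np.float32)
    var_g = float(np.sum(panel.genotype_variance() * panel.gamma**2))
    rng = np.random.default_rng(seed)
    if h2 <= 0:
        return rng.normal(size=founders.n_individuals)
    sigma = np.sqrt(var_g * (1 - h2) / h2)
    return g + rng.normal(scale=sigma, size=founders.n_individuals)


def pair_mates(
    founders: FamilyCohort,
    phenotype: np.ndarray,
    spousal_corr: float,
    seed: int,
) -> MatePairs:
    """Assign mate pairs, optionally phenotype-assortative.

    Positive ``spousal_corr`` is realized by noisy rank-matching: both
    halves of the pool are sorted on phenotype perturbed with Gaussian
    noise whose scale is calibrated by bisection so the realized spousal
    phenotype correlation is close to the target (|error| <~ 0.03 for
    continuous phenotypes).  A discreteness ceiling below the target
    triggers a warning and the best achievable matching.
    """
    if not 0 <= spousal_corr < 1:
        raise ValueError("spousal_corr must lie in [0, 1)")
    phenotype = np.asarray(phenotype, dtype=float)
    n = founders.n_individuals
    if len(phenotype) != n:
        raise ValueError("phenotype length mismatch")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    half = n // 2
    fa = perm[:half]
    mo = perm[half : 2 * half]
    zf = phenotype[fa]
    zm = phenotype[mo]
    sd = phenotype.std()
    if sd == 0:
        if spousal_corr > 0:
            warnings.warn("constant phenotype: spousal correlation unachievable")
        return MatePairs(founders, fa, mo, float("nan"), spousal_corr)
    zf = (zf - zf.mean()) / zf.std()
    zm = (zm - zm.mean()) / zm.std()

    if spousal_corr == 0:
        return MatePairs(
            founders, fa, mo, float(np.corrcoef(zf, zm)[0, 1]), spousal_corr
        )

    ef = rng.normal(size=half)
    em = rng.normal(size=half)

    def realized(s: float) -> tuple[float, np.ndarray, np.ndarray]:
        of = np.argsort(zf + s * ef, kind="stable")
        om = np.argsort(zm + s * em, kind="stable")
        return float(np.corrcoef(zf[of], zm[om])[0, 1]), of, om

    ceiling, of0, om0 = realized(0.0)
    if ceiling < spousal_corr - 0.03:
        warnings.warn(
            f"target spousal correlation {spousal_corr:.3f} exceeds matching "
            f"ceiling {ceiling:.3f}; using best achievable"
        )
        return MatePairs(founders, fa[of0], mo[om0], ceiling, spousal_corr)

    lo, hi = 0.0, 1.0
    while realized(hi)[0] > spousal_corr and hi < 64:
        hi *= 2
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if realized(mid)[0] > spousal_corr:
            lo = mid
        else:
            hi = mid
    r, of, om = realized(0.5 * (lo + hi))
    return MatePairs(founders, fa[of], mo[om], r, spousal_corr)


def _transmit(
    geno: np.ndarray, hap_choice: np.ndarray
) -> np.ndarray:
    """Allele transmitted by each parent given a haplotype choice in {0,1}.

    Unphased parents: genotype 0 -> haplotypes (0,0), 1 -> (0,1), 2 -> (1,1),
    so the transmitted allele is the chosen haplotype only for heterozygotes.
    """
    return np.where(geno == 1, hap_choice, geno >> 1).astype(np.int8)


def meiosis_transmit(
    mates: MatePairs,
    panel: SNPPanel,
    n_children_per_family: int,
    seed: int,
    block_size: int = 1,
) -> FamilyCohort:
    """Produce offspring by Mendelian transmission.

    Each child receives one allele per parent, chosen uniformly from that
    parent's two haplotypes, independently across SNPs when
    ``block_size == 1`` or constant within consecutive blocks of that many
    SNPs otherwise (a crude linkage emulation).  With two children the
    per-SNP sibling IBD state (0/1/2 shared parental haplotypes) is
    recorded from the haplotype-choice identities.
    """
    if n_children_per_family not in (1, 2):
        raise ValueError("n_children_per_family must be 1 or 2")
    rng = np.random.default_rng(seed)
    founders = mates.founders
    gf = founders.dosage[mates.father_rows]
    gm = founders.dosage[mates.mother_rows]
    n_fam, m = gf.shape

    def hap(size_fam: int) -> np.ndarray:
        nblocks = -(-m // block_size)
        h = rng.integers(0, 2, size=(size_fam, nblocks), dtype=np.int8)
        return np.repeat(h, block_size, axis=1)[:, :m]

    children = []
    hf_list, hm_list = [], []
    for _ in range(n_children_per_family):
        hf, hm = hap(n_fam), hap(n_fam)
        hf_list.append(hf)
        hm_list.append(hm)
        children.append(_transmit(gf, hf) + _transmit(gm, hm))

    fam_ids = np.array([f"F{i:06d}" for i in range(n_fam)], dtype=object)
    roles = ["father", "mother", "proband"] + (
        ["sibling"] if n_children_per_family == 2 else []
    )
    blocks_id, blocks_fam, blocks_role, blocks_dos = [], [], [], []
    for k, role in enumerate(roles):
        if role == "father":
            ids = founders.individual_id[mates.father_rows]
            dos = gf
        elif role == "mother":
            ids = founders.individual_id[mates.mother_rows]
            dos = gm
        else:
            child_idx = 0 if role == "proband" else 1
            ids = np.array(
                [f"{f}_c{child_idx + 1}" for f in fam_ids], dtype=object
            )
            dos = children[child_idx]
        blocks_id.append(ids)
        blocks_fam.append(fam_ids)
        blocks_role.append(np.full(n_fam, role, dtype=object))
        blocks_dos.append(dos)

    sib_pairs = None
    ibd = None
    if n_children_per_family == 2:
        # rows: fathers [0,nf), mothers [nf,2nf), probands [2nf,3nf), sibs [3nf,4nf)
        sib_pairs = np.stack(
            [np.arange(2 * n_fam, 3 * n_fam), np.arange(3 * n_fam, 4 * n_fam)],
            axis=1,
        )
        ibd = (
            (hf_list[0] == hf_list[1]).astype(np.int8)
            + (hm_list[0] == hm_list[1]).astype(np.int8)
        )

    parent_observed = pd.DataFrame(
        {"family_id": fam_ids, "father": True, "mother": True}
    )
    return FamilyCohort(
        individual_id=np.concatenate(blocks_id),
        family_id=np.concatenate(blocks_fam),
        role=np.concatenate(blocks_role),
        dosage=np.concatenate(blocks_dos),
        snp_id=panel.snp_id,
        parent_observed=parent_observed,
        sib_pairs=sib_pairs,
        ibd_state=ibd,
        seed=seed,
    )


def _parental_sums(cohort: FamilyCohort) -> tuple[np.ndarray, np.ndarray]:
    """(child row indices, summed parental dosage) for families with both parents."""
    rows = np.arange(cohort.n_individuals)
    fam = pd.Series(cohort.family_id)
    fa = pd.Series(rows[cohort.role == "father"],
                   index=fam[cohort.role == "father"])
    mo = pd.Series(rows[cohort.role == "mother"],
                   index=fam[cohort.role == "mother"])
    fa = fa[~fa.index.duplicated(keep=False)]
    mo = mo[~mo.index.duplicated(keep=False)]
    kids = rows[np.isin(cohort.role, ("proband", "sibling"))]
    fa_of = fam.iloc[kids].map(fa)
    mo_of = fam.iloc[kids].map(mo)
    ok = fa_of.notna().to_numpy() & mo_of.notna().to_numpy()
    child_rows = kids[ok]
    if len(child_rows) == 0:
        raise ValueError("no individuals with both parents present in the cohort")
    xp = (
        cohort.dosage[fa_of.to_numpy()[ok].astype(int)].astype(np.int16)
        + cohort.dosage[mo_of.to_numpy()[ok].astype(int)]
    )
    return child_rows, xp


def simulate_phenotype(
    cohort: FamilyCohort,
    panel: SNPPanel,
    h2_direct: float,
    seed: int,
    parental_share: float | None = None,
    binary: bool = False,
    prevalence: float = 0.5,
    parental: bool = True,
    subgroup_scale: float = 1.0,
) -> pd.DataFrame:
    """Simulate phenotypes y = x gamma + x_p theta + eps.

    Noise is scaled so that the *theoretical* (random-mating HWE) share
    Var(x gamma)/Var(y) equals ``h2_direct``.  If ``parental_share`` is
    given, theta is rescaled so the parental term's theoretical variance
    share equals it.  With ``parental=False`` the parental term is
    dropped (founder phenotypes).  Binary phenotypes are thresholded on
    the liability at the requested prevalence.  ``subgroup_scale``
    multiplies the full genetic component in the (random half) subgroup
    coded 1, for heterogeneity experiments.

    Returns a DataFrame with individual_id, family_id, y, sex, age and
    subgroup columns; ``.attrs['decomposition']`` holds the theoretical
    and realized variance shares.
    """
    if not 0 <= h2_direct <= 1:
        raise ValueError("h2_direct must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    vj = panel.genotype_variance()
    var_g = float(np.sum(vj * panel.gamma**2))
    theta = panel.theta.copy()

    if parental and np.any(theta != 0) or (parental and parental_share):
        child_rows, xp = _parental_sums(cohort)
    elif parental:
        try:
            child_rows, xp = _parental_sums(cohort)
        except ValueError:
            child_rows, xp = np.arange(cohort.n_individuals), None
    else:
        child_rows, xp = np.arange(cohort.n_individuals), None

    if h2_direct == 0:
        var_y = 1.0 if var_g == 0 else float("inf")
        if var_g > 0:
            raise ValueError("h2_direct=0 with nonzero gamma is infeasible")
    else:
        var_y = var_g / h2_direct

    var_p = float(np.sum(2 * vj * theta**2))  # Var(x_p) = 2 Var(x) per SNP
    cov_gp = float(np.sum(vj * panel.gamma * theta))  # Cov(x_j, x_p,j) = Var(x_j)

    if parental_share is not None and parental:
        if parental_share < 0 or h2_direct + parental_share > 1:
            raise ValueError("infeasible variance shares")
        if parental_share == 0:
            theta = np.zeros_like(theta)
        else:
            if var_p == 0:
                raise ValueError("parental_share > 0 requires nonzero theta")
            theta = theta * np.sqrt(parental_share * var_y / var_p)
        var_p = float(np.sum(2 * vj * theta**2))
        cov_gp = float(np.sum(vj * panel.gamma * theta))
    if not parental:
        theta = np.zeros_like(theta)
        var_p = cov_gp = 0.0

    sigma2 = var_y - var_g - var_p - 2 * cov_gp
    if sigma2 < -1e-9:
        raise ValueError(
            "infeasible variance target: genetic variance exceeds Var(y) "
            f"(sigma^2 = {sigma2:.4g})"
        )
    sigma2 = max(sigma2, 0.0)

    n = len(child_rows)
    child_dos = cohort.dosage[child_rows].astype(np.float32)
    direct = child_dos @ panel.gamma.astype(np.float32)
    genetic = direct.copy()
    if xp is not None and np.any(theta != 0):
        genetic += xp.astype(np.float32) @ theta.astype(np.float32)
    subgroup = rng.integers(0, 2, size=n)
    if subgroup_scale != 1.0:
        genetic = np.where(subgroup == 1, subgroup_scale * genetic, genetic)
    eps = rng.normal(scale=np.sqrt(sigma2), size=n)
    y = genetic + eps

    decomposition = {
        "var_y_theory": var_y,
        "sigma2": sigma2,
        "h2_direct_theory": var_g / var_y if var_y > 0 else 0.0,
        "parental_share_theory": var_p / var_y if var_y > 0 else 0.0,
        "h2_direct_realized": float(np.var(direct) / np.var(y)),
        "theta_used": theta,
    }

    if binary:
        if not 0 < prevalence < 1:
            raise ValueError("prevalence must lie in (0, 1)")
        thr = y.mean() + y.std() * stats.norm.ppf(1 - prevalence)
        y = (y > thr).astype(int)

    out = pd.DataFrame(
        {
            "individual_id": cohort.individual_id[child_rows],
            "family_id": cohort.family_id[child_rows],
            "y": y,
            "sex": rng.integers(0, 2, size=n),
            "age": rng.uniform(40, 70, size=n),
            "subgroup": subgroup,
        }
    )
    out.attrs["decomposition"] = decomposition
    return out


def make_population(
    panel: SNPPanel,
    n: int,
    h2_direct: float,
    seed: int,
    spousal_corr: float = 0.0,
    mating_h2: float = 0.5,
    **phen_kwargs,
) -> tuple[FamilyCohort, pd.DataFrame]:
    """Founders -> mating -> one child per family -> phenotype.

    The returned cohort contains parents and children; the phenotype table
    covers the children (one unrelated child per family), which is the
    natural GWAS estimation sample since their phenotypes carry the
    parental-genotype term.
    """
    founders = simulate_founders(2 * n, panel, seed)
    mp = mating_phenotype(founders, panel, mating_h2, seed + 1)
    mates = pair_mates(founders, mp, spousal_corr, seed + 2)
    cohort = meiosis_transmit(mates, panel, 1, seed + 3)
    phen = simulate_phenotype(cohort, panel, h2_direct, seed + 4, **phen_kwargs)
    return cohort, phen


def make_trio_cohort(
    panel: SNPPanel,
    n_families: int,
    h2_direct: float,
    seed: int,
    spousal_corr: float = 0.0,
    n_children: int = 1,
    **phen_kwargs,
) -> tuple[FamilyCohort, pd.DataFrame]:
    """Trio (or quad, with two siblings) families plus child phenotypes."""
    return make_population(
        panel,
        n_families,
        h2_direct,
        seed,
        spousal_corr=spousal_corr,
        **phen_kwargs,
    ) if n_children == 1 else _make_multichild(
        panel, n_families, h2_direct, seed, spousal_corr, **phen_kwargs
    )


def _make_multichild(panel, n_families, h2_direct, seed, spousal_corr, **phen_kwargs):
    founders = simulate_founders(2 * n_families, panel, seed)
    mp = mating_phenotype(founders, panel, 0.5, seed + 1)
    mates = pair_mates(founders, mp, spousal_corr, seed + 2)
    cohort = meiosis_transmit(mates, panel, 2, seed + 3)
    phen = simulate_phenotype(cohort, panel, h2_direct, seed + 4, **phen_kwargs)
    return cohort, phen


def count_mendel_violations(cohort: FamilyCohort) -> int:
    """Trio-inconsistent (child, father, mother) genotype triples, summed over SNPs."""
    fam = pd.Series(np.arange(cohort.n_individuals)).groupby(cohort.family_id)
    total = 0
    for _, rows in fam:
        rows = rows.to_numpy()
        fa = rows[cohort.role[rows] == "father"]
        mo = rows[cohort.role[rows] == "mother"]
        kids = rows[np.isin(cohort.role[rows], ("proband", "sibling"))]
        if len(fa) != 1 or len(mo) != 1:
            continue
        gf, gm = cohort.dosage[fa[0]], cohort.dosage[mo[0]]
        lo = (gf >> 1) + (gm >> 1)  # each homozygous-alt parent forces an allele
        hi = (gf > 0).astype(np.int8) + (gm > 0).astype(np.int8)
        for k in kids:
            c = cohort.dosage[k]
            total += int(np.sum((c < lo) | (c > hi)))
    return total
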