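"""Shared containers for the family-PGI pipeline.

The containers are thin, validated wrappers around numpy arrays and pandas
DataFrames.  Genotypes are stored as effect-allele dosages in {0, 1, 2}
(int8), individuals × SNPs.  Phenotype and PGI tables are plain DataFrames
with documented column conventions so they round-trip through TSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

ROLES = ("proband", "sibling", "father", "mother", "unrelated")


class MendelInconsistencyError(ValueError):
    """Observed genotypes are impossible under Mendelian transmission."""


@dataclass
class SNPPanel:
    """Per-SNP allele frequencies and true effect sizes.

    ``gamma`` is the direct (within-family causal) per-allele effect,
    ``theta`` the effect of the summed parental genotype on the offspring
    phenotype; the population-GWAS estimand is ``mu = gamma + theta``.
    """

    snp_id: np.ndarray
    effect_allele: np.ndarray
    other_allele: np.ndarray
    maf: np.ndarray
    gamma: np.ndarray
    theta: np.ndarray

    def __post_init__(self) -> None:
        self.snp_id = np.asarray(self.snp_id, dtype=object)
        self.effect_allele = np.asarray(self.effect_allele, dtype=object)
        self.other_allele = np.asarray(self.other_allele, dtype=object)
        self.maf = np.asarray(self.maf, dtype=float)
        self.gamma = np.asarray(self.gamma, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        m = len(self.snp_id)
        for name in ("effect_allele", "other_allele", "maf", "gamma", "theta"):
            if len(getattr(self, name)) != m:
                raise ValueError(f"{name} length != number of SNPs")
        if m == 0:
            raise ValueError("empty SNP panel")
        if np.any(self.maf <= 0) or np.any(self.maf > 0.5):
            raise ValueError("maf must lie in (0, 0.5]")
        if not (np.all(np.isfinite(self.gamma)) and np.all(np.isfinite(self.theta))):
            raise ValueError("effects must be finite")

    @property
    def mu(self) -> np.ndarray:
        return self.gamma + self.theta

    @property
    def n_snps(self) -> int:
        return len(self.snp_id)

    def genotype_variance(self) -> np.ndarray:
        """Per-SNP HWE dosage variance 2·maf·(1−maf)."""
        return 2.0 * self.maf * (1.0 - self.maf)


@dataclass
class FamilyCohort:
    """Genotyped individuals with pedigree roles.

    ``dosage`` holds effect-allele counts, one row per individual.  For
    two-offspring families ``sib_pairs`` indexes sibling rows and
    ``ibd_state`` gives, per pair per SNP, the number of parental
    haplotypes shared identical by descent (0/1/2).  ``parent_observed``
    masks which parental genotypes are treated as available downstream;
    the simulator always generates them.
    """

    individual_id: np.ndarray
    family_id: np.ndarray
    role: np.ndarray
    dosage: np.ndarray
    snp_id: np.ndarray
    parent_observed: Optional[pd.DataFrame] = None  # family_id, father, mother
    sib_pairs: Optional[np.ndarray] = None          # (n_pairs, 2) row indices
    ibd_state: Optional[np.ndarray] = None          # (n_pairs, n_snps) int8
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        self.individual_id = np.asarray(self.individual_id, dtype=object)
        self.family_id = np.asarray(self.family_id, dtype=object)
        self.role = np.asarray(self.role, dtype=object)
        self.dosage = np.asarray(self.dosage)
        self.snp_id = np.asarray(self.snp_id, dtype=object)
        n = len(self.individual_id)
        if self.dosage.shape != (n, len(self.snp_id)):
            raise ValueError("dosage shape mismatch")
        bad = set(self.role) - set(ROLES)
        if bad:
            raise ValueError(f"unknown roles: {bad}")

    @property
    def n_individuals(self) -> int:
        return len(self.individual_id)

    @property
    def n_snps(self) -> int:
        return len(self.snp_id)

    def rows(self, role: str) -> np.ndarray:
        return np.flatnonzero(self.role == role)

    def subset(self, idx: np.ndarray) -> "FamilyCohort":
        """Row subset; sibling pairs with both members retained keep their
        per-SNP IBD states (indices remapped)."""
        idx = np.asarray(idx)
        sib_pairs = ibd = None
        if self.sib_pairs is not None:
            remap = {int(r): i for i, r in enumerate(idx)}
            keep = [
                k
                for k, (a, b) in enumerate(self.sib_pairs)
                if int(a) in remap and int(b) in remap
            ]
            if keep:
                sib_pairs = np.array(
                    [[remap[int(a)], remap[int(b)]] for a, b in self.sib_pairs[keep]]
                )
                if self.ibd_state is not None:
                    ibd = self.ibd_state[keep]
        return FamilyCohort(
            individual_id=self.individual_id[idx],
            family_id=self.family_id[idx],
            role=self.role[idx],
            dosage=self.dosage[idx],
            snp_id=self.snp_id,
            parent_observed=self.parent_observed,
            sib_pairs=sib_pairs,
            ibd_state=ibd,
            seed=self.seed,
        )

    def children_only(self) -> "FamilyCohort":
        """Offspring rows only, with parent_observed flags cleared."""
        out = self.subset(np.flatnonzero(np.isin(self.role, ("proband", "sibling"))))
        out.parent_observed = pd.DataFrame(
            {"family_id": pd.unique(out.family_id), "father": False, "mother": False}
        )
        return out

    def to_frame(self) -> pd.DataFrame:
        """TSV dosage dialect: ids, family, role, one column per SNP."""
        df = pd.DataFrame(
            {
                "individual_id": self.individual_id,
                "family_id": self.family_id,
                "role": self.role,
            }
        )
        dos = pd.DataFrame(self.dosage, columns=list(self.snp_id), index=df.index)
        return pd.concat([df, dos], axis=1)


@dataclass
class WeightSet:
    """Per-SNP PGI weights with effect-allele orientation."""

    snp_id: np.ndarray
    effect_allele: np.ndarray
    other_allele: np.ndarray
    weight: np.ndarray

    def __post_init__(self) -> None:
        self.snp_id = np.asarray(self.snp_id, dtype=object)
        self.effect_allele = np.asarray(self.effect_allele, dtype=object)
        self.other_allele = np.asarray(self.other_allele, dtype=object)
        self.weight = np.asarray(self.weight, dtype=float)
        if np.all(self.weight == 0):
            raise ValueError("all-zero weight vector")

    @classmethod
    def from_panel(cls, panel: SNPPanel, which: str = "mu") -> "WeightSet":
        w = {"gamma": panel.gamma, "theta": panel.theta, "mu": panel.mu}[which]
        return cls(panel.snp_id, panel.effect_allele, panel.other_allele, w.copy())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp_id": self.snp_id,
                "effect_allele": self.effect_allele,
                "other_allele": self.other_allele,
                "weight": self.weight,
            }
        )


@dataclass
class SummaryStats:
    """Single-variant association results from a population GWAS."""

    snp_id: np.ndarray
    effect_allele: np.ndarray
    other_allele: np.ndarray
    beta_hat: np.ndarray
    se: np.ndarray
    maf: np.ndarray
    n: np.ndarray
    excluded: np.ndarray = field(default=None)  # snp ids dropped (monomorphic)

    def __post_init__(self) -> None:
        self.beta_hat = np.asarray(self.beta_hat, dtype=float)
        self.se = np.asarray(self.se, dtype=float)
        self.n = np.asarray(self.n)
        if self.excluded is None:
            self.excluded = np.asarray([], dtype=object)
        if np.any(self.se <= 0):
            raise ValueError("standard errors must be positive")
        if np.any(self.n <= 0):
            raise ValueError("per-SNP n must be positive")

    @property
    def n_snps(self) -> int:
        return len(self.snp_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp_id": self.snp_id,
                "effect_allele": self.effect_allele,
                "other_allele": self.other_allele,
                "maf": self.maf,
                "beta": self.beta_hat,
                "se": self.se,
                "n": self.n,
            }
        )


@dataclass
class AssocResult:
    """A single PGI coefficient with inferential metadata.

    ``estimate`` is the coefficient on the (standardized) proband PGI:
    the population association when no parental controls were included,
    the direct effect when they were.  ``parental_coefs`` maps
    ``alpha_p``/``alpha_m`` (or ``alpha`` for a combined parental PGI)
    to (estimate, se).
    """

    estimate: float
    se: float
    n: int
    model: str                      # linear | linear_mixed | logistic | logistic_mixed
    scale: str = "raw"              # raw | log_odds
    parental_coefs: Optional[dict] = None

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise ValueError("se must be positive")

    @property
    def odds_ratio(self) -> float:
        if self.scale != "log_odds":
            raise ValueError("odds ratio only defined on the log-odds scale")
        return float(np.exp(self.estimate))


@dataclass
class RatioEstimate:
    ratio: float
    se: float
    ci_low: float
    ci_high: float
    method: str = "delta"

    def __post_init__(self) -> None:
        if self.method == "delta" and not (self.ci_low <= self.ratio <= self.ci_high):
            raise ValueError("delta CI must bracket the ratio")


@dataclass
class HeteroResult:
    """Subgroup-interaction fit: base effect, interaction, and their vcov."""

    base_effect: float
    interaction: float
    vcov: np.ndarray
    n: int
    model: str
    with_parents: bool

    def __post_init__(self) -> None:
        self.vcov = np.asarray(self.vcov, dtype=float)
        if self.vcov.shape != (2, 2):
            raise ValueError("vcov must be 2x2")
        if not np.allclose(self.vcov, self.vcov.T, atol=1e-10):
            raise ValueError("vcov must be symmetric")
        if np.any(np.linalg.eigvalsh(self.vcov) < -1e-10):
            raise ValueError("vcov must be positive semidefinite")

    @property
    def group1_effect(self) -> float:
        return self.base_effect + self.interaction


@dataclass
class AttenuationReport:
    """One phenotype's attenuation accounting (a Table-3-style row)."""

    phenotype: str
    n_gwas: float
    h2_mu: float
    se_h2: float
    r2_theory: float
    rho: float
    se_rho: float
    corr_gm: float
    se_corr: float
    bias_factor: float
    se_bias_factor: float
    m_eff: int = 60_000

    def __post_init__(self) -> None:
        if not 0 < self.r2_theory <= self.h2_mu:
            raise ValueError("need 0 < R2 <= h2_mu")
        if self.rho < 1 - 1e-9:
            raise ValueError("rho must be >= 1")
        if not 0 < self.corr_gm <= 1:
            raise ValueError("corr must lie in (0, 1]")
        if not 0 < self.bias_factor <= self.corr_gm + 1e-12:
            raise ValueError("bias factor must lie in (0, corr]")


@dataclass
class ImputationResult:
    """Per-family expected parental genotype sums."""

    family_id: str
    expected_parental_sum: np.ndarray  # per SNP, in [0, 4]
    design: str                        # trio | one_parent | sib_pair | singleton
    combined_only: bool

    def __post_init__(self) -> None:
        self.expected_parental_sum = np.asarray(self.expected_parental_sum, dtype=float)
        if np.any(self.expected_parental_sum < -1e-9) or np.any(
            self.expected_parental_sum > 4 + 1e-9
        ):
            raise ValueError("expected parental sum out of [0, 4]")
        if self.design not in ("trio", "one_parent", "sib_pair", "singleton"):
            raise ValueError(f"unknown design {self.design}")
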