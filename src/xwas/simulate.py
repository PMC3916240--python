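"""Synthetic non-PAR chrX genotypes and phenotypes.

Females are diploid with Hardy-Weinberg genotypes; males are hemizygous and
carry a single allele. Phenotypes are built from a sparse additive
architecture whose male per-allele effect depends on the assumed
dosage-compensation model:

* ``FDC`` (full dosage compensation): one X is silenced in females, so a
  male's single allele acts like a female homozygote — per-copy effect
  ``2 b`` where ``b`` is the female per-allele effect.
* ``NDC`` (no dosage compensation): both female copies are active and a male
  allele acts like a single female allele — per-copy effect ``b``.
* ``EV`` (equal variance): male per-copy effect ``sqrt(2) b``, which makes the
  male genetic variance equal to the female one.

SNPs are simulated without linkage disequilibrium; every implemented
statistic is a per-SNP contract, so LD structure would add nothing testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtri
from scipy.stats import rankdata
import statsmodels.api as sm

__all__ = [
    "XGenotypes",
    "PhenotypeTable",
    "ArchitectureSpec",
    "MALE_PER_COPY_SCALE",
    "simulate_genotypes",
    "simulate_phenotype",
    "inverse_normal_transform",
    "adjust_covariates",
]

#: Male per-copy effect relative to the female per-allele effect b.
MALE_PER_COPY_SCALE = {"FDC": 2.0, "NDC": 1.0, "EV": float(np.sqrt(2.0))}


@dataclass
class XGenotypes:
    """Sex-partitioned dosage matrices for non-PAR chrX SNPs.

    Female dosages live in [0, 2] (expected allele counts allowed); male
    dosages are raw single-copy counts in [0, 1]. The {0,2} association
    coding for males is applied downstream, never at storage time.
    """

    snp_ids: np.ndarray
    positions: np.ndarray
    effect_allele: np.ndarray
    other_allele: np.ndarray
    female_dosages: np.ndarray  # n_F x m
    male_dosages: np.ndarray  # n_M x m
    eaf_female: np.ndarray
    eaf_male: np.ndarray
    info_female: np.ndarray

    def __post_init__(self) -> None:
        self.female_dosages = np.asarray(self.female_dosages, dtype=float)
        self.male_dosages = np.asarray(self.male_dosages, dtype=float)
        m = self.n_snps
        for name in ("snp_ids", "positions", "effect_allele", "other_allele",
                     "eaf_female", "eaf_male", "info_female"):
            arr = np.asarray(getattr(self, name))
            if arr.shape[0] != m:
                raise ValueError(f"{name} has length {arr.shape[0]}, expected {m}")
            setattr(self, name, arr)
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.female_dosages, initial=0) < 0 or \
               np.nanmax(self.female_dosages, initial=0) > 2:
                raise ValueError("female dosages must lie in [0, 2]")
            if np.nanmin(self.male_dosages, initial=0) < 0 or \
               np.nanmax(self.male_dosages, initial=0) > 1:
                raise ValueError("male dosages must lie in [0, 1]")

    @property
    def n_snps(self) -> int:
        return self.female_dosages.shape[1]

    @property
    def n_females(self) -> int:
        return self.female_dosages.shape[0]

    @property
    def n_males(self) -> int:
        return self.male_dosages.shape[0]


@dataclass
class PhenotypeTable:
    """Per-sample trait values with sex labels and optional covariates."""

    sample_ids: np.ndarray
    sex: np.ndarray  # 'male' / 'female'
    raw_trait: np.ndarray
    covariates: np.ndarray  # n x k (k may be 0)
    covariate_names: list[str] = field(default_factory=list)
    normalized_residual: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.sex = np.asarray(self.sex)
        bad = set(np.unique(self.sex)) - {"male", "female"}
        if bad:
            raise ValueError(f"sex labels must be 'male'/'female'; got {sorted(bad)}")
        self.raw_trait = np.asarray(self.raw_trait, dtype=float)
        self.covariates = np.atleast_2d(np.asarray(self.covariates, dtype=float))
        if self.covariates.size == 0:
            self.covariates = np.empty((len(self.raw_trait), 0))


@dataclass
class ArchitectureSpec:
    """Sparse additive genetic architecture on the female per-allele scale."""

    causal_indices: np.ndarray
    per_copy_effects: np.ndarray
    dc_model: str = "FDC"
    residual_variance: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.dc_model = self.dc_model.upper()
        if self.dc_model not in MALE_PER_COPY_SCALE:
            raise ValueError(f"dc_model must be one of {sorted(MALE_PER_COPY_SCALE)}")
        if self.residual_variance <= 0:
            raise ValueError("residual_variance must be > 0")
        self.causal_indices = np.atleast_1d(np.asarray(self.causal_indices, dtype=int))
        self.per_copy_effects = np.atleast_1d(np.asarray(self.per_copy_effects, dtype=float))
        if self.causal_indices.shape != self.per_copy_effects.shape:
            raise ValueError("causal_indices and per_copy_effects differ in length")


def _rngs(seed: int, n: int) -> list[np.random.Generator]:
    """Deterministic independent substreams derived from one global seed."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_genotypes(
    n_females: int,
    n_males: int,
    mafs,
    seed: int,
    positions=None,
) -> XGenotypes:
    """Draw HWE female genotypes and hemizygous male alleles.

    Female dosages ~ Binomial(2, maf); male counts ~ Bernoulli(maf). Stored
    allele frequencies are the empirical column frequencies of the draw.
    """
    mafs = np.atleast_1d(np.asarray(mafs, dtype=float))
    if n_females < 0 or n_males < 0:
        raise ValueError("sample sizes must be non-negative")
    if np.any((mafs < 0) | (mafs > 1)):
        raise ValueError("allele frequencies must lie in [0, 1]")
    m = len(mafs)
    rng_f, rng_m = _rngs(seed, 2)
    fem = rng_f.binomial(2, mafs, size=(n_females, m)).astype(float)
    mal = rng_m.binomial(1, mafs, size=(n_males, m)).astype(float)
    eaf_f = fem.mean(axis=0) / 2.0 if n_females else np.full(m, np.nan)
    eaf_m = mal.mean(axis=0) if n_males else np.full(m, np.nan)
    if positions is None:
        positions = np.arange(1, m + 1) * 1000
    return XGenotypes(
        snp_ids=np.array([f"snp{i + 1}" for i in range(m)]),
        positions=np.asarray(positions, dtype=int),
        effect_allele=np.full(m, "G"),
        other_allele=np.full(m, "A"),
        female_dosages=fem,
        male_dosages=mal,
        eaf_female=eaf_f,
        eaf_male=eaf_m,
        info_female=np.ones(m),
    )


def genetic_values(geno: XGenotypes, arch: ArchitectureSpec) -> tuple[np.ndarray, np.ndarray]:
    """Additive genetic values (females, males) under the architecture's model."""
    idx = arch.causal_indices
    if idx.size and (idx.min() < 0 or idx.max() >= geno.n_snps):
        raise ValueError("causal index out of range")
    b = arch.per_copy_effects
    scale = MALE_PER_COPY_SCALE[arch.dc_model]
    g_f = geno.female_dosages[:, idx] @ b
    g_m = geno.male_dosages[:, idx] @ (scale * b)
    return g_f, g_m


def simulate_phenotype(geno: XGenotypes, arch: ArchitectureSpec) -> PhenotypeTable:
    """Trait = genetic value + N(0, residual_variance) noise, un-normalized.

    Females precede males in the returned table; sample ids are ``F0001``…/
    ``M0001``… to keep the two sexes visually distinct in written files.
    """
    g_f, g_m = genetic_values(geno, arch)
    (rng,) = _rngs(arch.seed, 1)
    sd = float(np.sqrt(arch.residual_variance))
    trait = np.concatenate([
        g_f + rng.normal(0.0, sd, size=geno.n_females),
        g_m + rng.normal(0.0, sd, size=geno.n_males),
    ])
    ids = np.array(
        [f"F{i + 1:04d}" for i in range(geno.n_females)]
        + [f"M{i + 1:04d}" for i in range(geno.n_males)]
    )
    sex = np.array(["female"] * geno.n_females + ["male"] * geno.n_males)
    return PhenotypeTable(
        sample_ids=ids,
        sex=sex,
        raw_trait=trait,
        covariates=np.empty((len(trait), 0)),
    )


def inverse_normal_transform(values) -> np.ndarray:
    """Rank-based inverse normal transform with Blom offsets.

    Maps value ranks r (ties get the average rank) to standard normal
    quantiles at (r - 3/8) / (n + 1/4), yielding mean ~0 and sd ~1.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D array")
    if len(x) < 2:
        raise ValueError("need at least two values")
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    if np.ptp(x) <= 1e-10 * max(1.0, float(np.max(np.abs(x)))):
        raise ValueError("constant input: inverse normal transform undefined")
    ranks = rankdata(x, method="average")
    return ndtri((ranks - 3.0 / 8.0) / (len(x) + 0.25))


def _check_full_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank == X.shape[1]:
        return
    # identify a minimal set of columns that break the rank when added
    culprits = []
    kept: list[int] = []
    for j in range(X.shape[1]):
        trial = X[:, kept + [j]]
        if np.linalg.matrix_rank(trial) == len(kept) + 1:
            kept.append(j)
        else:
            culprits.append(names[j] if j < len(names) else f"col{j}")
    raise ValueError(f"rank-deficient covariates; collinear columns: {culprits}")


def adjust_covariates(pheno: PhenotypeTable, sex_separate: bool = True) -> PhenotypeTable:
    """Residualize the trait on covariates, then inverse-normal transform.

    With ``sex_separate`` the regression and the transform are both done
    within each sex, so the normalized residual has mean 0 and sd ~1 in males
    and in females separately. An intercept is always included, so with no
    covariates the residual is the (within-sex) centered trait.
    """
    n = len(pheno.raw_trait)
    out = np.full(n, np.nan)
    groups = (
        [pheno.sex == "female", pheno.sex == "male"] if sex_separate
        else [np.ones(n, dtype=bool)]
    )
    names = ["intercept"] + list(
        pheno.covariate_names or [f"cov{j + 1}" for j in range(pheno.covariates.shape[1])]
    )
    for mask in groups:
        if not mask.any():
            continue
        X = sm.add_constant(pheno.covariates[mask], has_constant="add")
        _check_full_rank(X, names)
        resid = sm.OLS(pheno.raw_trait[mask], X).fit().resid
        out[mask] = inverse_normal_transform(resid)
    return PhenotypeTable(
        sample_ids=pheno.sample_ids,
        sex=pheno.sex,
        raw_trait=pheno.raw_trait,
        covariates=pheno.covariates,
        covariate_names=list(pheno.covariate_names),
        normalized_residual=out,
    )
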