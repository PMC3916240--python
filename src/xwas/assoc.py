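"""Per-sex additive association on X-coded dosages.

Two male coding conventions are supported and tracked explicitly:

* ``slope02`` — hemizygous males coded {0, 2}, equivalent to female
  homozygotes under full dosage compensation. This is the default and the
  scale on which summary statistics are reported.
* ``per_copy`` — males coded {0, 1}; the slope is the full per-allele effect
  (exactly twice the slope02 slope, with twice the SE, so z and p agree).

Females are always coded {0, 1, 2} (expected counts allowed for imputed
data) and are unaffected by the convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import PhenotypeTable, XGenotypes

__all__ = [
    "SexStratifiedEstimate",
    "VariantQC",
    "encode_dosage",
    "fit_additive",
    "female_minor_allele_count",
    "filter_variants",
    "run_association",
]

MALE_CODINGS = ("slope02", "per_copy")


@dataclass
class SexStratifiedEstimate:
    """One SNP's additive effect in one sex on the normalized trait scale."""

    snp_id: str
    sex: str
    beta: float
    se: float
    p: float
    n: int
    eaf: float
    male_coding: str | None = None  # required when sex == 'male'

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError("sex must be 'male' or 'female'")
        if self.sex == "male":
            if self.male_coding not in MALE_CODINGS:
                raise ValueError("male estimates must declare male_coding "
                                 f"as one of {MALE_CODINGS}")
        if np.isfinite(self.beta) and not self.se >= 0:
            raise ValueError("se must be non-negative")

    @property
    def z(self) -> float:
        return self.beta / self.se


@dataclass
class VariantQC:
    """Female-side quality metrics used by the variant filter."""

    snp_id: str
    info_female: float
    mac_female: int

    def __post_init__(self) -> None:
        if not 0 <= self.info_female <= 1:
            raise ValueError(f"{self.snp_id}: info must lie in [0, 1]")
        if self.mac_female < 0 or self.mac_female != int(self.mac_female):
            raise ValueError(f"{self.snp_id}: MAC must be a non-negative integer")


def encode_dosage(raw_dosage, sex: str, convention: str = "slope02",
                  snp_id: str = "?") -> np.ndarray:
    """Apply the X-chromosome allele coding for one sex.

    Females pass through unchanged; male raw counts in [0, 1] are doubled
    under ``slope02`` and returned as-is under ``per_copy``.
    """
    if convention not in MALE_CODINGS:
        raise ValueError(f"unknown convention {convention!r}")
    x = np.asarray(raw_dosage, dtype=float)
    finite = x[np.isfinite(x)]
    if sex == "female":
        if finite.size and (finite.min() < 0 or finite.max() > 2):
            raise ValueError(f"{snp_id}: female dosage outside [0, 2]")
        return x
    if sex == "male":
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError(f"{snp_id}: male dosage outside [0, 1]")
        return 2.0 * x if convention == "slope02" else x
    raise ValueError("sex must be 'male' or 'female'")


def fit_additive(coded_dosage, normalized_trait, snp_id: str = "?",
                 sex: str = "female", male_coding: str | None = None,
                 eaf: float = np.nan, min_pairs: int = 10) -> SexStratifiedEstimate:
    """Simple linear regression of trait on coded dosage.

    Missing values are dropped pairwise. The slope SE comes from the usual
    least-squares formula; the two-sided p-value uses the normal
    approximation z = beta/se, matching large-sample summary-statistic
    pipelines rather than the small-sample t reference.
    """
    x = np.asarray(coded_dosage, dtype=float)
    y = np.asarray(normalized_trait, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < min_pairs:
        raise ValueError(f"{snp_id}: only {len(x)} complete pairs "
                         f"(need >= {min_pairs})")
    if np.ptp(x) == 0:
        raise ValueError(f"{snp_id}: monomorphic variant (zero dosage variance)")
    fit = stats.linregress(x, y)
    beta, se = float(fit.slope), float(fit.stderr)
    p = float(2.0 * stats.norm.sf(abs(beta / se))) if se > 0 else 0.0
    if sex == "male" and male_coding is None:
        male_coding = "slope02"
    return SexStratifiedEstimate(
        snp_id=snp_id, sex=sex, beta=beta, se=se, p=p, n=len(x),
        eaf=float(eaf), male_coding=male_coding if sex == "male" else None,
    )


def female_minor_allele_count(female_dosages: np.ndarray) -> int:
    """Minor allele count from female dosages, rounded for imputed data."""
    d = np.asarray(female_dosages, dtype=float)
    d = d[np.isfinite(d)]
    total = float(d.sum())
    return int(round(min(total, 2 * len(d) - total)))


def filter_variants(qc, info_min: float = 0.4, mac_min: int = 3) -> list[str]:
    """Keep SNP ids with female info > info_min AND female MAC > mac_min.

    Both inequalities are strict: info 0.4 or MAC 3 exactly are dropped.
    """
    if info_min < 0 or mac_min < 0:
        raise ValueError("thresholds must be >= 0")
    return [q.snp_id for q in qc
            if q.info_female > info_min and q.mac_female > mac_min]


def run_association(
    geno: XGenotypes,
    pheno: PhenotypeTable,
    sex: str = "both",
    convention: str = "slope02",
    info_min: float = 0.4,
    mac_min: int = 3,
    min_pairs: int = 10,
) -> pd.DataFrame:
    """Per-SNP association for one or both sexes, with variant QC filters.

    Phenotype rows are matched to genotype rows by position within sex
    (females in genotype row order, then males), which is how the simulator
    and the VCF/TSV writers lay samples out. Returns the summary-statistic
    table (one row per SNP x sex) with columns SNP, POS, EA, OA, SEX, EAF,
    BETA, SE, P, N, INFO, MALE_CODING.
    """
    if pheno.normalized_residual is None:
        raise ValueError("phenotype has no normalized residual; "
                         "run adjust_covariates first")
    sexes = ["female", "male"] if sex == "both" else [sex]
    y_f = pheno.normalized_residual[pheno.sex == "female"]
    y_m = pheno.normalized_residual[pheno.sex == "male"]
    if len(y_f) != geno.n_females or len(y_m) != geno.n_males:
        raise ValueError("phenotype and genotype sample counts disagree")

    qc = [VariantQC(sid, float(info), female_minor_allele_count(geno.female_dosages[:, j]))
          for j, (sid, info) in enumerate(zip(geno.snp_ids, geno.info_female))]
    kept = set(filter_variants(qc, info_min=info_min, mac_min=mac_min))

    rows = []
    for j, sid in enumerate(geno.snp_ids):
        if sid not in kept:
            continue
        for s in sexes:
            raw = geno.female_dosages[:, j] if s == "female" else geno.male_dosages[:, j]
            y = y_f if s == "female" else y_m
            coded = encode_dosage(raw, s, convention, snp_id=sid)
            eaf = geno.eaf_female[j] if s == "female" else geno.eaf_male[j]
            try:
                est = fit_additive(coded, y, snp_id=sid, sex=s,
                                   male_coding=convention if s == "male" else None,
                                   eaf=eaf, min_pairs=min_pairs)
            except ValueError:
                continue  # monomorphic in this sex / too few pairs
            rows.append({
                "SNP": sid, "POS": int(geno.positions[j]),
                "EA": geno.effect_allele[j], "OA": geno.other_allele[j],
                "SEX": s, "EAF": est.eaf, "BETA": est.beta, "SE": est.se,
                "P": est.p, "N": est.n, "INFO": float(geno.info_female[j]),
                "MALE_CODING": est.male_coding if s == "male" else "",
            })
    return pd.DataFrame(rows, columns=["SNP", "POS", "EA", "OA", "SEX", "EAF",
                                       "BETA", "SE", "P", "N", "INFO",
                                       "MALE_CODING"])
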