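"""Per-SNP variance explained and the dosage-compensation contribution to
sex differences in trait means.

On the non-pseudoautosomal X the genotype variance differs by sex: with
males coded {0, 2} and females {0, 1, 2}, a SNP with allele frequency P has
genotype variance 2P(1-P) in females but 4P(1-P) in males. Variance
explained must therefore be computed per sex: 2P(1-P) b_F^2 (females) and
4P(1-P) b_M^2 (males), with the betas on the standardized trait scale.

When a locus escapes X-inactivation (no dosage compensation), each copy of
an allele with per-copy effect b shifts the male mean by f_a b but the
female mean by 2 f_a b, so the male-minus-female mean changes by -f_a b
relative to a population monomorphic for the other allele.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .meta import fixed_effects_meta

__all__ = [
    "SNPVarianceReport",
    "DimorphismReport",
    "variance_explained",
    "per_copy_effect_combined",
    "sex_mean_shift",
    "fraction_of_dimorphism",
]


@dataclass
class SNPVarianceReport:
    snp_id: str
    eaf_female: float
    eaf_male: float
    var_explained_female: float
    var_explained_male: float


@dataclass
class DimorphismReport:
    f_a: float
    b: float
    shift: float
    observed_diff: float
    fraction: float


def variance_explained(eaf: float, beta_slope02: float, sex: str) -> float:
    """Fraction of unit trait variance explained by one SNP in one sex."""
    if sex not in ("male", "female"):
        raise ValueError("sex must be 'male' or 'female'")
    if eaf in (0.0, 1.0):
        warnings.warn("monomorphic allele frequency: variance explained is 0",
                      stacklevel=2)
        return 0.0
    if not 0 < eaf < 1:
        raise ValueError("allele frequency must lie in [0, 1]")
    pq = eaf * (1.0 - eaf)
    factor = 2.0 if sex == "female" else 4.0
    return factor * pq * beta_slope02 ** 2


def per_copy_effect_combined(b_f: float, se_f: float, b_m_per_copy: float,
                             se_m: float, trait_sd: float = 1.0,
                             male_coding: str = "per_copy") -> tuple[float, float]:
    """Fixed-effects combination of female and male per-copy effects.

    Both inputs must be per-copy allelic effects (male {0,1} coding — twice
    the slope02 value); a slope02-tagged male input is rejected rather than
    silently doubled. The combined effect and its SE are scaled to trait
    units by ``trait_sd``.
    """
    if male_coding != "per_copy":
        raise ValueError("male effect must be per_copy-coded "
                         "(2 x slope02); refusing to rescale implicitly")
    if trait_sd <= 0:
        raise ValueError("trait_sd must be positive")
    beta, se, _p = fixed_effects_meta([(b_f, se_f), (b_m_per_copy, se_m)])
    return beta * trait_sd, se * trait_sd


def sex_mean_shift(f_a: float, b: float) -> float:
    """Change in (male mean - female mean) due to an XCI-escaping allele.

    Relative to a population monomorphic for the major allele, an allele at
    frequency f_a with per-copy effect b (both sexes, no dosage
    compensation) shifts the sex difference by -f_a * b.
    """
    if not 0 <= f_a <= 1:
        raise ValueError("allele frequency must lie in [0, 1]")
    return -f_a * b


def fraction_of_dimorphism(shift: float, observed_diff: float) -> float:
    """Share of the observed sex difference attributable to the shift."""
    if observed_diff == 0:
        raise ValueError("observed sex difference must be non-zero")
    return shift / observed_diff


def snp_variance_report(snp_id: str, eaf_female: float, beta_f: float,
                        eaf_male: float, beta_m_slope02: float) -> SNPVarianceReport:
    """Convenience bundling of the per-sex variance-explained fractions."""
    return SNPVarianceReport(
        snp_id=snp_id,
        eaf_female=eaf_female,
        eaf_male=eaf_male,
        var_explained_female=variance_explained(eaf_female, beta_f, "female"),
        var_explained_male=variance_explained(eaf_male, beta_m_slope02, "male"),
    )


def dimorphism_report(f_a: float, b: float, observed_diff: float) -> DimorphismReport:
    shift = sex_mean_shift(f_a, b)
    return DimorphismReport(
        f_a=f_a, b=b, shift=shift, observed_diff=observed_diff,
        fraction=fraction_of_dimorphism(shift, observed_diff),
    )
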