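"""Bayesian comparison of X-inactivation dosage-compensation models.

Given sex-stratified GWAS effect estimates for a SNP — the female per-allele
effect ``b_F`` and the male effect ``b_M`` on the {0,2} (slope02) coding —
two generative models are compared through their marginal likelihoods:

* FDC (full dosage compensation): b_F ~ N(0, s^2), b_M ~ N(0, s^2),
  cor(b_F, b_M) = 1 — the two effects are identical.
* NDC (no dosage compensation): b_F ~ N(0, s^2), b_M ~ N(0, 0.25 s^2),
  cor(b_F, b_M) = 1 — on the {0,2} scale the male effect is half the
  female one (b_F = 2 b_M).

The sampling distribution of the estimates is approximated as normal with
the reported standard errors, so each marginal likelihood is a bivariate
normal density: mean zero, covariance ``prior + diag(se_F^2, se_M^2)`` where
the degenerate (rank-1, cor = 1) prior is integrated out analytically.

The prior scale ``s`` is tied to the SNP's allele frequency by requiring
that the SNP explain less than 1% of trait variance with 95% probability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special, stats

from .assoc import SexStratifiedEstimate

__all__ = [
    "DCComparison",
    "prior_sd",
    "log_marginal",
    "posterior_ndc",
    "model_lines_and_ellipse",
]

#: Male prior effect as a multiple of the female effect on the slope02 scale.
MALE_MULTIPLIER = {"FDC": 1.0, "NDC": 0.5}


@dataclass
class DCComparison:
    """Evidence summary for NDC vs FDC at one SNP."""

    snp_id: str
    s: float
    logml_fdc: float
    logml_ndc: float
    log10_bf_ndc_fdc: float
    posterior_ndc: float
    prior_ndc: float

    @property
    def posterior_fdc(self) -> float:
        return 1.0 - self.posterior_ndc


def prior_sd(eaf: float, max_var: float = 0.01, prob: float = 0.95) -> float:
    """Prior sd of the female allelic effect from the variance bound.

    A female per-allele effect b at allele frequency p explains
    2 p (1 - p) b^2 of a unit-variance trait. s is chosen so that
    P(2 p (1 - p) b^2 < max_var) = prob under b ~ N(0, s^2):
    s = sqrt(max_var / (2 p (1 - p))) / z, with z the two-sided normal
    quantile at ``prob`` (1.959964 for 95%).
    """
    if not 0 < eaf < 1:
        raise ValueError("allele frequency must lie strictly in (0, 1)")
    if not 0 < prob < 1 or max_var <= 0:
        raise ValueError("need 0 < prob < 1 and max_var > 0")
    z = stats.norm.ppf(1.0 - (1.0 - prob) / 2.0)
    return float(np.sqrt(max_var / (2.0 * eaf * (1.0 - eaf))) / z)


def log_marginal(b_f: float, se_f: float, b_m: float, se_m: float,
                 s: float, male_multiplier: float) -> float:
    """Log marginal likelihood of (b_F_hat, b_M_hat) under one model.

    The cor = 1 prior concentrates on the line b_M = c b_F (c the male
    multiplier), so integrating the shared effect out gives a zero-mean
    bivariate normal with covariance
    [[s^2 + se_F^2, c s^2], [c s^2, c^2 s^2 + se_M^2]].
    """
    if se_f <= 0 or se_m <= 0:
        raise ValueError("standard errors must be positive")
    if s < 0:
        raise ValueError("prior sd must be non-negative")
    c = male_multiplier
    cov = np.array([
        [s * s + se_f * se_f, c * s * s],
        [c * s * s, c * c * s * s + se_m * se_m],
    ])
    if np.linalg.det(cov) <= 0:
        raise ValueError("model covariance is not positive definite")
    return float(stats.multivariate_normal.logpdf([b_f, b_m], mean=[0.0, 0.0],
                                                  cov=cov))


def posterior_ndc(
    est_female: SexStratifiedEstimate,
    est_male: SexStratifiedEstimate,
    eaf: float,
    prior_ndc: float = 0.5,
    max_var: float = 0.01,
    prob: float = 0.95,
) -> DCComparison:
    """Posterior probability of no dosage compensation at one SNP.

    The male estimate must be on the slope02 coding; a per_copy-tagged input
    is rejected rather than silently rescaled, because the two differ by a
    factor of 2 that is exactly what the models discriminate.
    """
    if est_male.male_coding != "slope02":
        raise ValueError("male estimate must be slope02-coded; got "
                         f"{est_male.male_coding!r} (convert before comparing)")
    if not 0 < prior_ndc < 1:
        raise ValueError("prior_ndc must lie strictly in (0, 1)")
    s = prior_sd(eaf, max_var=max_var, prob=prob)
    ml_fdc = log_marginal(est_female.beta, est_female.se,
                          est_male.beta, est_male.se, s, MALE_MULTIPLIER["FDC"])
    ml_ndc = log_marginal(est_female.beta, est_female.se,
                          est_male.beta, est_male.se, s, MALE_MULTIPLIER["NDC"])
    log_bf = ml_ndc - ml_fdc
    # posterior on the log scale for numerical safety at extreme Bayes factors
    log_odds = np.log(prior_ndc) - np.log1p(-prior_ndc) + log_bf
    post = float(special.expit(log_odds))
    return DCComparison(
        snp_id=est_female.snp_id,
        s=s,
        logml_fdc=ml_fdc,
        logml_ndc=ml_ndc,
        log10_bf_ndc_fdc=float(log_bf / np.log(10.0)),
        posterior_ndc=post,
        prior_ndc=prior_ndc,
    )


def model_lines_and_ellipse(est_female: SexStratifiedEstimate,
                            est_male: SexStratifiedEstimate,
                            level: float = 0.95) -> dict:
    """Plot geometry for the effect-size plane (female on x, male on y).

    Returns the axis-aligned confidence ellipse around the estimates
    (semi-axes sqrt(chi2_2 quantile) x se per axis) and the slopes of the
    model lines: b_M = b_F under FDC and b_M = b_F / 2 under NDC.
    """
    if est_female.se <= 0 or est_male.se <= 0:
        raise ValueError("standard errors must be positive")
    k = float(np.sqrt(stats.chi2.ppf(level, df=2)))
    return {
        "center": (est_female.beta, est_male.beta),
        "semi_axis_female": k * est_female.se,
        "semi_axis_male": k * est_male.se,
        "level": level,
        "fdc_line_slope": 1.0,
        "ndc_line_slope": 0.5,
    }
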