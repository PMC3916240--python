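"""Meta-analysis of sex- and cohort-stratified association results.

Implements inverse-variance fixed-effects combination, the 2-df
sex-differentiated test (allows different allelic effects in men and women),
the 1-df sex-heterogeneity Wald test, and median-based genomic control.

The pipeline driver applies the stages in the order the per-cohort workflow
requires: genomic control within each cohort x sex stratum first, then
fixed-effects meta within each sex across cohorts, then the sex-level
combination and heterogeneity tests on the per-sex meta results.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MetaResult",
    "fixed_effects_meta",
    "sex_differentiated_test",
    "sex_heterogeneity_test",
    "genomic_control",
    "meta_analyse",
]

#: Median of the chi-square distribution with 1 df.
CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, df=1))


@dataclass
class MetaResult:
    snp_id: str
    beta: float
    se: float
    p: float
    chi2_sexdiff: float
    p_sexdiff: float
    q_het: float
    p_het: float
    n_total: int
    lambda_applied: float = 1.0


def fixed_effects_meta(estimates) -> tuple[float, float, float]:
    """Inverse-variance weighted fixed-effects combination.

    ``estimates`` is a sequence of (beta, se) pairs. Returns (beta, se, p)
    with beta = sum(w_i b_i)/sum(w_i), se = sum(w_i)^(-1/2), w_i = se_i^-2,
    and a two-sided normal p-value.
    """
    est = list(estimates)
    if not est:
        raise ValueError("need at least one estimate")
    b = np.array([e[0] for e in est], dtype=float)
    s = np.array([e[1] for e in est], dtype=float)
    if np.any(s <= 0):
        raise ValueError("all standard errors must be positive")
    w = s ** -2
    beta = float((w * b).sum() / w.sum())
    se = float(w.sum() ** -0.5)
    p = float(2.0 * stats.norm.sf(abs(beta / se)))
    return beta, se, p


def sex_differentiated_test(beta_f, se_f, beta_m, se_m):
    """2-df chi-square combining the female and male z-scores.

    chi2 = z_F^2 + z_M^2 with z = beta/se. If one sex is missing (beta/se
    None) the test degrades to 1 df on the available sex and the result is
    flagged. Returns (chi2, p, df).
    """
    zs = []
    for b, s in ((beta_f, se_f), (beta_m, se_m)):
        if b is None or s is None:
            continue
        if s <= 0:
            raise ValueError("standard errors must be positive")
        zs.append(b / s)
    if not zs:
        raise ValueError("no estimates supplied")
    chi2 = float(sum(z * z for z in zs))
    df = len(zs)
    return chi2, float(stats.chi2.sf(chi2, df=df)), df


def sex_heterogeneity_test(beta_f, se_f, beta_m, se_m) -> tuple[float, float]:
    """1-df Wald test of b_F = b_M; algebraically Cochran's Q for 2 groups.

    q = (b_F - b_M)^2 / (se_F^2 + se_M^2); p from chi-square with 1 df.
    """
    if se_f <= 0 or se_m <= 0:
        raise ValueError("standard errors must be positive")
    q = float((beta_f - beta_m) ** 2 / (se_f ** 2 + se_m ** 2))
    return q, float(stats.chi2.sf(q, df=1))


def genomic_control(chi2_values, apply_if_above: float = 1.0):
    """Median-based genomic-control inflation factor and corrected stats.

    lambda = median(chi2) / median(chi2_1). When lambda exceeds
    ``apply_if_above`` every statistic is divided by lambda and p-values are
    recomputed; otherwise the statistics pass through untouched (genomic
    control never inflates evidence). Returns
    (lambda, corrected_chi2, corrected_p).
    """
    chi2 = np.asarray(chi2_values, dtype=float)
    if chi2.size < 2:
        raise ValueError("need at least two statistics to estimate lambda")
    lam = float(np.median(chi2) / CHI2_1_MEDIAN)
    corrected = chi2 / lam if lam > apply_if_above else chi2.copy()
    p = stats.chi2.sf(corrected, df=1)
    return lam, corrected, p


def _gc_stratum(df: pd.DataFrame, apply_if_above: float) -> tuple[pd.DataFrame, float]:
    """Genomic control on one cohort x sex summary table (SE inflation form)."""
    chi2 = (df["BETA"] / df["SE"]) ** 2
    lam, corrected, p = genomic_control(chi2.to_numpy(), apply_if_above)
    out = df.copy()
    if lam > apply_if_above:
        out["SE"] = out["SE"] * np.sqrt(lam)
        out["P"] = p
    return out, lam


def meta_analyse(
    strata: list[pd.DataFrame],
    gc: bool = True,
    gc_apply_if_above: float = 1.0,
    min_strata: int = 2,
) -> pd.DataFrame:
    """Full meta-analysis over cohort x sex summary tables.

    Each input frame is one stratum in the xwas summary format (columns SNP,
    SEX, BETA, SE, P, N, ...). Stages: per-stratum genomic control (optional),
    per-sex fixed-effects meta across strata, then the sex-differentiated and
    heterogeneity tests plus an all-strata fixed-effects combination. SNPs
    present in fewer than ``min_strata`` strata are dropped.
    """
    if gc:
        corrected = []
        lambdas = []
        for df in strata:
            out, lam = _gc_stratum(df, gc_apply_if_above)
            corrected.append(out)
            lambdas.append(lam)
    else:
        corrected = [df.copy() for df in strata]
        lambdas = [1.0] * len(strata)

    for df, lam in zip(corrected, lambdas):
        df["LAMBDA"] = lam
    stacked = pd.concat(corrected, ignore_index=True)
    counts = stacked.groupby("SNP")["BETA"].size()
    keep = counts[counts >= min_strata].index
    stacked = stacked[stacked["SNP"].isin(keep)]

    rows = []
    for snp, grp in stacked.groupby("SNP", sort=False):
        per_sex: dict[str, tuple[float, float]] = {}
        for s, sgrp in grp.groupby("SEX"):
            per_sex[s] = fixed_effects_meta(
                list(zip(sgrp["BETA"], sgrp["SE"])))[:2]
        beta, se, p = fixed_effects_meta(list(zip(grp["BETA"], grp["SE"])))
        bf, sf_ = per_sex.get("female", (None, None))
        bm, sm = per_sex.get("male", (None, None))
        chi2_sd, p_sd, _df = sex_differentiated_test(bf, sf_, bm, sm)
        if bf is not None and bm is not None:
            q, p_het = sex_heterogeneity_test(bf, sf_, bm, sm)
        else:
            q, p_het = np.nan, np.nan
        rows.append({
            "SNP": snp, "BETA_META": beta, "SE_META": se, "P_META": p,
            "BETA_F": bf, "SE_F": sf_, "BETA_M": bm, "SE_M": sm,
            "CHI2_SEXDIFF": chi2_sd, "P_SEXDIFF": p_sd,
            "Q_HET": q, "P_HET": p_het,
            "N_TOTAL": int(grp["N"].sum()),
            "LAMBDA": float(grp["LAMBDA"].max()),
        })
    return pd.DataFrame(rows)


def significant_hits(meta: pd.DataFrame, threshold: float = 5e-8) -> pd.DataFrame:
    """Rows reaching the conventional genome-wide threshold (P < 5e-8)."""
    mask = (meta["P_META"] < threshold) | (meta["P_SEXDIFF"] < threshold)
    return meta[mask].reset_index(drop=True)
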