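"""X-aware GREML: genetic relationship matrices and REML variance components.

The genetic relationship matrix (GRM) for non-PAR chrX depends on the
assumed dosage-compensation model. Genotypes are standardized per SNP using
the pooled allele frequency p (males counted once):

* females: (x - 2p) / sqrt(2 p (1 - p))
* males:   (x - p) / sqrt(p (1 - p))

and male rows are then scaled by d_M = sqrt(2) (FDC), 1/sqrt(2) (NDC) or 1
(EV), so that the male genetic variance implied by the GRM is twice, half,
or equal to the female one. GRM = (1/m) D W W^T D.

Variance components are estimated by average-information REML with EM
fallback steps and non-negativity constraints; a boundary likelihood-ratio
test (the 50:50 chi0/chi1 mixture) tests whether the X-linked variance is
zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .simulate import XGenotypes

__all__ = [
    "GRM",
    "VarianceComponents",
    "MALE_GRM_SCALE",
    "make_grm",
    "prune_related",
    "reml_fit",
    "lrt_zero_variance",
]

MALE_GRM_SCALE = {"FDC": float(np.sqrt(2.0)), "NDC": float(1.0 / np.sqrt(2.0)),
                  "EV": 1.0}


@dataclass
class GRM:
    matrix: np.ndarray
    sample_ids: np.ndarray
    sex: np.ndarray
    dc_model: str
    m_snps: int

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise ValueError("GRM must be square")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("GRM entries must be finite")
        if not np.allclose(self.matrix, self.matrix.T):
            raise ValueError("GRM must be symmetric")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


@dataclass
class VarianceComponents:
    sigma2: np.ndarray          # one per GRM component
    sigma2_e: float
    h2: np.ndarray              # sigma2 / total, per GRM component
    se: np.ndarray              # SEs for (sigma2..., sigma2_e) from inverse AI
    loglik: float
    converged: bool
    n_used: int
    n_iter: int = 0
    message: str = ""
    h2_se: np.ndarray = field(default=None)  # delta-method SEs for h2


def make_grm(geno, dc_model: str = "EV", maf_min: float = 0.01) -> GRM:
    """Build a GRM from X genotypes (sex-aware) or an autosomal dosage matrix.

    Monomorphic SNPs and SNPs with pooled MAF <= ``maf_min`` are skipped.
    For a plain n x m autosomal matrix (dosages in [0, 2]) the standard
    (x - 2p)/sqrt(2p(1-p)) scaling is applied to every row and ``dc_model``
    is ignored.
    """
    if isinstance(geno, XGenotypes):
        dc_model = dc_model.upper()
        if dc_model not in MALE_GRM_SCALE:
            raise ValueError(f"dc_model must be one of {sorted(MALE_GRM_SCALE)}")
        n_f, n_m = geno.n_females, geno.n_males
        # pooled allele frequency counting each male allele once
        p = (geno.female_dosages.sum(axis=0) + geno.male_dosages.sum(axis=0)) \
            / (2.0 * n_f + n_m)
        usable = (p > maf_min) & (p < 1.0 - maf_min)
        if not usable.any():
            raise ValueError("no usable polymorphic SNPs after the MAF filter")
        p = p[usable]
        w_f = (geno.female_dosages[:, usable] - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
        w_m = (geno.male_dosages[:, usable] - p) / np.sqrt(p * (1.0 - p))
        w_m *= MALE_GRM_SCALE[dc_model]
        w = np.vstack([w_f, w_m])
        m = int(usable.sum())
        sample_ids = np.array([f"F{i + 1:04d}" for i in range(n_f)]
                              + [f"M{i + 1:04d}" for i in range(n_m)])
        sex = np.array(["female"] * n_f + ["male"] * n_m)
        tag = dc_model
    else:
        x = np.asarray(geno, dtype=float)
        p = x.mean(axis=0) / 2.0
        usable = (p > maf_min) & (p < 1.0 - maf_min)
        if not usable.any():
            raise ValueError("no usable polymorphic SNPs after the MAF filter")
        p = p[usable]
        w = (x[:, usable] - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
        m = int(usable.sum())
        sample_ids = np.array([f"S{i + 1:04d}" for i in range(x.shape[0])])
        sex = np.full(x.shape[0], "unknown")
        tag = "AUTO"
    return GRM(matrix=(w @ w.T) / m, sample_ids=sample_ids, sex=sex,
               dc_model=tag, m_snps=m)


def prune_related(grm: GRM, threshold: float = 0.05) -> np.ndarray:
    """Greedy removal of related individuals until no pair exceeds threshold.

    While any off-diagonal relatedness exceeds the threshold, the individual
    involved in the most offending pairs is dropped (ties broken toward the
    larger index). Deterministic; returns the kept sample ids.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    a = np.abs(grm.matrix.copy())
    np.fill_diagonal(a, 0.0)
    alive = np.ones(grm.n, dtype=bool)
    over = a > threshold
    while True:
        counts = (over & alive[None, :] & alive[:, None]).sum(axis=1)
        counts[~alive] = 0
        if counts.max() == 0:
            break
        worst = np.flatnonzero(counts == counts.max()).max()
        alive[worst] = False
    return grm.sample_ids[alive]


def _reml_loglik(y, X, V):
    """Restricted log-likelihood pieces: (loglik, P matrix, Py)."""
    L = np.linalg.cholesky(V)
    Vinv_X = np.linalg.solve(V, X)
    Vinv_y = np.linalg.solve(V, y)
    XtVinvX = X.T @ Vinv_X
    logdet_V = 2.0 * np.log(np.diag(L)).sum()
    sign, logdet_X = np.linalg.slogdet(XtVinvX)
    if sign <= 0:
        raise np.linalg.LinAlgError("X'V^-1 X not positive definite")
    beta = np.linalg.solve(XtVinvX, X.T @ Vinv_y)
    Py = Vinv_y - Vinv_X @ beta
    ll = -0.5 * (logdet_V + logdet_X + float(y @ Py))
    P = np.linalg.inv(V) - Vinv_X @ np.linalg.solve(XtVinvX, Vinv_X.T)
    return ll, P, Py


def reml_fit(normalized_trait, grms, tol: float = 1e-8, max_iter: int = 100,
             covariates=None) -> VarianceComponents:
    """Average-information REML for trait variance components.

    ``grms`` is a list of GRM objects (or bare symmetric matrices); the
    model is y = Xb + sum_k g_k + e with var(g_k) = sigma2_k A_k and
    var(e) = sigma2_e I. X is an intercept plus optional covariates. AI
    updates that leave the feasible region fall back to single EM steps;
    components are constrained to be non-negative. Standard errors come from
    the inverse average-information matrix at convergence. Non-convergence
    and unidentifiable models are flagged, not raised.
    """
    y = np.asarray(normalized_trait, dtype=float)
    n = len(y)
    mats = [g.matrix if isinstance(g, GRM) else np.asarray(g, dtype=float)
            for g in grms]
    for a in mats:
        if a.shape != (n, n):
            raise ValueError("GRM order does not match trait length")
    if covariates is None:
        X = np.ones((n, 1))
    else:
        X = np.column_stack([np.ones(n), np.asarray(covariates, dtype=float)])
    k = len(mats)
    vary = float(np.var(y, ddof=1))
    theta = np.full(k + 1, vary / (k + 1))  # (sigma2_1..k, sigma2_e)
    floor = 1e-8 * vary
    comps = mats + [np.eye(n)]

    def build_V(th):
        V = th[-1] * np.eye(n)
        for t, a in zip(th[:-1], mats):
            V += t * a
        return V

    ll_old = -np.inf
    converged = False
    message = ""
    AI = None
    it = 0
    for it in range(1, max_iter + 1):
        try:
            ll, P, Py = _reml_loglik(y, X, build_V(theta))
        except np.linalg.LinAlgError:
            message = "variance matrix not positive definite"
            break
        # score and average information
        APy = [a @ Py for a in comps]
        score = np.array([-0.5 * (np.sum(P * a) - float(Py @ apy))
                          for a, apy in zip(comps, APy)])
        AI = 0.5 * np.array([[float(ai @ P @ aj) for aj in APy] for ai in APy])
        at_boundary = theta <= floor * (1 + 1e-12)
        stationary = (np.abs(score) < 1e-3) | (at_boundary & (score < 0))
        if abs(ll - ll_old) < tol and np.all(stationary):
            converged = True
            ll_old = ll
            break
        ll_old = ll
        try:
            delta = np.linalg.solve(AI, score)
        except np.linalg.LinAlgError:
            delta = None
        new = theta + delta if delta is not None else None
        if new is None or np.any(new < 0):
            # EM fallback: guaranteed-feasible single step per component
            new = theta + theta ** 2 * np.array(
                [(float(Py @ apy) - np.sum(P * a)) / n
                 for a, apy in zip(comps, APy)])
            new = np.maximum(new, floor)
        theta = np.maximum(new, floor)
    else:
        message = message or f"no convergence in {max_iter} iterations"

    if AI is not None:
        # SEs from the inverse AI matrix; singular AI => unidentifiable model
        try:
            cond = np.linalg.cond(AI)
            if not np.isfinite(cond) or cond > 1e12:
                raise np.linalg.LinAlgError
            se = np.sqrt(np.diag(np.linalg.inv(AI)))
        except np.linalg.LinAlgError:
            se = np.full(k + 1, np.nan)
            converged = False
            message = message or "singular information matrix (aliased components)"
    else:
        se = np.full(k + 1, np.nan)

    total = float(theta.sum())
    h2 = theta[:-1] / total
    # delta-method SE for h2_i = s_i / total, using inverse-AI covariance
    h2_se = np.full(k, np.nan)
    if np.all(np.isfinite(se)):
        try:
            cov = np.linalg.inv(AI)
            for i in range(k):
                grad = np.full(k + 1, -theta[i] / total ** 2)
                grad[i] += 1.0 / total
                h2_se[i] = float(np.sqrt(grad @ cov @ grad))
        except np.linalg.LinAlgError:
            pass
    return VarianceComponents(
        sigma2=theta[:-1].copy(), sigma2_e=float(theta[-1]), h2=h2, se=se,
        loglik=float(ll_old), converged=converged, n_used=n, n_iter=it,
        message=message, h2_se=h2_se,
    )


def lrt_zero_variance(loglik_full: float, loglik_null: float,
                      tol: float = 1e-6) -> float:
    """Boundary likelihood-ratio test of a zero variance component.

    The null value lies on the boundary of the parameter space, so the LR
    statistic follows the 50:50 mixture of a point mass at 0 and chi2(1):
    p = 0.5 P(chi2_1 > LR). LR = 0 gives p = 0.5.
    """
    lr = 2.0 * (loglik_full - loglik_null)
    if lr < -tol:
        raise ValueError("full-model likelihood below null: optimizer fault")
    lr = max(lr, 0.0)
    return float(0.5 * stats.chi2.sf(lr, df=1))
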