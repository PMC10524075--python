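"""Diagnostic-test-accuracy meta-analysis.

The centrepiece is the bivariate random-effects model for paired
(sensitivity, specificity): each study contributes logit-transformed
estimates (y1_i, y2_i) = (logit sens_i, logit spec_i) whose true values are
drawn from a bivariate normal

    (theta1_i, theta2_i) ~ N2((mu_sens, mu_spec), Sigma),
    Sigma = [[tau_sens^2, rho tau_sens tau_spec],
             [rho tau_sens tau_spec, tau_spec^2]],

with within-study sampling handled either by the normal approximation
(variances 1/tp + 1/fn and 1/tn + 1/fp on the logit scale; REML fit — the
default) or by the exact binomial likelihood integrated over the random
effects with adaptive Gauss-Hermite quadrature (ML fit).

On top of the fitted model the module provides

* pooled sensitivity/specificity with Wald logit-scale intervals and pooled
  likelihood ratios as functions of the pooled logits with delta-method
  intervals on the log-LR scale (a plug-in bivariate LR pooling in the
  spirit of Zwinderman & Bossuyt), with an optional parametric-bootstrap
  cross-check;
* the summary ROC curve induced by the bivariate parameters via the
  Harbord accuracy/threshold reparameterisation, with trapezoidal AUC;
* random-effects pooling of single proportions (logit scale,
  DerSimonian-Laird) for detection rates and the like;
* Cochran's Q and I^2;
* meta-regression on the bivariate means with likelihood-ratio tests and
  the share of between-study variance explained per outcome;
* Deeks' funnel-plot asymmetry test for small-study effects;
* Fagan pretest-to-posttest probability arithmetic.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, gammaln, logit, logsumexp
from scipy.stats import chi2, norm, t as t_dist

from .accuracy import Interval, proportion_ci

__all__ = [
    "StudyRecord",
    "BivariateFit",
    "PooledAccuracy",
    "SROC",
    "PooledProportion",
    "HeterogeneityResult",
    "MetaRegressionResult",
    "DeeksResult",
    "FaganResult",
    "ConvergenceError",
    "fit_bivariate",
    "summarize_bivariate",
    "sroc_curve",
    "pool_proportion",
    "heterogeneity",
    "meta_regression",
    "deeks_test",
    "fagan_posttest",
]

_RHO_CAP = 0.999
_TAU_CAP = 10.0


class ConvergenceError(RuntimeError):
    """Raised when no optimizer start converges; carries the best fit found."""

    def __init__(self, message: str, best_fit: Optional["BivariateFit"] = None):
        super().__init__(message)
        self.best_fit = best_fit


@dataclass(frozen=True)
class StudyRecord:
    """One study's 2x2 counts plus stratification covariates."""

    study_id: str
    tp: int
    fp: int
    fn: int
    tn: int
    covariates: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cell in (self.tp, self.fp, self.fn, self.tn):
            if cell < 0:
                raise ValueError("study counts must be >= 0")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def informative_for_sensitivity(self) -> bool:
        return self.tp + self.fn > 0


@dataclass(frozen=True)
class BivariateFit:
    """Fitted bivariate logit-normal model."""

    mu_sens: float
    mu_spec: float
    tau2_sens: float
    tau2_spec: float
    rho: float
    loglik: float
    n_studies: int
    method: str
    mu_cov: np.ndarray  # 2x2 covariance of (mu_sens, mu_spec)
    tau_sens_se: float = math.nan
    tau_spec_se: float = math.nan
    rho_se: float = math.nan
    converged: bool = True

    @property
    def pooled_sensitivity(self) -> float:
        return float(expit(self.mu_sens))

    @property
    def pooled_specificity(self) -> float:
        return float(expit(self.mu_spec))


@dataclass(frozen=True)
class PooledAccuracy:
    sensitivity: float
    specificity: float
    sensitivity_ci: Interval
    specificity_ci: Interval
    lr_pos: float
    lr_neg: float
    lr_pos_ci: Interval
    lr_neg_ci: Interval
    level: float = 0.95


@dataclass(frozen=True)
class SROC:
    curve: np.ndarray  # (k, 2) array of (FPR, sensitivity)
    auc: Optional[float]
    summary_point: tuple[float, float]  # (1 - pooled spec, pooled sens)
    degenerate: bool = False


@dataclass(frozen=True)
class PooledProportion:
    estimate: float
    interval: Interval
    tau2: float
    i2: float
    scale: str = "proportion"
    all_zero: bool = False


@dataclass(frozen=True)
class HeterogeneityResult:
    q: float
    df: int
    i2: float
    p_value: float


@dataclass(frozen=True)
class MetaRegressionResult:
    covariate: str
    reference: str
    coefficients: Mapping[str, tuple[float, float]]  # category -> (sens, spec) logit shifts
    p_values: Mapping[str, float]  # outcome -> LRT p-value
    het_explained: Mapping[str, float]  # outcome -> share of tau2 removed
    n_studies: int
    dropped_categories: tuple[str, ...] = ()


@dataclass(frozen=True)
class DeeksResult:
    slope: float
    intercept: float
    p_value: float
    ess: np.ndarray


@dataclass(frozen=True)
class FaganResult:
    pretest: float
    lr: float
    posttest: float


# ---------------------------------------------------------------------------
# normal-approximation (logit) data preparation
# ---------------------------------------------------------------------------


def _logit_data(
    studies: Sequence[StudyRecord], correction: float
) -> tuple[np.ndarray, np.ndarray]:
    """Per-study logits and within-study variances, zero cells corrected.

    The correction is added to *all four* cells of any study containing a
    zero cell (per-study correction, the common DTA convention).
    """
    cells = np.array([[s.tp, s.fp, s.fn, s.tn] for s in studies], dtype=float)
    has_zero = (cells == 0).any(axis=1)
    cells[has_zero] += correction
    tp, fp, fn, tn = cells.T
    if np.any(tp + fn <= 0) or np.any(tn + fp <= 0):
        raise ValueError("every study needs positive case and non-case margins")
    y = np.column_stack([np.log(tp / fn), np.log(tn / fp)])
    s2 = np.column_stack([1.0 / tp + 1.0 / fn, 1.0 / tn + 1.0 / fp])
    return y, s2


def _sigma(tau1: float, tau2: float, rho: float) -> np.ndarray:
    return np.array(
        [[tau1 * tau1, rho * tau1 * tau2], [rho * tau1 * tau2, tau2 * tau2]]
    )


def _gls(
    y: np.ndarray, s2: np.ndarray, X: np.ndarray, tau1: float, tau2: float, rho: float
):
    """Profile the mean out of the bivariate normal-normal likelihood.

    Returns (beta, A, Vinv, logdetV, quad) where A = sum X' Vinv X and quad
    is the weighted residual sum of squares.
    """
    v11 = tau1 * tau1 + s2[:, 0]
    v22 = tau2 * tau2 + s2[:, 1]
    v12 = np.full(len(y), rho * tau1 * tau2)
    det = v11 * v22 - v12 * v12
    Vinv = np.empty((len(y), 2, 2))
    Vinv[:, 0, 0] = v22 / det
    Vinv[:, 1, 1] = v11 / det
    Vinv[:, 0, 1] = Vinv[:, 1, 0] = -v12 / det
    A = np.einsum("nji,njk,nkl->il", X, Vinv, X)
    b = np.einsum("nji,njk,nk->i", X, Vinv, y)
    beta = np.linalg.solve(A, b)
    r = y - np.einsum("nij,j->ni", X, beta)
    quad = float(np.einsum("ni,nij,nj->", r, Vinv, r))
    return beta, A, Vinv, float(np.sum(np.log(det))), quad


def _nll_normal(
    theta: np.ndarray, y: np.ndarray, s2: np.ndarray, X: np.ndarray, reml: bool
) -> float:
    tau1, tau2, rho = theta
    try:
        beta, A, _, logdetV, quad = _gls(y, s2, X, tau1, tau2, rho)
    except np.linalg.LinAlgError:
        return 1e30
    nll = 0.5 * (logdetV + quad)
    if reml:
        sign, logdetA = np.linalg.slogdet(A)
        if sign <= 0:
            return 1e30
        nll += 0.5 * logdetA
    if not np.isfinite(nll):
        return 1e30
    return nll


_STARTS = (
    (0.05, 0.05, 0.0),
    (0.2, 0.2, -0.5),
    (0.2, 0.2, 0.5),
    (0.5, 0.5, -0.5),
    (0.5, 0.5, 0.5),
    (1.0, 1.0, 0.0),
)


def _fit_normal(
    y: np.ndarray,
    s2: np.ndarray,
    X: np.ndarray,
    reml: bool,
    tau2_fixed: Optional[tuple[float, float]] = None,
) -> dict:
    """Maximise the (restricted) bivariate normal likelihood over (tau1, tau2, rho)."""
    if tau2_fixed is not None:
        t1, t2 = math.sqrt(tau2_fixed[0]), math.sqrt(tau2_fixed[1])
        if t1 == 0.0 or t2 == 0.0:
            theta = np.array([t1, t2, 0.0])
            nll = _nll_normal(theta, y, s2, X, reml)
            best = {"theta": theta, "nll": nll, "converged": True}
        else:
            obj = lambda r: _nll_normal(np.array([t1, t2, r[0]]), y, s2, X, reml)
            res = minimize(obj, [0.0], method="L-BFGS-B", bounds=[(-_RHO_CAP, _RHO_CAP)])
            best = {
                "theta": np.array([t1, t2, float(res.x[0])]),
                "nll": float(res.fun),
                "converged": bool(res.success),
            }
    else:
        bounds = [(0.0, _TAU_CAP), (0.0, _TAU_CAP), (-_RHO_CAP, _RHO_CAP)]
        best = None
        for start in _STARTS:
            res = minimize(
                _nll_normal,
                np.array(start),
                args=(y, s2, X, reml),
                method="L-BFGS-B",
                bounds=bounds,
                options={"ftol": 1e-12, "gtol": 1e-8, "maxiter": 500},
            )
            cand = {
                "theta": np.asarray(res.x, dtype=float),
                "nll": float(res.fun),
                "converged": bool(res.success),
            }
            if best is None or cand["nll"] < best["nll"] - 1e-12 or (
                cand["converged"] and not best["converged"] and cand["nll"] <= best["nll"] + 1e-9
            ):
                best = cand
    tau1, tau2, rho = best["theta"]
    beta, A, Vinv, _, _ = _gls(y, s2, X, tau1, tau2, rho)
    best.update(beta=beta, A=A, Vinv=Vinv)
    return best


def _hessian_cov(f, theta: np.ndarray, bounds_lo: np.ndarray) -> Optional[np.ndarray]:
    """Covariance from a central finite-difference Hessian; None when unstable."""
    k = len(theta)
    h = np.maximum(1e-4, 1e-3 * np.abs(theta))
    # step inside the boundary for parameters at their floor
    theta = np.maximum(theta, bounds_lo + 2 * h)
    H = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k)
            ej = np.zeros(k)
            ei[i] = h[i]
            ej[j] = h[j]
            if i == j:
                H[i, i] = (f(theta + ei) - 2 * f(theta) + f(theta - ei)) / h[i] ** 2
            else:
                H[i, j] = H[j, i] = (
                    f(theta + ei + ej)
                    - f(theta + ei - ej)
                    - f(theta - ei + ej)
                    + f(theta - ei - ej)
                ) / (4 * h[i] * h[j])
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return None
    if np.any(np.diag(cov) <= 0):
        return None
    return cov


def _hessian_se(f, theta: np.ndarray, bounds_lo: np.ndarray) -> np.ndarray:
    cov = _hessian_cov(f, theta, bounds_lo)
    if cov is None:
        return np.full(len(theta), math.nan)
    return np.sqrt(np.diag(cov))


def fit_bivariate(
    studies: Sequence[StudyRecord],
    method: str = "reml_normal",
    correction: float = 0.5,
    tau2_fixed: Optional[tuple[float, float]] = None,
) -> BivariateFit:
    """Fit the bivariate random-effects model to a set of studies.

    ``method='reml_normal'`` (default): logit-normal approximation, REML.
    ``method='ml_binomial'``: exact binomial within-study likelihood,
    integrated by adaptive Gauss-Hermite quadrature (21 nodes/dimension),
    maximum likelihood.

    ``correction`` is added to all four cells of any study containing a
    zero cell before logit transformation (normal method only; the binomial
    likelihood needs no correction).  ``tau2_fixed`` pins the between-study
    variances (e.g. ``(0, 0)`` gives fixed-effect inverse-variance pooling).
    """
    usable = [s for s in studies if s.tp + s.fn > 0 or correction > 0]
    if len(usable) < 2:
        raise ValueError("need at least 2 usable studies")
    if method == "reml_normal":
        return _fit_bivariate_normal(usable, correction, tau2_fixed)
    if method == "ml_binomial":
        return _fit_bivariate_binomial(usable)
    raise ValueError(f"unknown method {method!r}")


def _fit_bivariate_normal(
    studies: Sequence[StudyRecord],
    correction: float,
    tau2_fixed: Optional[tuple[float, float]],
) -> BivariateFit:
    y, s2 = _logit_data(studies, correction)
    X = np.broadcast_to(np.eye(2), (len(y), 2, 2))
    res = _fit_normal(y, s2, X, reml=True, tau2_fixed=tau2_fixed)
    tau1, tau2, rho = res["theta"]
    if not res["converged"]:
        fit = _build_fit(res, y, s2, X, len(studies), "reml_normal", converged=False)
        raise ConvergenceError("bivariate REML did not converge from any start", fit)
    return _build_fit(res, y, s2, X, len(studies), "reml_normal")


def _build_fit(res, y, s2, X, n, method, converged=True) -> BivariateFit:
    tau1, tau2, rho = res["theta"]
    ses = (
        _hessian_se(
            lambda th: _nll_normal(th, y, s2, X, True),
            res["theta"],
            np.array([0.0, 0.0, -_RHO_CAP]),
        )
        if n > 2
        else np.full(3, math.nan)
    )
    mu_cov = np.linalg.inv(res["A"])
    beta = res["beta"]
    return BivariateFit(
        mu_sens=float(beta[0]),
        mu_spec=float(beta[1]),
        tau2_sens=float(tau1**2),
        tau2_spec=float(tau2**2),
        rho=float(rho) if (tau1 > 0 and tau2 > 0) else 0.0,
        loglik=-res["nll"],
        n_studies=n,
        method=method,
        mu_cov=mu_cov,
        tau_sens_se=float(ses[0]),
        tau_spec_se=float(ses[1]),
        rho_se=float(ses[2]),
        converged=converged,
    )


# ---------------------------------------------------------------------------
# exact binomial likelihood via adaptive Gauss-Hermite quadrature
# ---------------------------------------------------------------------------

_GH_NODES = 21


def _nll_binomial(theta: np.ndarray, data: dict) -> float:
    """Negative marginal log-likelihood of the binomial bivariate model.

    Per study the two binomial likelihoods are integrated over the bivariate
    normal random effect with Gauss-Hermite quadrature adaptively centred at
    the per-study posterior mode and scaled by the Laplace curvature.
    """
    mu1, mu2, tau1, tau2, rho = theta
    Sigma = _sigma(tau1, tau2, rho)
    det = np.linalg.det(Sigma)
    if det <= 1e-12:
        return 1e30
    Sinv = np.linalg.inv(Sigma)
    x, fn_, tn, fp = data["tp"], data["fn"], data["tn"], data["fp"]
    n1, n2 = x + fn_, tn + fp
    mu = np.array([mu1, mu2])

    # Newton iterations (vectorised over studies) for the mode of
    # log f(eta) = binom loglik + log-normal prior.
    eta = np.column_stack(
        [np.log((x + 0.5) / (fn_ + 0.5)), np.log((tn + 0.5) / (fp + 0.5))]
    )
    for _ in range(50):
        p1, p2 = expit(eta[:, 0]), expit(eta[:, 1])
        d = eta - mu
        g = np.column_stack([x - n1 * p1, tn - n2 * p2]) - d @ Sinv
        w1, w2 = n1 * p1 * (1 - p1), n2 * p2 * (1 - p2)
        # H = -(diag(w) + Sinv); solve H^{-1} g analytically (2x2)
        a = w1 + Sinv[0, 0]
        c = w2 + Sinv[1, 1]
        b = np.full_like(a, Sinv[0, 1])
        detH = a * c - b * b
        step1 = (c * g[:, 0] - b * g[:, 1]) / detH
        step2 = (a * g[:, 1] - b * g[:, 0]) / detH
        eta[:, 0] += step1
        eta[:, 1] += step2
        if max(np.abs(step1).max(), np.abs(step2).max()) < 1e-10:
            break
    p1, p2 = expit(eta[:, 0]), expit(eta[:, 1])
    a = n1 * p1 * (1 - p1) + Sinv[0, 0]
    c = n2 * p2 * (1 - p2) + Sinv[1, 1]
    b = np.full_like(a, Sinv[0, 1])
    detH = a * c - b * b
    if np.any(detH <= 0):
        return 1e30
    # L = chol((-H)^{-1}): inverse of [[a,b],[b,c]] is [[c,-b],[-b,a]]/detH
    m11, m12, m22 = c / detH, -b / detH, a / detH
    L11 = np.sqrt(m11)
    L21 = m12 / L11
    L22 = np.sqrt(np.maximum(m22 - L21**2, 1e-300))
    logdetL = np.log(L11) + np.log(L22)

    z, zlw = data["gh_nodes"], data["gh_logw"]  # (k,2), (k,)
    # eta_grid[i, j, :] = eta*_i + sqrt(2) L_i z_j
    sq2 = math.sqrt(2.0)
    e1 = eta[:, None, 0] + sq2 * L11[:, None] * z[None, :, 0]
    e2 = eta[:, None, 1] + sq2 * (
        L21[:, None] * z[None, :, 0] + L22[:, None] * z[None, :, 1]
    )
    q1, q2 = expit(e1), expit(e2)
    with np.errstate(divide="ignore", invalid="ignore"):
        ll_bin = (
            x[:, None] * np.log(q1)
            + fn_[:, None] * np.log1p(-q1)
            + tn[:, None] * np.log(q2)
            + fp[:, None] * np.log1p(-q2)
        )
    ll_bin = np.where(np.isnan(ll_bin), -np.inf, ll_bin)
    d1, d2 = e1 - mu1, e2 - mu2
    ll_prior = -0.5 * (
        Sinv[0, 0] * d1 * d1 + 2 * Sinv[0, 1] * d1 * d2 + Sinv[1, 1] * d2 * d2
    ) - 0.5 * math.log((2 * math.pi) ** 2 * det)
    logI = (
        math.log(2.0)
        + logdetL
        + logsumexp(ll_bin + ll_prior + (zlw + z[:, 0] ** 2 + z[:, 1] ** 2)[None, :], axis=1)
    )
    const = float(
        np.sum(
            gammaln(n1 + 1) - gammaln(x + 1) - gammaln(fn_ + 1)
            + gammaln(n2 + 1) - gammaln(tn + 1) - gammaln(fp + 1)
        )
    )
    nll = -(float(np.sum(logI)) + const)
    return nll if np.isfinite(nll) else 1e30


def _fit_bivariate_binomial(studies: Sequence[StudyRecord]) -> BivariateFit:
    xg, wg = np.polynomial.hermite.hermgauss(_GH_NODES)
    zz1, zz2 = np.meshgrid(xg, xg, indexing="ij")
    data = {
        "tp": np.array([s.tp for s in studies], float),
        "fn": np.array([s.fn for s in studies], float),
        "tn": np.array([s.tn for s in studies], float),
        "fp": np.array([s.fp for s in studies], float),
        "gh_nodes": np.column_stack([zz1.ravel(), zz2.ravel()]),
        "gh_logw": (np.log(wg)[:, None] + np.log(wg)[None, :]).ravel(),
    }
    # warm-start from the REML normal fit
    try:
        warm = _fit_bivariate_normal(studies, 0.5, None)
        starts = [
            np.array(
                [
                    warm.mu_sens,
                    warm.mu_spec,
                    max(math.sqrt(warm.tau2_sens), 0.05),
                    max(math.sqrt(warm.tau2_spec), 0.05),
                    warm.rho,
                ]
            )
        ]
    except ConvergenceError as err:  # pragma: no cover - defensive
        f = err.best_fit
        starts = [np.array([f.mu_sens, f.mu_spec, 0.2, 0.2, 0.0])]
    y, _ = _logit_data(studies, 0.5)
    m = y.mean(axis=0)
    starts += [
        np.array([m[0], m[1], 0.2, 0.2, 0.0]),
        np.array([m[0], m[1], 0.5, 0.5, -0.3]),
        np.array([m[0], m[1], 0.05, 0.05, 0.0]),
        np.array([m[0], m[1], 1.0, 1.0, 0.3]),
    ]
    bounds = [(-10, 10), (-10, 10), (1e-3, _TAU_CAP), (1e-3, _TAU_CAP), (-_RHO_CAP, _RHO_CAP)]
    best = None
    for s0 in starts:
        s0 = np.clip(s0, [b[0] for b in bounds], [b[1] for b in bounds])
        res = minimize(
            _nll_binomial,
            s0,
            args=(data,),
            method="L-BFGS-B",
            bounds=bounds,
            options={"ftol": 1e-11, "gtol": 1e-7, "maxiter": 400},
        )
        if best is None or res.fun < best.fun:
            best = res
    mu1, mu2, tau1, tau2, rho = best.x
    cov5 = _hessian_cov(
        lambda th: _nll_binomial(th, data),
        best.x,
        np.array([-10.0, -10.0, 1e-3, 1e-3, -_RHO_CAP]),
    )
    if cov5 is None:
        ses = np.full(5, math.nan)
        mu_cov = np.full((2, 2), math.nan)
    else:
        ses = np.sqrt(np.diag(cov5))
        mu_cov = cov5[:2, :2]
    fit = BivariateFit(
        mu_sens=float(mu1),
        mu_spec=float(mu2),
        tau2_sens=float(tau1**2),
        tau2_spec=float(tau2**2),
        rho=float(rho),
        loglik=-float(best.fun),
        n_studies=len(studies),
        method="ml_binomial",
        mu_cov=mu_cov,
        tau_sens_se=float(ses[2]),
        tau_spec_se=float(ses[3]),
        rho_se=float(ses[4]),
        converged=bool(best.success),
    )
    if not best.success:
        raise ConvergenceError("binomial ML did not converge from any start", fit)
    return fit


# ---------------------------------------------------------------------------
# summaries of a fitted model
# ---------------------------------------------------------------------------


def summarize_bivariate(
    fit: BivariateFit,
    level: float = 0.95,
    bootstrap: int = 0,
    seed: Optional[int] = None,
) -> PooledAccuracy:
    """Pooled sensitivity/specificity and plug-in pooled likelihood ratios.

    Pooled proportions are inverse-logits of the fitted means with Wald
    intervals on the logit scale.  The LRs are evaluated at the pooled
    proportions; their intervals come from the delta method on the log-LR
    scale using the covariance of (mu_sens, mu_spec).  ``bootstrap > 0``
    replaces the delta-method LR intervals with percentile intervals from
    that many parametric draws of mu (a cross-check option).
    """
    z = norm.ppf(0.5 + level / 2.0)
    se = np.sqrt(np.diag(fit.mu_cov))
    if not np.all(np.isfinite(se)) or np.any(se < 0):
        raise ValueError("degenerate mu covariance; refit or bootstrap manually")
    sens = fit.pooled_sensitivity
    spec = fit.pooled_specificity
    sens_ci = Interval(
        float(expit(fit.mu_sens - z * se[0])), float(expit(fit.mu_sens + z * se[0])), level
    )
    spec_ci = Interval(
        float(expit(fit.mu_spec - z * se[1])), float(expit(fit.mu_spec + z * se[1])), level
    )
    lr_pos = sens / (1.0 - spec)
    lr_neg = (1.0 - sens) / spec
    if bootstrap > 0:
        rng = np.random.default_rng(seed)
        draws = rng.multivariate_normal(
            [fit.mu_sens, fit.mu_spec], fit.mu_cov, size=bootstrap
        )
        s_d, c_d = expit(draws[:, 0]), expit(draws[:, 1])
        lp = s_d / (1.0 - c_d)
        ln = (1.0 - s_d) / c_d
        a = (1.0 - level) / 2.0
        lr_pos_ci = Interval(*np.quantile(lp, [a, 1 - a]).tolist(), level)
        lr_neg_ci = Interval(*np.quantile(ln, [a, 1 - a]).tolist(), level)
    else:
        # gradients of log LR w.r.t. (mu_sens, mu_spec)
        g_pos = np.array([1.0 - sens, spec])
        g_neg = np.array([-sens, -(1.0 - spec)])
        se_pos = math.sqrt(float(g_pos @ fit.mu_cov @ g_pos))
        se_neg = math.sqrt(float(g_neg @ fit.mu_cov @ g_neg))
        lr_pos_ci = Interval(
            lr_pos * math.exp(-z * se_pos), lr_pos * math.exp(z * se_pos), level
        )
        lr_neg_ci = Interval(
            lr_neg * math.exp(-z * se_neg), lr_neg * math.exp(z * se_neg), level
        )
    return PooledAccuracy(
        sensitivity=sens,
        specificity=spec,
        sensitivity_ci=sens_ci,
        specificity_ci=spec_ci,
        lr_pos=lr_pos,
        lr_neg=lr_neg,
        lr_pos_ci=lr_pos_ci,
        lr_neg_ci=lr_neg_ci,
        level=level,
    )


def sroc_curve(fit: BivariateFit, grid_size: int = 1000) -> SROC:
    """Summary ROC curve induced by the bivariate parameters.

    Uses the accuracy/threshold reparameterisation (Harbord):
    beta = ln(tau_spec / tau_sens), Lambda = sqrt(tau_spec/tau_sens) mu_sens
    + sqrt(tau_sens/tau_spec) mu_spec, giving the curve
    sens(FPR) = expit(Lambda e^{-beta/2} + e^{-beta} logit(FPR)).
    AUC by trapezoidal integration over the full (0, 1) FPR range.
    """
    summary = (1.0 - fit.pooled_specificity, fit.pooled_sensitivity)
    if fit.tau2_sens + fit.tau2_spec <= 1e-10:
        warnings.warn("no between-study variance: sROC degenerates to the summary point")
        return SROC(
            curve=np.array([summary]), auc=None, summary_point=summary, degenerate=True
        )
    t1 = max(math.sqrt(fit.tau2_sens), 1e-6)
    t2 = max(math.sqrt(fit.tau2_spec), 1e-6)
    beta = math.log(t2 / t1)
    lam = math.sqrt(t2 / t1) * fit.mu_sens + math.sqrt(t1 / t2) * fit.mu_spec
    eps = 1e-9
    fpr = np.concatenate([[eps], np.linspace(0.0, 1.0, grid_size + 2)[1:-1], [1 - eps]])
    sens = expit(lam * math.exp(-beta / 2.0) + math.exp(-beta) * logit(fpr))
    grid = np.concatenate([[0.0], fpr, [1.0]])
    vals = np.concatenate([[sens[0]], sens, [sens[-1]]])
    auc = float(np.trapezoid(vals, grid))
    curve = np.column_stack([fpr, sens])
    return SROC(curve=curve, auc=auc, summary_point=summary, degenerate=False)


# ---------------------------------------------------------------------------
# proportion pooling and heterogeneity
# ---------------------------------------------------------------------------


def heterogeneity(
    values: Sequence[float], variances: Sequence[float]
) -> HeterogeneityResult:
    """Cochran's Q under fixed-effect weights, and I^2 = max(0, (Q-df)/Q)."""
    values = np.asarray(values, float)
    variances = np.asarray(variances, float)
    if len(values) < 2:
        raise ValueError("need >= 2 studies")
    if np.any(variances <= 0):
        raise ValueError("variances must be positive")
    w = 1.0 / variances
    mean = float(np.sum(w * values) / np.sum(w))
    q = float(np.sum(w * (values - mean) ** 2))
    df = len(values) - 1
    i2 = max(0.0, (q - df) / q) if q > 0 else 0.0
    p = float(chi2.sf(q, df))
    return HeterogeneityResult(q=q, df=df, i2=i2, p_value=p)


def pool_proportion(
    events: Sequence[int],
    denoms: Sequence[int],
    scale: str = "proportion",
    level: float = 0.95,
) -> PooledProportion:
    """Random-effects pooling of single proportions on the logit scale.

    DerSimonian-Laird between-study variance; 0.5 continuity correction for
    studies at the 0 or 100% boundary; I^2 from the fixed-effect Q of the
    logit-scale estimates.  ``scale='per_1000'`` multiplies the
    back-transformed estimate and interval by 1000 (detection rates).
    """
    events = np.asarray(events, float)
    denoms = np.asarray(denoms, float)
    if events.shape != denoms.shape:
        raise ValueError("events and denoms must have equal length")
    if np.any(denoms <= 0):
        raise ValueError("denominators must be > 0")
    if np.any(events < 0) or np.any(events > denoms):
        raise ValueError("events must lie in [0, denom]")
    mult = 1000.0 if scale == "per_1000" else 1.0
    if scale not in ("proportion", "per_1000"):
        raise ValueError(f"unknown scale {scale!r}")
    k = len(events)
    if np.all(events == 0):
        upper = proportion_ci(0, int(denoms.sum()), level, "clopper_pearson").upper
        return PooledProportion(
            estimate=0.0,
            interval=Interval(0.0, upper * mult, level),
            tau2=0.0,
            i2=0.0,
            scale=scale,
            all_zero=True,
        )
    if k == 1:
        p = float(events[0] / denoms[0])
        ci = proportion_ci(int(events[0]), int(denoms[0]), level)
        return PooledProportion(
            estimate=p * mult,
            interval=Interval(ci.lower * mult, ci.upper * mult, level),
            tau2=0.0,
            i2=0.0,
            scale=scale,
        )
    e = events.copy()
    n = denoms.copy()
    boundary = (e == 0) | (e == n)
    e[boundary] += 0.5
    n[boundary] += 1.0
    y = np.log(e / (n - e))
    v = 1.0 / e + 1.0 / (n - e)
    w = 1.0 / v
    mean_fe = np.sum(w * y) / np.sum(w)
    q = float(np.sum(w * (y - mean_fe) ** 2))
    df = k - 1
    s1 = np.sum(w)
    s2 = np.sum(w**2)
    tau2 = max(0.0, (q - df) / (s1 - s2 / s1))
    w_re = 1.0 / (v + tau2)
    mu = float(np.sum(w_re * y) / np.sum(w_re))
    se = math.sqrt(1.0 / float(np.sum(w_re)))
    z = norm.ppf(0.5 + level / 2.0)
    i2 = max(0.0, (q - df) / q) if q > 0 else 0.0
    return PooledProportion(
        estimate=float(expit(mu)) * mult,
        interval=Interval(
            float(expit(mu - z * se)) * mult, float(expit(mu + z * se)) * mult, level
        ),
        tau2=float(tau2),
        i2=float(i2),
        scale=scale,
    )


# ---------------------------------------------------------------------------
# meta-regression
# ---------------------------------------------------------------------------


def _design(
    n: int, cat_idx: np.ndarray, n_cat: int, on_sens: bool, on_spec: bool
) -> np.ndarray:
    """Block design: intercepts for both outcomes plus reference-coded
    category shifts on the selected outcome(s)."""
    p = 2 + (n_cat - 1) * (int(on_sens) + int(on_spec))
    X = np.zeros((n, 2, p))
    X[:, 0, 0] = 1.0
    X[:, 1, 1] = 1.0
    col = 2
    if on_sens:
        for c in range(1, n_cat):
            X[cat_idx == c, 0, col] = 1.0
            col += 1
    if on_spec:
        for c in range(1, n_cat):
            X[cat_idx == c, 1, col] = 1.0
            col += 1
    return X


def meta_regression(
    studies: Sequence[StudyRecord],
    covariate: str,
    correction: float = 0.5,
) -> MetaRegressionResult:
    """Bivariate meta-regression on one categorical covariate.

    The covariate enters as category indicators on both the sensitivity and
    specificity means.  Per-outcome p-values come from likelihood-ratio
    tests (ML fits) of the covariate on that outcome against the
    covariate-free model; the share of between-study heterogeneity
    explained per outcome is the relative reduction in the REML tau^2
    (clipped to [0, 1]).  Categories with fewer than 2 studies are dropped
    with a warning.
    """
    values = []
    for s in studies:
        if covariate not in s.covariates:
            raise ValueError(f"study {s.study_id!r} lacks covariate {covariate!r}")
        values.append(str(s.covariates[covariate]))
    cats, counts = np.unique(values, return_counts=True)
    dropped = tuple(str(c) for c in cats[counts < 2])
    keep_cats = [str(c) for c in cats if str(c) not in dropped]
    if dropped:
        warnings.warn(f"dropping singleton categories {dropped!r} for {covariate!r}")
    if len(keep_cats) < 2:
        raise ValueError("need >= 2 categories each with >= 2 studies")
    kept = [s for s, v in zip(studies, values) if v in keep_cats]
    vals = [v for v in values if v in keep_cats]
    cat_idx = np.array([keep_cats.index(v) for v in vals])
    n_cat = len(keep_cats)

    y, s2 = _logit_data(kept, correction)
    n = len(kept)
    X_null = _design(n, cat_idx, n_cat, False, False)
    X_full = _design(n, cat_idx, n_cat, True, True)
    X_sens = _design(n, cat_idx, n_cat, True, False)
    X_spec = _design(n, cat_idx, n_cat, False, True)

    ml_null = _fit_normal(y, s2, X_null, reml=False)
    ml_sens = _fit_normal(y, s2, X_sens, reml=False)
    ml_spec = _fit_normal(y, s2, X_spec, reml=False)
    df = n_cat - 1
    p_sens = float(chi2.sf(max(0.0, 2.0 * (ml_null["nll"] - ml_sens["nll"])), df))
    p_spec = float(chi2.sf(max(0.0, 2.0 * (ml_null["nll"] - ml_spec["nll"])), df))

    reml_null = _fit_normal(y, s2, X_null, reml=True)
    reml_full = _fit_normal(y, s2, X_full, reml=True)
    tau2_null = reml_null["theta"][:2] ** 2
    tau2_full = reml_full["theta"][:2] ** 2
    het = {}
    for i, outcome in enumerate(("sensitivity", "specificity")):
        if tau2_null[i] <= 0:
            het[outcome] = 0.0
        else:
            het[outcome] = float(
                np.clip((tau2_null[i] - tau2_full[i]) / tau2_null[i], 0.0, 1.0)
            )
    beta = reml_full["beta"]
    coefficients = {}
    for j, c in enumerate(keep_cats[1:], start=0):
        coefficients[c] = (float(beta[2 + j]), float(beta[2 + (n_cat - 1) + j]))
    return MetaRegressionResult(
        covariate=covariate,
        reference=keep_cats[0],
        coefficients=coefficients,
        p_values={"sensitivity": p_sens, "specificity": p_spec},
        het_explained=het,
        n_studies=n,
        dropped_categories=dropped,
    )


# ---------------------------------------------------------------------------
# small-study effects and Fagan arithmetic
# ---------------------------------------------------------------------------


def deeks_test(studies: Sequence[StudyRecord]) -> DeeksResult:
    """Deeks' funnel-plot asymmetry test for DTA meta-analysis.

    Weighted least squares of ln DOR on 1/sqrt(ESS) with weights ESS, where
    ESS = 4 n_dis n_nondis / n is the effective sample size; the two-sided
    t-test on the slope indicates small-study effects.  Zero cells get a
    0.5 correction (all four cells of the affected study).
    """
    if len(studies) < 3:
        raise ValueError("need >= 3 studies")
    cells = np.array([[s.tp, s.fp, s.fn, s.tn] for s in studies], dtype=float)
    has_zero = (cells == 0).any(axis=1)
    cells[has_zero] += 0.5
    tp, fp, fn_, tn = cells.T
    n1 = tp + fn_
    n2 = fp + tn
    ntot = n1 + n2
    if np.any(n1 <= 0) or np.any(n2 <= 0):
        raise ValueError("every study needs positive margins")
    ess = 4.0 * n1 * n2 / ntot
    ln_dor = np.log(tp * tn / (fp * fn_))
    x = 1.0 / np.sqrt(ess)
    if np.ptp(x) < 1e-12:
        # all effective sample sizes equal: no asymmetry is estimable
        return DeeksResult(
            slope=0.0,
            intercept=float(np.average(ln_dor, weights=ess)),
            p_value=1.0,
            ess=ess,
        )
    import statsmodels.api as sm

    Xmat = sm.add_constant(x)
    res = sm.WLS(ln_dor, Xmat, weights=ess).fit()
    return DeeksResult(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        p_value=float(res.pvalues[1]),
        ess=ess,
    )


def fagan_posttest(pretest: float, lr: float) -> FaganResult:
    """Bayes' theorem in odds form: posttest odds = pretest odds x LR."""
    if not 0.0 < pretest < 1.0:
        raise ValueError("pretest probability must lie strictly in (0, 1)")
    if lr <= 0:
        raise ValueError("likelihood ratio must be positive")
    odds = pretest / (1.0 - pretest) * lr
    return FaganResult(pretest=pretest, lr=lr, posttest=odds / (1.0 + odds))
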