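"""Random variance model: empirical-Bayes moderation of per-gene variances.

Model: each gene's residual precision 1/sigma^2 is drawn from a
Gamma(shape=a, scale=b) distribution.  Under this model the observed
residual variance s^2 on m degrees of freedom satisfies the identity

    a * b * s^2  ~  F(m, 2a)

which is what :func:`fit_rvm` maximises the likelihood of.  The derived,
user-facing parameterization is prior degrees of freedom nu0 = 2a and
prior variance s0^2 = 1/(a*b); the shrunken variance is the usual
precision-weighted blend

    s_tilde^2 = (m*s^2 + nu0*s0^2) / (m + nu0)

and the moderated F statistic gains nu0 denominator degrees of freedom.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import optimize, stats

log = logging.getLogger("polyapv.rvm")

A_UPPER_BOUND = 1e6  # finite stand-in for "complete shrinkage"
MIN_GENES = 50


class RvmError(RuntimeError):
    pass


class RvmConvergenceError(RvmError):
    """Optimizer failed; carries the optimizer result as ``trace``."""

    def __init__(self, message: str, trace=None):
        super().__init__(message)
        self.trace = trace


@dataclass(frozen=True)
class RvmParams:
    """Fitted hyperparameters of the gamma prior on precisions."""

    a: float
    b: float
    fit_loglik: float = float("nan")
    n_genes_fit: int = 0
    converged: bool = True

    def __post_init__(self):
        if not (self.a > 0 and self.b > 0):
            raise ValueError(f"a and b must be positive, got a={self.a} b={self.b}")

    @property
    def nu0(self) -> float:
        return 2.0 * self.a

    @property
    def s0_sq(self) -> float:
        return 1.0 / (self.a * self.b)

    @staticmethod
    def from_prior(nu0: float, s0_sq: float) -> "RvmParams":
        """Build from the (prior df, prior variance) parameterization.

        nu0 = 0 encodes "no moderation" and is represented by a -> 0 limit;
        it is handled explicitly by the moderation functions.
        """
        if nu0 == 0:
            return RvmParams(a=np.finfo(float).tiny, b=1.0 / np.finfo(float).tiny)
        a = nu0 / 2.0
        b = 1.0 / (a * s0_sq)
        return RvmParams(a=a, b=b)


def _loglik(s_sq: np.ndarray, m: int, a: float, b: float) -> float:
    """Sum of log densities of s^2 under a*b*s^2 ~ F(m, 2a)."""
    ab = a * b
    return float(np.sum(stats.f.logpdf(ab * s_sq, m, 2.0 * a) + np.log(ab)))


def _moment_init(s_sq: np.ndarray, m: int) -> tuple[float, float]:
    """Method-of-moments start for (a, b) from the mean/variance of s^2."""
    mu = float(np.mean(s_sq))
    v = float(np.var(s_sq, ddof=1))
    if mu <= 0 or v <= 0:
        return 3.0, 1.0 / (3.0 * mu) if mu > 0 else (3.0, 1.0)
    r = v / mu**2
    denom = r - 2.0 / m
    if denom <= 1e-12:
        a0 = 100.0  # very light-tailed: large shape
    else:
        a0 = (2.0 * r + 1.0 - 2.0 / m) / denom
        a0 = min(max(a0, 2.2), 1e4)
    b0 = 1.0 / (mu * (a0 - 1.0))
    return a0, max(b0, 1e-12)


def fit_rvm(
    residual_variances: np.ndarray,
    m: int,
    init: Optional[tuple[float, float]] = None,
) -> RvmParams:
    """Maximum-likelihood fit of (a, b) on per-gene residual variances.

    Non-positive or non-finite variances are excluded (counted in the
    log).  At least :data:`MIN_GENES` usable genes are required.  When the
    variances are (numerically) all identical the fit degenerates to
    complete shrinkage: a is pinned at its upper bound with s0^2 equal to
    the common value.
    """
    s_sq = np.asarray(residual_variances, dtype=float).ravel()
    usable = np.isfinite(s_sq) & (s_sq > 0)
    n_dropped = int((~usable).sum())
    if n_dropped:
        log.info("fit_rvm: excluded %d gene(s) with non-positive or "
                 "non-finite variance", n_dropped)
    s_sq = s_sq[usable]
    if s_sq.size < MIN_GENES:
        raise RvmError(
            f"need >= {MIN_GENES} genes with positive finite variance to fit "
            f"the RVM, got {s_sq.size}"
        )
    if m < 1:
        raise RvmError(f"residual df must be >= 1, got {m}")

    if np.var(s_sq) < 1e-30 * max(1.0, float(np.mean(s_sq)) ** 2):
        c = float(np.mean(s_sq))
        a = A_UPPER_BOUND
        b = 1.0 / (a * c)  # s0^2 == c -> complete shrinkage to c
        log.warning("fit_rvm: variances are constant; returning complete "
                    "shrinkage toward %.6g", c)
        return RvmParams(a=a, b=b, fit_loglik=_loglik(s_sq, m, a, b),
                         n_genes_fit=s_sq.size, converged=True)

    a0, b0 = init if init is not None else _moment_init(s_sq, m)
    x0 = np.log([a0, b0])

    def nll(x: np.ndarray) -> float:
        a, b = np.exp(x)
        if not np.isfinite(a) or not np.isfinite(b):
            return np.inf
        return -_loglik(s_sq, m, a, b)

    bounds = [(np.log(1e-6), np.log(A_UPPER_BOUND)), (np.log(1e-12), np.log(1e12))]
    res = optimize.minimize(
        nll, x0, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8},
    )
    if not res.success or not np.isfinite(res.fun):
        # one retry from a neutral start before giving up
        res2 = optimize.minimize(
            nll, np.log([3.0, 1.0 / (3.0 * np.mean(s_sq))]),
            method="Nelder-Mead",
            options={"maxiter": 2000, "xatol": 1e-10, "fatol": 1e-12},
        )
        if res2.success and np.isfinite(res2.fun) and res2.fun <= res.fun:
            res = res2
        elif not np.isfinite(res.fun):
            raise RvmConvergenceError(
                f"RVM optimizer failed: {res.message}", trace=res
            )
    a, b = np.exp(res.x)
    params = RvmParams(
        a=float(a), b=float(b), fit_loglik=float(-res.fun),
        n_genes_fit=int(s_sq.size), converged=bool(res.success),
    )
    log.info("fit_rvm: a=%.4g b=%.4g (nu0=%.4g s0^2=%.4g) on %d genes, "
             "loglik=%.4f", params.a, params.b, params.nu0, params.s0_sq,
             params.n_genes_fit, params.fit_loglik)
    return params


def moderate_variance(
    s_sq: "float | np.ndarray", m: int, params: RvmParams
) -> "float | np.ndarray":
    """Shrunken variance (m*s^2 + nu0*s0^2) / (m + nu0).

    nu0 may overflow-free dominate (complete shrinkage); with nu0 == 0 the
    observed variance is returned unchanged.
    """
    nu0, s0 = params.nu0, params.s0_sq
    if nu0 == 0:
        return s_sq
    return (m * np.asarray(s_sq, dtype=float) + nu0 * s0) / (m + nu0)


def moderated_f(
    ss_effect: "float | np.ndarray",
    df1: int,
    s_tilde_sq: "float | np.ndarray",
    m: int,
    params: RvmParams,
) -> tuple[np.ndarray, np.ndarray]:
    """Moderated F = (ss_effect/df1) / s_tilde^2 with (df1, m + nu0) df.

    A zero moderated variance yields an infinite-F sentinel with p = 0
    (logged).  With nu0 = 0 this is the classical test.
    """
    if df1 < 1:
        raise ValueError(f"df1 must be >= 1, got {df1}")
    ss = np.asarray(ss_effect, dtype=float)
    st = np.asarray(s_tilde_sq, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        f_stat = (ss / df1) / st
    zero_var = st == 0
    if np.any(zero_var):
        log.warning("moderated_f: %d gene(s) with zero moderated variance; "
                    "p set to 0", int(np.sum(zero_var)))
        f_stat = np.where(zero_var, np.inf, f_stat)
    df2 = m + params.nu0
    p = stats.f.sf(f_stat, df1, df2)
    # F == 0 must give exactly p = 1
    p = np.where(f_stat == 0, 1.0, p)
    return f_stat, p
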