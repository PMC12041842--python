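"""REML estimation of the variance components (tau_alpha2[, tau_gamma2], sigma_w2).

The restricted likelihood is profiled over the residual variance: writing the
covariance blocks as ``sigma_w2 * C(phi)`` with variance ratios
``phi = (tau_alpha2/sigma_w2, tau_gamma2/sigma_w2)``, the restricted
log-likelihood at the profiled ``sigma_w2_hat = Q/(n-p)`` is

    -2 lr(phi) = (n-p) log(2 pi) + sum_i log|C_i| + log|Z' C^-1 Z|
                 + (n-p) log(Q/(n-p)) + (n-p)

where ``Q = r' C^-1 r`` at the GLS coefficients for that ``phi``.  Because
the design is constant within cluster-period cells, one evaluation is O(I)
vector arithmetic on the per-cluster sufficient statistics.

The ratios are optimized on the log scale (1-d bounded search for the
exchangeable model; Nelder-Mead with three fixed starts for the
nested-exchangeable model) and compared against the boundary candidates with
each ratio pinned to zero; ratios below ``exp(-12)`` are projected to an
exact zero and flagged as boundary estimates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .core_data import PBCRTData, ClusterStats
from .closed_form_estimators import EstimationError
from .gls_estimators import VarianceComponents, _inverse_terms, _gls_fit_stats

__all__ = ["REMLFit", "reml_estimate", "reml_loglik"]

_P = 3  # fixed-effect parameters: mu, delta, phi1
_ZERO_RATIO = math.exp(-12.0)
_LOG_LO, _LOG_HI = -18.0, 6.0

#: fixed multistart points in (log phi_alpha, log phi_gamma) ratio space
_NM_STARTS = ((-3.0, -4.6), (-1.2, -2.3), (-5.3, -5.3))


@dataclass
class REMLFit:
    """A converged (or boundary/flagged) REML fit."""

    vc: VarianceComponents
    theta_hat: np.ndarray  # (mu, delta, phi1) GLS coefficients at the optimum
    loglik: float
    converged: bool = True
    boundary: bool = False
    structure: str = "NEME"
    n_evals: int = 0


class _Profile:
    """Precomputed per-cluster context for fast profiled-objective evaluations.

    Everything data-dependent is cached once; each objective evaluation is a
    handful of length-I vector operations plus one 3x3 solve.
    """

    def __init__(self, st: ClusterStats):
        self.K = st.k0.astype(float)
        self.S = st.seq.astype(float)
        self.sum0 = st.sum0
        self.sum1 = st.sum1
        self.ss = float(np.sum(st.ss0 + st.ss1))
        self.n = st.n
        self.npp = st.n - _P

    def neg2(self, phi_w: float, phi_b: float) -> float:
        K, S = self.K, self.S
        lam_p = 1.0 + K * (phi_w + phi_b)
        lam_m = 1.0 + K * (phi_w - phi_b)
        if np.any(lam_m <= 0) or np.any(lam_p <= 0):
            return np.inf
        det = lam_p * lam_m
        b = ((1.0 + K * phi_w) / det - 1.0) / K
        c = -phi_b / det
        u = 1.0 + K * b  # within-period row sum of C^-1
        v = K * c
        cu = K * u
        s01 = K * v
        cus = cu + s01
        M = np.empty((3, 3))
        M[0, 0] = 2.0 * cus.sum()
        M[0, 1] = M[1, 0] = float(cus @ S)
        M[0, 2] = M[2, 0] = cus.sum()
        M[1, 1] = M[1, 2] = M[2, 1] = float(cu @ S)
        M[2, 2] = cu.sum()
        q0 = u * self.sum0 + v * self.sum1
        q1 = u * self.sum1 + v * self.sum0
        rhs = np.array([q0.sum() + q1.sum(), float(S @ q1), q1.sum()])
        try:
            mu, delta, phi1 = np.linalg.solve(M, rhs)
        except np.linalg.LinAlgError:
            return np.inf
        sign, logdetM = np.linalg.slogdet(M)
        if sign <= 0:
            return np.inf
        m0 = mu
        m1 = mu + phi1 + S * delta
        sum_r2 = self.ss - 2.0 * float(m0 * self.sum0.sum() + m1 @ self.sum1) \
            + float(K @ (m0 * m0 + m1 * m1))
        T0 = self.sum0 - K * m0
        T1 = self.sum1 - K * m1
        a = 1.0  # diagonal minus within off-diagonal of C^-1
        Q = a * sum_r2 + float(b @ (T0 * T0 + T1 * T1)) + 2.0 * float(c @ (T0 * T1))
        if Q <= 0:
            return np.inf
        logdetC = float(np.sum(np.log(lam_p) + np.log(lam_m)))
        return logdetC + logdetM + self.npp * (
            math.log(2 * math.pi) + math.log(Q / self.npp) + 1.0)


def _resid_quadform(st: ClusterStats, theta, d, b, c):
    """r' C^-1 r from sufficient statistics, given the inverse constants."""
    mu, delta, phi1 = theta
    K = st.k0.astype(float)
    S = st.seq.astype(float)
    m0 = mu
    m1 = mu + phi1 + S * delta
    sum_r2 = (st.ss0 + st.ss1) - 2.0 * (m0 * st.sum0 + m1 * st.sum1) \
        + K * (m0 * m0 + m1 * m1)
    T0 = st.sum0 - K * m0
    T1 = st.sum1 - K * m1
    a = d - b  # pure-diagonal part of the inverse
    return float(np.sum(a * sum_r2 + b * (T0 * T0 + T1 * T1) + 2.0 * c * T0 * T1))


def reml_loglik(data: PBCRTData | ClusterStats, structure: str,
                vc: VarianceComponents) -> float:
    """Restricted log-likelihood of the Gaussian model at a given ``vc``.

    Uses the standard REML criterion
    ``-1/2 [ (n-p) log 2pi + log|V| + log|Z'V^-1 Z| + r'V^-1 r ]`` with ``r``
    the GLS residuals at ``vc``.
    """
    st = data if isinstance(data, ClusterStats) else data.cluster_stats()
    if not st.equal_cells:
        raise EstimationError("REML requires equal within-cluster cell sizes")
    if structure.upper() == "EME":
        t_w = t_b = vc.tau_alpha2
    elif structure.upper() == "NEME":
        t_w, t_b = vc.tau_alpha2 + vc.tau_gamma2, vc.tau_alpha2
    else:
        raise ValueError(f"unknown structure {structure!r}")
    d, b, c, logdetV = _inverse_terms(st.k0, t_w, t_b, vc.sigma_w2)
    theta, M = _gls_fit_stats(st, t_w, t_b, vc.sigma_w2, weighted=False)
    sign, logdetM = np.linalg.slogdet(M)
    quad = _resid_quadform(st, theta, d, b, c)
    n = st.n
    return -0.5 * ((n - _P) * math.log(2 * math.pi) + float(np.sum(logdetV))
                   + logdetM + quad)


def _finish(st: ClusterStats, structure: str, phi_a: float, phi_g: float,
            converged: bool, n_evals: int) -> REMLFit:
    boundary = False
    if phi_a < _ZERO_RATIO:
        phi_a, boundary = 0.0, True
    if structure.upper() == "NEME" and phi_g < _ZERO_RATIO:
        phi_g, boundary = 0.0, True
    phi_w = phi_a + (phi_g if structure.upper() == "NEME" else 0.0)
    theta, _ = _gls_fit_stats(st, phi_w, phi_a, 1.0, weighted=False)
    d, b, c, _ = _inverse_terms(st.k0, phi_w, phi_a, 1.0)
    sigma2 = _resid_quadform(st, theta, d, b, c) / (st.n - _P)
    vc = VarianceComponents(phi_a * sigma2,
                            (phi_g * sigma2) if structure.upper() == "NEME" else 0.0,
                            sigma2)
    # theta is invariant to the overall scale of V, so the C-scale GLS fit
    # above is already the GLS fit at the final variance components
    ll = reml_loglik(st, structure, vc)
    return REMLFit(vc=vc, theta_hat=np.asarray(theta), loglik=ll,
                   converged=converged, boundary=boundary,
                   structure=structure.upper(), n_evals=n_evals)


def _min_1d(fun, evals):
    """Bounded 1-d minimization on the log-ratio scale; returns (x, f)."""
    res = optimize.minimize_scalar(
        fun, bounds=(_LOG_LO, _LOG_HI), method="bounded",
        options={"xatol": 1e-5})
    evals[0] += res.nfev
    return float(res.x), float(res.fun)


def reml_estimate(data: PBCRTData | ClusterStats, structure: str) -> REMLFit:
    """REML variance components and GLS coefficients for EME or NEME.

    Boundary estimates (a variance component estimated at zero) are returned
    with ``boundary=True``, not raised; non-convergence of every start is
    flagged through ``converged=False`` on the best candidate found.
    """
    st = data if isinstance(data, ClusterStats) else data.cluster_stats()
    if st.I < 2:
        raise EstimationError("REML needs at least two clusters")
    if not st.equal_cells:
        raise EstimationError("REML requires equal within-cluster cell sizes")
    structure = structure.upper()
    prof = _Profile(st)
    evals = [0]
    candidates = []  # (neg2, phi_a, phi_g, converged)

    # shared 1-d exchangeable profile: phi_gamma fixed at 0
    def f_eme(x):
        phi = math.exp(x)
        return prof.neg2(phi, phi)

    x_a, f_a = _min_1d(f_eme, evals)
    ols = prof.neg2(0.0, 0.0)
    evals[0] += 1

    if structure == "EME":
        candidates.append((f_a, math.exp(x_a), 0.0, True))
        candidates.append((ols, 0.0, 0.0, True))
    elif structure == "NEME":
        def f_nm(x):
            pa, pg = math.exp(x[0]), math.exp(x[1])
            return prof.neg2(pa + pg, pa)

        best = None
        any_ok = False
        for start in _NM_STARTS:
            res = optimize.minimize(
                f_nm, np.array(start), method="Nelder-Mead",
                options={"xatol": 1e-3, "fatol": 1e-7, "maxiter": 200})
            evals[0] += res.nfev
            any_ok = any_ok or bool(res.success)
            if best is None or res.fun < best.fun:
                best = res
        candidates.append((float(best.fun), math.exp(best.x[0]),
                           math.exp(best.x[1]), any_ok))
        # boundary candidates
        candidates.append((f_a, math.exp(x_a), 0.0, True))  # tau_gamma2 = 0

        def f_g_only(x):  # tau_alpha2 = 0
            return prof.neg2(math.exp(x), 0.0)

        x_g, f_g = _min_1d(f_g_only, evals)
        candidates.append((f_g, 0.0, math.exp(x_g), True))
        candidates.append((ols, 0.0, 0.0, True))
    else:
        raise ValueError(f"unknown structure {structure!r}")

    candidates.sort(key=lambda t: t[0])
    f_best, phi_a, phi_g, ok = candidates[0]
    if not np.isfinite(f_best):
        raise EstimationError("restricted likelihood is degenerate for these data")
    return _finish(st, structure, phi_a, phi_g, ok, evals[0])
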