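"""True estimands, probability limits, and estimand weights.

Under the two-subpopulation generative model the individual-average treatment
effect weights each subpopulation's effect by its expected cluster-period
size,

    iATE = sum_u P(u) E[K|u] delta_u / sum_u P(u) E[K|u],

while the cluster-average treatment effect weights clusters equally,
``cATE = sum_u P(u) delta_u``.  The mixed-model estimators converge instead
to ``E[g(K) K delta]/E[g(K) K]`` (unweighted) or ``E[g(K) delta]/E[g(K)]``
(inverse-size weighted), with structure-specific size weights

    g_EME(K)  = (1 + (K-1) rho) / (1 + (2K-1) rho)
    g_NEME(K) = (1 + (K-1) rho_wp) / ((1 + (K-1) rho_wp)^2 - K^2 rho_bp^2).

The cluster-specific estimand weights ``lambda = g(K)/E[g(K)]`` quantify how
far a weighted mixed-model estimand departs from the cATE; ``lambda == 1``
everywhere means the cATE is recovered.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .gls_estimators import VarianceComponents
from .simulator import DGPConfig

__all__ = [
    "TrueEstimands",
    "EstimandWeightProfile",
    "true_iate",
    "true_cate",
    "true_estimands",
    "icc_summary",
    "prob_limit",
    "lambda_emew",
    "lambda_nemew",
    "rho_star",
    "p_star",
]


@dataclass(frozen=True)
class TrueEstimands:
    iate: float
    cate: float


@dataclass(frozen=True)
class EstimandWeightProfile:
    """Per-subpopulation estimand weights lambda_u with their inputs.

    The probability-weighted mean of ``lambdas`` is exactly 1 by
    construction (normalization by the population expectation of ``g``).
    """

    lambdas: np.ndarray
    normalizer: float
    K: np.ndarray
    probs: np.ndarray
    params: dict


# ----------------------------------------------------------------------
def _subpop_arrays(config: DGPConfig):
    p = np.array([sp.prob for sp in config.subpops], dtype=float)
    K = np.array([sp.size_mean for sp in config.subpops], dtype=float)
    d = np.array([sp.delta for sp in config.subpops], dtype=float)
    return p, K, d


def true_iate(config: DGPConfig) -> float:
    """Individual-average treatment effect: E[K delta]/E[K] over subpopulations."""
    p, K, d = _subpop_arrays(config)
    denom = float(np.sum(p * K))
    if denom <= 0:
        raise ValueError("expected cluster-period size must be positive")
    return float(np.sum(p * K * d) / denom)


def true_cate(config: DGPConfig) -> float:
    """Cluster-average treatment effect: E[delta] over subpopulations."""
    p, _, d = _subpop_arrays(config)
    return float(np.sum(p * d))


def true_estimands(config: DGPConfig) -> TrueEstimands:
    return TrueEstimands(true_iate(config), true_cate(config))


def icc_summary(vc: VarianceComponents):
    """(rho, rho_wp, rho_bp, CAC) implied by the variance components."""
    return vc.rho, vc.rho_wp, vc.rho_bp, vc.cac


# ----------------------------------------------------------------------
def _g_eme(K, rho):
    K = np.asarray(K, dtype=float)
    return (1.0 + (K - 1.0) * rho) / (1.0 + (2.0 * K - 1.0) * rho)


def _g_neme(K, rho_wp, rho_bp):
    K = np.asarray(K, dtype=float)
    a = 1.0 + (K - 1.0) * rho_wp
    den = a * a - (K * rho_bp) ** 2
    if np.any(den <= 0):
        raise ValueError(
            "inadmissible correlation combination: the nested-exchangeable "
            "estimand weight denominator must be positive"
        )
    return a / den


def _truncated_poisson_expectation(fun, mean: float, tol: float = 1e-12) -> float:
    """E[fun(K)] for K ~ Poisson(mean) conditioned on K >= 1."""
    hi = int(mean + 12 * np.sqrt(mean) + 20)
    k = np.arange(1, hi + 1)
    pmf = sps.poisson.pmf(k, mean)
    pmf = pmf / (1.0 - np.exp(-mean))
    return float(np.sum(pmf * fun(k)))


def _expect(fun, config: DGPConfig, size_dist: str) -> float:
    """E[fun(K, delta)] over the subpopulation mixture.

    ``size_dist="plugin"`` plugs each subpopulation's Poisson mean into
    ``fun`` (the simple evaluation used for the headline limits);
    ``"poisson"`` integrates ``fun`` over the zero-truncated Poisson size
    distribution the simulator actually draws from.
    """
    p, K, d = _subpop_arrays(config)
    if size_dist == "plugin":
        return float(np.sum(p * fun(K, d)))
    if size_dist == "poisson":
        return float(sum(
            pu * _truncated_poisson_expectation(lambda k: fun(k, du), Ku)
            for pu, Ku, du in zip(p, K, d)
        ))
    raise ValueError(f"unknown size_dist {size_dist!r}")


def prob_limit(method: str, config: DGPConfig, vc: VarianceComponents | None = None,
               size_dist: str = "plugin") -> float:
    """Large-I probability limit of a treatment-effect estimator under the DGP.

    IEE/FE converge to the iATE, IEEw/FEw to the cATE; the mixed-model
    estimators converge to size-weighted estimands driven by the ICC(s).
    ``vc`` is required for the mixed-model methods and should be the
    probability limit of the model's variance-component estimator (the true
    generating components are the conventional plug-in).
    """
    method = method.lower()
    if method in ("iee", "fe"):
        num = _expect(lambda K, d: K * d, config, size_dist)
        den = _expect(lambda K, d: K, config, size_dist)
        return num / den
    if method in ("ieew", "few"):
        return _expect(lambda K, d: d, config, size_dist)
    if vc is None:
        raise ValueError("mixed-model probability limits need variance components")
    if method in ("eme", "emew"):
        g = lambda K: _g_eme(K, vc.rho)  # noqa: E731
    elif method in ("neme", "nemew"):
        g = lambda K: _g_neme(K, vc.rho_wp, vc.rho_bp)  # noqa: E731
    else:
        raise ValueError(f"unknown method {method!r}")
    if method.endswith("w"):
        num = _expect(lambda K, d: g(K) * d, config, size_dist)
        den = _expect(lambda K, d: g(K), config, size_dist)
    else:
        num = _expect(lambda K, d: g(K) * K * d, config, size_dist)
        den = _expect(lambda K, d: g(K) * K, config, size_dist)
    return num / den


# ----------------------------------------------------------------------
def _profile(g_vals: np.ndarray, K, probs, params: dict) -> EstimandWeightProfile:
    K = np.asarray(K, dtype=float)
    p = np.asarray(probs, dtype=float)
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("subpopulation probabilities must sum to 1")
    norm = float(np.sum(p * g_vals))
    return EstimandWeightProfile(lambdas=g_vals / norm, normalizer=norm,
                                 K=K, probs=p, params=params)


def lambda_emew(K_list, p_list, rho: float) -> EstimandWeightProfile:
    """EMEw estimand weights lambda_u = g(K_u)/E[g(K)] at ICC ``rho``.

    All weights equal 1 at ``rho = 0`` and ``rho = 1`` (the cATE is then
    recovered), and whenever all cluster-period sizes coincide.
    """
    if not 0 <= rho <= 1:
        raise ValueError("rho must lie in [0, 1]")
    return _profile(_g_eme(K_list, rho), K_list, p_list, {"rho": rho})


def lambda_nemew(K_list, p_list, rho_wp: float, rho_bp: float) -> EstimandWeightProfile:
    """NEMEw estimand weights at within/between-period ICCs (rho_wp, rho_bp)."""
    if not 0 <= rho_bp <= rho_wp <= 1:
        raise ValueError("need 0 <= rho_bp <= rho_wp <= 1")
    return _profile(_g_neme(K_list, rho_wp, rho_bp), K_list, p_list,
                    {"rho_wp": rho_wp, "rho_bp": rho_bp})


def rho_star(K1: float, K2: float, degenerate_flag: bool = False):
    """ICC maximizing the EMEw estimand-weight gap between two sizes.

    Closed form ``1/(1 + 2 sqrt(K1 K2))``.  When ``K1 == K2`` the weight gap
    is identically zero; the formula value is still returned (with a flag if
    ``degenerate_flag`` is set).
    """
    if K1 < 1 or K2 < 1:
        raise ValueError("cluster-period sizes must be >= 1")
    val = 1.0 / (1.0 + 2.0 * np.sqrt(K1 * K2))
    if degenerate_flag:
        return float(val), bool(K1 == K2)
    return float(val)


def p_star(K1: float, K2: float, rho: float) -> float:
    """Sampling probability P(u=1) maximizing the EMEw bias for the cATE.

    Equals ``g(K2) / (g(K1) + g(K2))`` (the lambda normalizers cancel);
    exactly 0.5 when the sizes coincide and close to 0.5 in general.
    """
    g1, g2 = _g_eme(K1, rho), _g_eme(K2, rho)
    return float(g2 / (g1 + g2))
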