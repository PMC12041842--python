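"""Model-based and leave-one-cluster-out jackknife variances; Wald intervals.

The jackknife refits the *entire* estimation procedure (including REML for
the mixed-model methods) on each leave-one-cluster-out subset:

    V_jk = (I-1)/I * sum_i (delta_(-i) - delta_bar)^2

centered by default at the mean of the leave-one-out estimates.  Wald
intervals use t quantiles with I-2 degrees of freedom (clusters minus the
two treatment-level parameters) by default; normal quantiles are available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .core_data import PBCRTData, ClusterStats
from .closed_form_estimators import EstimateResult, EstimationError
from .gls_estimators import VarianceComponents, _gls_fit_stats, _structure_terms
from .methods import fit, fit_all, METHODS, GLS_METHODS

__all__ = [
    "VarianceReport",
    "model_based_variance",
    "jackknife_estimates",
    "jackknife_variance",
    "wald_interval",
    "variance_report",
]


@dataclass
class VarianceReport:
    """Variances and the Wald interval(s) for one fitted method."""

    method: str
    model_based_var: float | None
    jackknife_var: float | None
    df: float
    ci_lower: float
    ci_upper: float
    reject_at_5pct: bool
    intervals: dict | None = None  # per variance type: (lo, hi, reject)


# ----------------------------------------------------------------------
def _stats_of(data) -> ClusterStats:
    return data if isinstance(data, ClusterStats) else data.cluster_stats()


def _cell_patterns(st: ClusterStats):
    """Counts and outcome sums of the three design patterns of the IEE model."""
    t = st.seq == 1
    n0 = st.k0.sum()
    n1c, n1t = st.k1[~t].sum(), st.k1[t].sum()
    return t, float(n0), float(n1c), float(n1t)


def _ols_rss(st: ClusterStats, m0: np.ndarray, m1: np.ndarray) -> float:
    """Residual sum of squares given per-cluster fitted cell means."""
    k0, k1 = st.k0.astype(float), st.k1.astype(float)
    return float(np.sum(st.ss0 - 2 * m0 * st.sum0 + k0 * m0 * m0)
                 + np.sum(st.ss1 - 2 * m1 * st.sum1 + k1 * m1 * m1))


def _var_iee(st: ClusterStats, res: EstimateResult) -> float:
    # classical sigma^2 (Z'Z)^-1 variance of the treatment coefficient from
    # the independence model fit to both periods
    t, n0, n1c, n1t = _cell_patterns(st)
    mu = st.sum0.sum() / n0
    mc = st.sum1[~t].sum() / n1c
    mt = st.sum1[t].sum() / n1t
    m1 = np.where(t, mt, mc)
    rss = _ols_rss(st, np.full(st.I, mu), m1)
    sigma2 = rss / (st.n - 3)
    return sigma2 * (1.0 / n1t + 1.0 / n1c)


def _var_fe(st: ClusterStats, res: EstimateResult) -> float:
    # delta-element of sigma^2 (Z'Z)^-1 for the two-way dummy design, built
    # on the 2I cluster-period cells
    I = st.I
    p = 2 + I  # mu, delta, phi1, alpha_2..alpha_I
    A = np.zeros((p, p))
    b = np.zeros(p)
    for i in range(I):
        for j, (k, s) in enumerate(((st.k0[i], st.sum0[i]), (st.k1[i], st.sum1[i]))):
            z = np.zeros(p)
            z[0] = 1.0
            z[1] = float(j) * st.seq[i]
            z[2] = float(j)
            if i > 0:
                z[2 + i] = 1.0
            A += k * np.outer(z, z)
            b += z * s
    theta = np.linalg.solve(A, b)
    # fitted cell means
    m0 = theta[0] + np.concatenate([[0.0], theta[3:]])
    m1 = m0 + theta[2] + theta[1] * st.seq
    rss = _ols_rss(st, m0, m1)
    dof = st.n - p
    if dof <= 0:
        raise EstimationError("no residual degrees of freedom for the FE model")
    sigma2 = rss / dof
    return sigma2 * float(np.linalg.inv(A)[1, 1])


def _var_two_sample(values: np.ndarray, treated: np.ndarray) -> float:
    # classical variance of a two-group mean difference from an I-observation
    # cluster-summary regression (pooled residual variance, I-2 df)
    I = values.shape[0]
    if I <= 2:
        raise EstimationError("cluster-summary variance needs more than 2 clusters")
    rt, rc = values[treated], values[~treated]
    rss = np.sum((rt - rt.mean()) ** 2) + np.sum((rc - rc.mean()) ** 2)
    sigma2 = rss / (I - 2)
    return float(sigma2 * (1.0 / rt.size + 1.0 / rc.size))


def _var_gls(st: ClusterStats, res: EstimateResult) -> float:
    M = None if res.extra is None else res.extra.get("normal_matrix")
    if M is None:
        if res.vc is None:
            raise EstimationError("GLS variance needs the fitted variance components")
        t_w, t_b = _structure_terms(
            "NEME" if res.method.startswith("neme") else "EME", res.vc)
        _, M = _gls_fit_stats(st, t_w, t_b, res.vc.sigma_w2,
                              weighted=res.method.endswith("w"))
    return float(np.linalg.inv(M)[1, 1])


def model_based_variance(data: PBCRTData | ClusterStats, res: EstimateResult) -> float:
    """Model-based variance of the treatment coefficient for a fitted method.

    OLS-type methods use the classical ``sigma^2 (Z'Z)^-1`` element (on the
    individual-level design for IEE/FE, on the cluster-period cell means for
    the weighted IEEw/FEw); GLS methods use the delta-element of
    ``(sum_i Z_i' W_i^-1 Z_i)^-1``.
    """
    st = _stats_of(data)
    m = res.method
    if m == "iee":
        v = _var_iee(st, res)
    elif m == "fe":
        v = _var_fe(st, res)
    elif m == "ieew":
        v = _var_two_sample(st.mean1, st.seq == 1)
    elif m == "few":
        v = _var_two_sample(st.mean1 - st.mean0, st.seq == 1)
    elif m in GLS_METHODS:
        v = _var_gls(st, res)
    else:
        raise ValueError(f"unknown method {m!r}")
    res.model_based_var = v
    return v


# ----------------------------------------------------------------------
def _loo_stats(st: ClusterStats):
    for i in range(st.I):
        sub = st.drop(i)
        if not (sub.seq == 1).any() or not (sub.seq == 0).any():
            raise EstimationError(
                f"leaving out cluster {st.clusters[i]!r} empties an arm; "
                "the jackknife is not defined"
            )
        yield st.clusters[i], sub


def jackknife_estimates(data: PBCRTData | ClusterStats, method,
                        vc: VarianceComponents | None = None) -> np.ndarray:
    """The I leave-one-cluster-out point estimates for one method.

    ``method`` may be a method name or any callable mapping per-cluster
    statistics to an :class:`EstimateResult`.  The full procedure is refit on
    every subset: GLS methods re-estimate their variance components by REML
    unless a fixed ``vc`` is given.
    """
    st = _stats_of(data)
    if st.I < 3:
        raise EstimationError("jackknife needs at least 3 clusters")
    est = (lambda s: fit(s, method, vc=vc)) if isinstance(method, str) else method
    out = np.empty(st.I)
    for i, (label, sub) in enumerate(_loo_stats(st)):
        try:
            out[i] = est(sub).delta_hat
        except Exception as err:
            raise EstimationError(
                f"leave-one-out refit failed without cluster {label!r}: {err}"
            ) from err
    return out


def jackknife_variance(data: PBCRTData | ClusterStats, method,
                       vc: VarianceComponents | None = None,
                       center: str = "loo_mean",
                       full_estimate: float | None = None) -> float:
    """Leave-one-cluster-out jackknife variance ``(I-1)/I sum (d_i - c)^2``.

    ``center`` is the mean of the leave-one-out estimates (default) or
    ``"full"`` for the full-sample estimate.
    """
    loo = jackknife_estimates(data, method, vc=vc)
    return jackknife_from_loo(loo, center=center, full_estimate=full_estimate)


def jackknife_from_loo(loo: np.ndarray, center: str = "loo_mean",
                       full_estimate: float | None = None) -> float:
    """Aggregate precomputed leave-one-out estimates into a jackknife variance."""
    I = loo.shape[0]
    if center == "loo_mean":
        c = loo.mean()
    elif center == "full":
        if full_estimate is None:
            raise ValueError("center='full' needs the full-sample estimate")
        c = full_estimate
    else:
        raise ValueError(f"unknown centering {center!r}")
    return float((I - 1) / I * np.sum((loo - c) ** 2))


# ----------------------------------------------------------------------
def wald_interval(delta_hat: float, var: float, I: int, alpha: float = 0.05,
                  dist: str = "t"):
    """Wald interval ``delta_hat +/- q * sqrt(var)`` and the 5%-level reject flag.

    ``dist="t"`` uses t quantiles with I-2 degrees of freedom; ``"normal"``
    uses standard normal quantiles.  The reject flag is True iff 0 falls
    outside the interval.
    """
    if var < 0:
        raise ValueError("variance must be nonnegative")
    if I < 3:
        raise ValueError("need at least 3 clusters for a Wald interval")
    if dist == "t":
        q = sps.t.ppf(1 - alpha / 2, df=I - 2)
    elif dist == "normal":
        q = sps.norm.ppf(1 - alpha / 2)
    else:
        raise ValueError(f"unknown reference distribution {dist!r}")
    half = q * np.sqrt(var)
    lo, hi = delta_hat - half, delta_hat + half
    return float(lo), float(hi), bool(lo > 0 or hi < 0)


def variance_report(data: PBCRTData | ClusterStats, res: EstimateResult,
                    variance_methods=("model", "jackknife"),
                    alpha: float = 0.05, dist: str = "t",
                    vc: VarianceComponents | None = None) -> VarianceReport:
    """Compute the requested variances and Wald intervals for one fit.

    The headline interval is the jackknife one when requested (the package's
    recommended inference), otherwise the model-based one; ``intervals``
    holds one entry per requested variance type.
    """
    st = _stats_of(data)
    mv = model_based_variance(st, res) if "model" in variance_methods else None
    jv = None
    if "jackknife" in variance_methods:
        jv = jackknife_variance(st, res.method, vc=vc)
        res.jackknife_var = jv
    intervals = {}
    if mv is not None:
        intervals["model"] = wald_interval(res.delta_hat, mv, st.I, alpha, dist)
    if jv is not None:
        intervals["jackknife"] = wald_interval(res.delta_hat, jv, st.I, alpha, dist)
    head = intervals.get("jackknife") or intervals.get("model")
    if head is None:
        raise ValueError("no variance method requested")
    return VarianceReport(
        method=res.method, model_based_var=mv, jackknife_var=jv,
        df=st.I - 2, ci_lower=head[0], ci_upper=head[1],
        reject_at_5pct=head[2], intervals=intervals,
    )
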