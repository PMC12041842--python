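"""Closed-form treatment-effect point estimators: IEE, IEEw, FE, FEw.

All four are exact arithmetic on per-cluster sufficient statistics:

* IEE  -- pooled follow-up mean difference between arms (equivalently the
  OLS treatment coefficient from the independence model with treatment and
  period fixed effects; the baseline period contributes no information).
* IEEw -- difference of arm-wise averages of cluster follow-up means
  (inverse cluster-period size weighting).
* FE   -- two-way fixed-effects (cluster + period dummies) estimator, a
  harmonic-weighted difference-in-differences.  The general unequal-cell
  form is implemented; it collapses to the familiar within-arm DiD of
  summed outcomes when K_i0 = K_i1.
* FEw  -- difference-in-differences on cluster-period cell means: arm-wise
  averages of (follow-up cell mean - baseline cell mean).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_data import PBCRTData, ClusterStats

__all__ = [
    "EstimateResult",
    "EstimationError",
    "estimate_iee",
    "estimate_ieew",
    "estimate_fe",
    "estimate_few",
]


class EstimationError(ValueError):
    """Raised when an estimator's preconditions fail (e.g. an empty arm)."""


@dataclass
class EstimateResult:
    """A point estimate with optional nuisance estimates and variance slots."""

    method: str
    delta_hat: float
    nuisance: dict = field(default_factory=dict)
    model_based_var: float | None = None
    jackknife_var: float | None = None
    vc: object = None  # VarianceComponents used/estimated for GLS fits
    extra: dict = field(default_factory=dict)


def _arms(st: ClusterStats):
    t = st.seq == 1
    c = ~t
    if not t.any() or not c.any():
        raise EstimationError("both a treated and a control arm are required")
    return t, c


def estimate_iee(data: PBCRTData | ClusterStats) -> EstimateResult:
    """Independence estimating equation: pooled follow-up means by arm."""
    st = data if isinstance(data, ClusterStats) else data.cluster_stats()
    t, c = _arms(st)
    delta = st.sum1[t].sum() / st.k1[t].sum() - st.sum1[c].sum() / st.k1[c].sum()
    mu = st.sum0.sum() / st.k0.sum()  # pooled baseline mean
    phi1 = st.sum1[c].sum() / st.k1[c].sum() - mu
    return EstimateResult("iee", float(delta), {"mu": float(mu), "phi1": float(phi1)})


def estimate_ieew(data: PBCRTData | ClusterStats) -> EstimateResult:
    """Inverse cluster-period size weighted IEE: averages of cluster means."""
    st = data if isinstance(data, ClusterStats) else data.cluster_stats()
    t, c = _arms(st)
    m1 = st.mean1
    delta = m1[t].mean() - m1[c].mean()
    mu = st.mean0.mean()
    phi1 = m1[c].mean() - mu
    return EstimateResult("ieew", float(delta), {"mu": float(mu), "phi1": float(phi1)})


def estimate_fe(data: PBCRTData | ClusterStats, nuisances: bool = False) -> EstimateResult:
    """Two-way fixed-effects estimator (general harmonic-weighted DiD).

    Per arm the contrast is
    ``sum_i [K_i0 * sum_k Y_i1k - K_i1 * sum_k Y_i0k] / (K_i0 + K_i1)``
    divided by ``sum_i K_i0 K_i1 / (K_i0 + K_i1)``; the estimate is the
    treated-arm term minus the control-arm term.  Identical to the OLS
    treatment coefficient from the model with cluster and period dummies.
    """
    st = data if isinstance(data, ClusterStats) else data.cluster_stats()
    t, c = _arms(st)

    def arm(term):
        ktot = st.k0[term] + st.k1[term]
        num = (st.k0[term] * st.sum1[term] - st.k1[term] * st.sum0[term]) / ktot
        den = st.k0[term] * st.k1[term] / ktot
        return num.sum() / den.sum()

    delta = arm(t) - arm(c)
    res = EstimateResult("fe", float(delta))
    if nuisances:
        res.nuisance.update(_fe_nuisances(st, delta))
    return res


def _fe_nuisances(st: ClusterStats, delta: float) -> dict:
    """Profile out the cluster effects given delta-hat (exact OLS nuisances)."""
    # With delta fixed, the remaining model y - delta*X = mu + phi*j + alpha_i
    # is a weighted two-way layout; solve the small normal equations on the
    # 2I cell means.
    adj1 = st.sum1 - delta * st.seq * st.k1  # remove treatment contribution
    I = st.I
    # parameters: mu, phi1, alpha_2..alpha_I (alpha for first cluster = 0)
    p = 2 + (I - 1)
    A = np.zeros((p, p))
    b = np.zeros(p)
    for i in range(I):
        for j, (k, s) in enumerate(((st.k0[i], st.sum0[i]), (st.k1[i], adj1[i]))):
            z = np.zeros(p)
            z[0] = 1.0
            z[1] = float(j)
            if i > 0:
                z[1 + i] = 1.0
            A += k * np.outer(z, z)
            b += z * s
    sol = np.linalg.solve(A, b)
    return {"mu": float(sol[0]), "phi1": float(sol[1]),
            "alpha": np.concatenate([[0.0], sol[2:]])}


def estimate_few(data: PBCRTData | ClusterStats) -> EstimateResult:
    """Weighted fixed-effects estimator: DiD on cluster-period cell means.

    Valid even when cluster-period sizes differ between periods within a
    cluster; adding any constant to all baseline outcomes leaves it unchanged.
    """
    st = data if isinstance(data, ClusterStats) else data.cluster_stats()
    t, c = _arms(st)
    d = st.mean1 - st.mean0
    delta = d[t].mean() - d[c].mean()
    mu = st.mean0.mean()
    phi1 = d[c].mean()
    return EstimateResult("few", float(delta), {"mu": float(mu), "phi1": float(phi1)})
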