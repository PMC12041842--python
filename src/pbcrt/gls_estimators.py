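"""GLS point estimators under exchangeable and nested-exchangeable correlation.

For a cluster with equal cell sizes ``K_i0 = K_i1 = K`` the model covariance
block is

    R = I_{2K} sigma_w2 + (I_2 (x) J_K) t_w + ((J_2 - I_2) (x) J_K) t_b

with ``t_w = tau_alpha2 (+ tau_gamma2)`` on the within-period off-diagonals
and ``t_b = tau_alpha2`` between periods (exchangeable: ``t_w = t_b``).  Its
inverse shares the same three-constant structure; the constants follow from
the eigenvalues ``sigma_w2`` (multiplicity 2K-2) and
``sigma_w2 + K t_w -/+ K t_b`` (the period-contrast / period-sum directions).
The inverse-cluster-period-size weighted analyses replace ``R`` by ``K * R``.

The GLS estimator is ``theta_hat = (sum_i Z_i' W_i^-1 Z_i)^-1
sum_i Z_i' W_i^-1 Y_i`` with design columns (intercept, treatment, period);
because the design is constant within each cluster-period cell, the normal
equations reduce to per-cluster scalar arithmetic, which is what makes
leave-one-cluster-out refits over thousands of replicates affordable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_data import PBCRTData, ClusterStats
from .closed_form_estimators import EstimateResult, EstimationError

__all__ = [
    "VarianceComponents",
    "GLSBlock",
    "block_inverse_eme",
    "block_inverse_neme",
    "gls_point_estimate",
]

_COND_WARN = 1e10


@dataclass(frozen=True)
class VarianceComponents:
    """(tau_alpha2, tau_gamma2, sigma_w2) and the ICCs they imply."""

    tau_alpha2: float
    tau_gamma2: float
    sigma_w2: float

    def __post_init__(self):
        if self.tau_alpha2 < 0 or self.tau_gamma2 < 0:
            raise ValueError("random-effect variances must be nonnegative")
        if self.sigma_w2 <= 0:
            raise ValueError("residual variance must be positive")

    @property
    def rho(self) -> float:
        """Exchangeable-model ICC tau_alpha2 / (tau_alpha2 + sigma_w2)."""
        return self.tau_alpha2 / (self.tau_alpha2 + self.sigma_w2)

    @property
    def rho_wp(self) -> float:
        """Within-period ICC (tau_alpha2+tau_gamma2)/(total variance)."""
        tot = self.tau_alpha2 + self.tau_gamma2 + self.sigma_w2
        return (self.tau_alpha2 + self.tau_gamma2) / tot

    @property
    def rho_bp(self) -> float:
        """Between-period ICC tau_alpha2/(total variance)."""
        return self.tau_alpha2 / (self.tau_alpha2 + self.tau_gamma2 + self.sigma_w2)

    @property
    def cac(self) -> float:
        """Cluster auto-correlation rho_bp / rho_wp (1 when rho_wp = 0)."""
        return 1.0 if self.rho_wp == 0 else self.rho_bp / self.rho_wp


@dataclass(frozen=True)
class GLSBlock:
    """Constants of the structured inverse of ``w * R`` for one cluster.

    ``D`` is the diagonal entry, ``F`` the within-period off-diagonal entry
    and ``F_between`` the between-period entry (``F_between == F`` for the
    exchangeable structure).  ``A = K*D + (K-1)*F`` is the quantity through
    which the estimator's probability limit weights each cluster.
    """

    K: int
    D: float
    F: float
    F_between: float
    A: float
    weight: float

    def dense(self) -> np.ndarray:
        """Materialize the 2K x 2K inverse block (for tests/small K)."""
        K = self.K
        blk_w = np.full((K, K), self.F)
        np.fill_diagonal(blk_w, self.D)
        blk_b = np.full((K, K), self.F_between)
        return np.block([[blk_w, blk_b], [blk_b, blk_w]])


def _inverse_terms(K, t_w, t_b, sigma_w2, weight=1.0):
    """(diag, within off-diag, between off-diag, logdet) of ``weight * R``.

    Vectorized over ``K`` (and ``weight``).  Raises on a non-positive-definite
    combination.
    """
    if sigma_w2 <= 0:
        raise ValueError("sigma_w2 must be positive")
    K = np.asarray(K, dtype=float)
    lam_plus = sigma_w2 + K * (t_w + t_b)
    lam_minus = sigma_w2 + K * (t_w - t_b)
    if np.any(lam_plus <= 0) or np.any(lam_minus <= 0):
        raise ValueError("variance components give a non-positive-definite block")
    det = lam_plus * lam_minus
    b = ((sigma_w2 + K * t_w) / det - 1.0 / sigma_w2) / K
    c = -t_b / det
    d = 1.0 / sigma_w2 + b
    logdet = (2 * K - 2) * np.log(sigma_w2) + np.log(lam_plus) + np.log(lam_minus) \
        + 2 * K * np.log(weight)
    w = np.asarray(weight, dtype=float)
    return d / w, b / w, c / w, logdet


def block_inverse_eme(K: int, vc: VarianceComponents, weighted: bool = False) -> GLSBlock:
    """Closed-form inverse block for the exchangeable structure.

    ``D = (sigma_w2 + (2K-1) tau_alpha2) / (sigma_w2 (sigma_w2 + 2K tau_alpha2))``
    and ``F = -tau_alpha2 / (sigma_w2 (sigma_w2 + 2K tau_alpha2))``; the
    weighted variant divides both by ``K``.
    """
    w = float(K) if weighted else 1.0
    d, b, c, _ = _inverse_terms(K, vc.tau_alpha2, vc.tau_alpha2, vc.sigma_w2, w)
    return GLSBlock(K=K, D=float(d), F=float(b), F_between=float(c),
                    A=float(K * d + (K - 1) * b), weight=w)


def block_inverse_neme(K: int, vc: VarianceComponents, weighted: bool = False) -> GLSBlock:
    """Closed-form inverse block for the nested-exchangeable structure.

    Within-period off-diagonals carry ``tau_alpha2 + tau_gamma2``; between
    periods only ``tau_alpha2``.  Collapses to :func:`block_inverse_eme`
    when ``tau_gamma2 = 0``.
    """
    w = float(K) if weighted else 1.0
    d, b, c, _ = _inverse_terms(K, vc.tau_alpha2 + vc.tau_gamma2, vc.tau_alpha2,
                                vc.sigma_w2, w)
    return GLSBlock(K=K, D=float(d), F=float(b), F_between=float(c),
                    A=float(K * d + (K - 1) * b), weight=w)


def _structure_terms(structure: str, vc: VarianceComponents):
    if structure.upper() == "EME":
        return vc.tau_alpha2, vc.tau_alpha2
    if structure.upper() == "NEME":
        return vc.tau_alpha2 + vc.tau_gamma2, vc.tau_alpha2
    raise ValueError(f"unknown correlation structure: {structure!r}")


def _gls_fit_stats(st: ClusterStats, t_w: float, t_b: float, sigma_w2: float,
                   weighted: bool):
    """Closed-block GLS on sufficient statistics (requires equal cell sizes).

    Returns (theta, M) with theta = (mu, delta, phi1) and
    M = sum_i Z_i' W_i^-1 Z_i.
    """
    K = st.k0.astype(float)
    w = K if weighted else 1.0
    d, b, c, _ = _inverse_terms(K, t_w, t_b, sigma_w2, w)
    u = d + (K - 1) * b  # within-period row sum of the inverse
    v = K * c            # cross-period row sum
    cu = K * u
    s01 = K * v
    S = st.seq.astype(float)
    M = np.empty((3, 3))
    M[0, 0] = 2 * np.sum(cu + s01)
    M[0, 1] = M[1, 0] = np.sum((cu + s01) * S)
    M[0, 2] = M[2, 0] = np.sum(cu + s01)
    M[1, 1] = M[1, 2] = M[2, 1] = np.sum(cu * S)
    M[2, 2] = np.sum(cu)
    q0 = u * st.sum0 + v * st.sum1
    q1 = u * st.sum1 + v * st.sum0
    rhs = np.array([np.sum(q0 + q1), np.sum(S * q1), np.sum(q1)])
    theta = _solve(M, rhs)
    return theta, M


def _solve(M: np.ndarray, rhs: np.ndarray) -> np.ndarray:
    cond = np.linalg.cond(M)
    if not np.isfinite(cond) or cond > 1e15:
        raise EstimationError("singular GLS design (is one arm empty?)")
    if cond > _COND_WARN:
        import warnings

        warnings.warn(f"ill-conditioned GLS normal equations (cond={cond:.2e})")
    # least-squares solve is stable for near-singular systems
    return np.linalg.solve(M, rhs)


def _dense_cluster_matrices(data: PBCRTData, t_w: float, t_b: float, sigma_w2: float):
    """Yield (Z_i, y_i, R_i) per cluster; supports unequal cell sizes."""
    for cl, grp in data.cluster_frames().items():
        j = grp["period"].to_numpy()
        y = grp["y"].to_numpy(dtype=float)
        s = int(grp["sequence"].iloc[0])
        Z = np.column_stack([np.ones_like(y), s * j.astype(float), j.astype(float)])
        same = (j[:, None] == j[None, :])
        R = np.where(same, t_w, t_b).astype(float)
        np.fill_diagonal(R, sigma_w2 + t_w)
        yield Z, y, R


def _gls_fit_dense(data: PBCRTData, t_w: float, t_b: float, sigma_w2: float):
    M = np.zeros((3, 3))
    rhs = np.zeros(3)
    for Z, y, R in _dense_cluster_matrices(data, t_w, t_b, sigma_w2):
        Ri = np.linalg.solve(R, np.column_stack([Z, y]))
        M += Z.T @ Ri[:, :3]
        rhs += Z.T @ Ri[:, 3]
    return _solve(M, rhs), M


def gls_point_estimate(data: PBCRTData | ClusterStats, structure: str,
                       weighted: bool, vc: VarianceComponents,
                       path: str = "auto") -> EstimateResult:
    """GLS treatment-effect estimate under a given correlation structure.

    Parameters
    ----------
    structure : {"EME", "NEME"}
    weighted : use inverse cluster-period size weights ``w_i = K_i``.
    vc : variance components defining the covariance blocks (known truth or
        a REML estimate from :mod:`pbcrt.varcomp`).
    path : "auto" uses the closed block inverses when ``K_i0 = K_i1`` for all
        clusters and the dense per-cluster solve otherwise; "closed"/"dense"
        force a path.  The weighted analysis is only defined for equal
        within-cluster cell sizes; with unequal cells use the IEEw/FEw
        cell-mean estimators instead.
    """
    t_w, t_b = _structure_terms(structure, vc)
    st = data if isinstance(data, ClusterStats) else data.cluster_stats()
    if not (st.seq == 1).any() or not (st.seq == 0).any():
        raise EstimationError("both arms must be present")
    equal = st.equal_cells
    if path not in ("auto", "closed", "dense"):
        raise ValueError(f"unknown path {path!r}")
    if path == "closed" and not equal:
        raise EstimationError("closed-block path requires K_i0 = K_i1")
    use_closed = path == "closed" or (path == "auto" and equal)
    if use_closed:
        theta, M = _gls_fit_stats(st, t_w, t_b, vc.sigma_w2, weighted)
    else:
        if weighted:
            raise EstimationError(
                "inverse cluster-period size weighted GLS is not defined for "
                "K_i0 != K_i1; use the IEEw or FEw cell-mean estimators"
            )
        if isinstance(data, ClusterStats):
            raise EstimationError("dense GLS path requires the full PBCRTData")
        theta, M = _gls_fit_dense(data, t_w, t_b, vc.sigma_w2)
    name = structure.lower() + ("w" if weighted else "")
    return EstimateResult(
        name, float(theta[1]),
        nuisance={"mu": float(theta[0]), "phi1": float(theta[2])},
        vc=vc, extra={"normal_matrix": M},
    )
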