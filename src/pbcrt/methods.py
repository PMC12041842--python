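"""Dispatch table over the eight treatment-effect estimation procedures.

``fit(data, method)`` runs the full estimation procedure for one method name:
for the mixed-model methods that includes REML estimation of the variance
components (the weighted variants plug the unweighted REML components into
the weighted estimating equation) unless a known ``vc`` is supplied.
"""

from __future__ import annotations

from .core_data import PBCRTData, ClusterStats
from .closed_form_estimators import (
    EstimateResult, estimate_iee, estimate_ieew, estimate_fe, estimate_few)
from .gls_estimators import VarianceComponents, gls_point_estimate
from .varcomp import reml_estimate

__all__ = ["METHODS", "GLS_METHODS", "fit", "fit_all"]

#: canonical method order used throughout the package
METHODS = ("iee", "fe", "eme", "neme", "ieew", "few", "emew", "nemew")
GLS_METHODS = ("eme", "emew", "neme", "nemew")

_CLOSED = {"iee": estimate_iee, "ieew": estimate_ieew,
           "fe": estimate_fe, "few": estimate_few}


def _structure(method: str) -> str:
    return "NEME" if method.startswith("neme") else "EME"


def fit(data: PBCRTData | ClusterStats, method: str,
        vc: VarianceComponents | None = None) -> EstimateResult:
    """Point-estimate ``method`` on ``data``; REML for GLS methods if ``vc`` is None."""
    method = method.lower()
    if method in _CLOSED:
        return _CLOSED[method](data)
    if method in GLS_METHODS:
        if vc is None:
            vc = reml_estimate(data, _structure(method)).vc
        return gls_point_estimate(data, _structure(method),
                                  weighted=method.endswith("w"), vc=vc)
    raise ValueError(f"unknown method {method!r}; choose from {METHODS}")


def fit_all(data: PBCRTData | ClusterStats, methods=METHODS,
            vc: VarianceComponents | None = None) -> dict:
    """Fit several methods, sharing one REML fit per correlation structure.

    Returns ``{method: EstimateResult}``; per-method failures are returned as
    the raised exception object rather than aborting the whole batch.
    """
    st = data if isinstance(data, ClusterStats) else data.cluster_stats()
    vc_cache: dict[str, VarianceComponents] = {}
    out = {}
    for m in methods:
        m = m.lower()
        try:
            use_vc = vc
            if m in GLS_METHODS and vc is None:
                s = _structure(m)
                if s not in vc_cache:
                    vc_cache[s] = reml_estimate(st, s).vc
                use_vc = vc_cache[s]
            out[m] = fit(st, m, vc=use_vc)
        except Exception as err:  # noqa: BLE001 - per-method failure code
            out[m] = err
    return out
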