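"""Canonical data container for a two-period parallel CRT with baseline period.

A PB-CRT observes a continuous outcome ``y`` for each individual ``k`` in
period ``j`` (0 = baseline, 1 = follow-up) of cluster ``i``.  Every cluster is
untreated at baseline; clusters randomized to sequence ``S_i = 1`` receive the
treatment in the follow-up period, so the treatment indicator satisfies
``X_ij = S_i * j`` for every record.

Data live in long format, one row per individual outcome, with columns
``cluster, period, sequence, treatment, subpop, y``.  ``subpop`` is an
optional opaque subpopulation label used by the simulator and the estimand
calculations; it never enters any estimator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PBCRTData",
    "ClusterPeriodSummary",
    "ClusterStats",
    "ValidationError",
    "read_long_csv",
    "write_long_csv",
    "summarize_cells",
]

#: fixed CSV column order
CSV_COLUMNS = ["cluster", "period", "sequence", "treatment", "subpop", "y"]


class ValidationError(ValueError):
    """Raised when a long-format table violates the PB-CRT design invariants."""


@dataclass(frozen=True)
class ClusterPeriodSummary:
    """Summary of one cluster-period cell: size ``K_ij`` and the cell mean."""

    cluster_id: object
    period: int
    K: int
    cell_mean: float
    sequence: int


@dataclass
class ClusterStats:
    """Per-cluster sufficient statistics, in one fixed cluster order.

    All estimators in this package depend on the data only through these
    per-cluster quantities (cell sizes, cell sums, and sums of squares), which
    makes leave-one-cluster-out refits cheap: dropping a cluster is dropping
    one row of each array.
    """

    clusters: np.ndarray  # cluster labels, object array
    seq: np.ndarray  # S_i in {0,1}
    k0: np.ndarray  # baseline cell sizes
    k1: np.ndarray  # follow-up cell sizes
    sum0: np.ndarray  # baseline outcome sums
    sum1: np.ndarray  # follow-up outcome sums
    ss0: np.ndarray  # baseline sums of squared outcomes
    ss1: np.ndarray  # follow-up sums of squared outcomes

    @property
    def I(self) -> int:
        return self.clusters.shape[0]

    @property
    def n(self) -> int:
        return int(self.k0.sum() + self.k1.sum())

    @property
    def equal_cells(self) -> bool:
        """True when ``K_i0 = K_i1`` for every cluster."""
        return bool(np.array_equal(self.k0, self.k1))

    def drop(self, index: int) -> "ClusterStats":
        """Leave-one-cluster-out copy (by positional index)."""
        keep = np.ones(self.I, dtype=bool)
        keep[index] = False
        return ClusterStats(
            self.clusters[keep], self.seq[keep],
            self.k0[keep], self.k1[keep],
            self.sum0[keep], self.sum1[keep],
            self.ss0[keep], self.ss1[keep],
        )

    @property
    def mean0(self) -> np.ndarray:
        return self.sum0 / self.k0

    @property
    def mean1(self) -> np.ndarray:
        return self.sum1 / self.k1


class PBCRTData:
    """Validated long-format PB-CRT dataset.

    Parameters
    ----------
    df:
        Long table with columns ``cluster``, ``period``, ``sequence``, ``y``
        and optionally ``treatment`` (derived as ``sequence * period`` when
        absent) and ``subpop``.
    validate:
        Run the design invariant checks (default True).
    """

    def __init__(self, df: pd.DataFrame, validate: bool = True):
        df = df.copy()
        missing = {"cluster", "period", "sequence", "y"} - set(df.columns)
        if missing:
            raise ValidationError(f"missing required columns: {sorted(missing)}")
        if "treatment" not in df.columns or df["treatment"].isna().all():
            df["treatment"] = df["sequence"] * df["period"]
        if "subpop" not in df.columns:
            df["subpop"] = np.nan
        self._df = df[CSV_COLUMNS].reset_index(drop=True)
        self._stats: ClusterStats | None = None
        if validate:
            self._validate()

    # ------------------------------------------------------------------
    @property
    def df(self) -> pd.DataFrame:
        """The underlying long table (fixed column order)."""
        return self._df

    @property
    def n(self) -> int:
        return len(self._df)

    @property
    def I(self) -> int:
        return self._df["cluster"].nunique()

    @property
    def clusters(self) -> list:
        return list(self.cluster_stats().clusters)

    @property
    def has_subpop(self) -> bool:
        return self._df["subpop"].notna().any()

    def __eq__(self, other) -> bool:
        if not isinstance(other, PBCRTData):
            return NotImplemented
        return self._df.equals(other._df)

    def __repr__(self) -> str:
        return f"PBCRTData(I={self.I}, n={self.n})"

    # ------------------------------------------------------------------
    def _validate(self) -> None:
        df = self._df
        if len(df) == 0:
            warnings.warn("PBCRTData contains no records", stacklevel=3)
            return
        for col in ("period", "sequence", "treatment"):
            vals = df[col]
            if vals.isna().any() or not vals.isin([0, 1]).all():
                raise ValidationError(f"column {col!r} must be coded 0/1")
        y = pd.to_numeric(df["y"], errors="coerce")
        if y.isna().any() or not np.isfinite(y.to_numpy(dtype=float)).all():
            bad = df.loc[~np.isfinite(y.to_numpy(dtype=float)), "cluster"]
            raise ValidationError(
                f"missing/non-finite outcomes in cluster(s) {sorted(set(bad))}: "
                "the design assumes complete cross-sectional cells"
            )
        if (df["treatment"] != df["sequence"] * df["period"]).any():
            bad = df.loc[df["treatment"] != df["sequence"] * df["period"], "cluster"]
            raise ValidationError(
                f"treatment must equal sequence*period; violated in cluster(s) "
                f"{sorted(set(bad))}"
            )
        for cl, grp in df.groupby("cluster", sort=False):
            if grp["sequence"].nunique() != 1:
                raise ValidationError(f"sequence not constant within cluster {cl!r}")
            present = set(grp["period"])
            for j in (0, 1):
                if j not in present:
                    raise ValidationError(
                        f"cluster {cl!r} has an empty cell in period {j}"
                    )

    # ------------------------------------------------------------------
    def cluster_stats(self) -> ClusterStats:
        """Per-cluster sufficient statistics (cached; sorted by cluster label)."""
        if self._stats is None:
            df = self._df
            y = df["y"].to_numpy(dtype=float)
            j = df["period"].to_numpy()
            # stable order by first appearance so permutation-invariance is
            # a property of the estimators, not an artifact of sorting
            labels, codes = np.unique(df["cluster"].to_numpy(), return_inverse=True)
            I = labels.shape[0]
            k = np.zeros((I, 2), dtype=np.int64)
            s = np.zeros((I, 2))
            ss = np.zeros((I, 2))
            np.add.at(k, (codes, j), 1)
            np.add.at(s, (codes, j), y)
            np.add.at(ss, (codes, j), y * y)
            seq = np.zeros(I, dtype=np.int64)
            seq[codes] = df["sequence"].to_numpy()
            self._stats = ClusterStats(
                clusters=labels, seq=seq,
                k0=k[:, 0], k1=k[:, 1],
                sum0=s[:, 0], sum1=s[:, 1],
                ss0=ss[:, 0], ss1=ss[:, 1],
            )
        return self._stats

    def drop_cluster(self, label) -> "PBCRTData":
        """Return a copy without the given cluster (for jackknife refits)."""
        sub = self._df[self._df["cluster"] != label]
        if len(sub) == len(self._df):
            raise KeyError(f"no such cluster: {label!r}")
        return PBCRTData(sub, validate=False)

    def cluster_frames(self) -> dict:
        """Outcome vectors per cluster, each sorted baseline-then-follow-up."""
        out = {}
        for cl, grp in self._df.groupby("cluster", sort=False):
            grp = grp.sort_values("period", kind="stable")
            out[cl] = grp
        return out


# ----------------------------------------------------------------------
def read_long_csv(path) -> PBCRTData:
    """Read a long-format PB-CRT CSV (``cluster,period,sequence[,treatment][,subpop],y``).

    The ``treatment`` column is derived as ``sequence * period`` when absent.
    Raises :class:`ValidationError` on design violations, naming the
    offending cluster/period.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    return PBCRTData(df)


def write_long_csv(data: PBCRTData, path) -> None:
    """Write the long table with the fixed column order; round-trips exactly."""
    if data.n == 0:
        warnings.warn("writing a PBCRTData with no records (header only)")
    # 17 significant digits so outcomes round-trip to full double precision
    data.df.to_csv(path, index=False, float_format="%.17g")


def summarize_cells(data: PBCRTData) -> list[ClusterPeriodSummary]:
    """One :class:`ClusterPeriodSummary` per nonempty cluster-period cell."""
    st = data.cluster_stats()
    out = []
    for i in range(st.I):
        out.append(ClusterPeriodSummary(st.clusters[i], 0, int(st.k0[i]),
                                        float(st.sum0[i] / st.k0[i]), int(st.seq[i])))
        out.append(ClusterPeriodSummary(st.clusters[i], 1, int(st.k1[i]),
                                        float(st.sum1[i] / st.k1[i]), int(st.seq[i])))
    return out
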