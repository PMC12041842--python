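"""Monte-Carlo evaluation of the eight estimators: bias, RMSE, variance, CP, power.

A scenario is a generative configuration plus a replicate count and a master
seed.  Each replicate simulates one trial, runs every requested estimator,
and (optionally) both variance estimators; the leave-one-cluster-out pass is
shared across methods so each subset's REML fits are computed once.
Replicate seeds are spawned from the master seed, so results are identical
for any degree of parallelism.

Coverage is evaluated against both estimands for every estimator (the
unweighted estimators naturally target the individual-average effect, the
weighted ones the cluster-average effect); power is the rejection rate of
the 5%-level Wald test of no effect, which under a zero-effect configuration
is the type-I error rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .core_data import ClusterStats
from .simulator import DGPConfig, simulate_pbcrt
from .methods import METHODS, fit_all
from .inference import (
    model_based_variance, jackknife_from_loo, wald_interval)
from .estimands import true_estimands, TrueEstimands

__all__ = ["ScenarioConfig", "SimSummary", "run_replicate", "run_scenario"]


@dataclass
class ScenarioConfig:
    """One Monte-Carlo scenario."""

    dgp: DGPConfig
    n_reps: int = 1000
    estimators: tuple = METHODS
    variance_methods: tuple = ("model", "jackknife")
    seed: int = 0
    alpha: float = 0.05
    dist: str = "t"
    n_jobs: int = 1
    keep_replicates: bool = False

    def __post_init__(self):
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        unknown = set(m.lower() for m in self.estimators) - set(METHODS)
        if unknown:
            raise ValueError(f"unknown estimators: {sorted(unknown)}")


@dataclass
class SimSummary:
    """Aggregated per-estimator performance over the replicates.

    ``table`` has one row per estimator with mean estimate, percent relative
    bias and RMSE against both estimands, Monte-Carlo variance, mean variance
    estimates, coverage and power per variance estimator, and Monte-Carlo
    standard errors for the headline quantities.
    """

    table: pd.DataFrame
    estimands: TrueEstimands
    n_reps: int
    failures: dict
    flagged: list
    replicates: pd.DataFrame | None = None


def run_replicate(dgp: DGPConfig, seed, estimators=METHODS,
                  variance_methods=("model", "jackknife"),
                  alpha: float = 0.05, dist: str = "t") -> dict:
    """Simulate one trial and analyze it with every requested method.

    Returns ``{method: record}`` where a record holds ``delta`` and the
    requested variances, or ``{"error": message}`` when that method failed;
    failures are per-method, never fatal.
    """
    trial = simulate_pbcrt(dgp, seed)
    st = trial.data.cluster_stats()
    fits = fit_all(st, estimators)

    loo_deltas: dict[str, list] = {m: [] for m in fits}
    if "jackknife" in variance_methods:
        for i in range(st.I):
            sub = st.drop(i)
            sub_fits = fit_all(sub, estimators)
            for m, r in sub_fits.items():
                loo_deltas[m].append(
                    np.nan if isinstance(r, Exception) else r.delta_hat)

    out = {}
    for m, res in fits.items():
        if isinstance(res, Exception):
            out[m] = {"error": f"{type(res).__name__}: {res}"}
            continue
        rec = {"delta": res.delta_hat}
        if "model" in variance_methods:
            try:
                rec["model_var"] = model_based_variance(st, res)
            except Exception as err:
                rec["model_var"] = np.nan
                rec.setdefault("warnings", []).append(str(err))
        if "jackknife" in variance_methods:
            loo = np.asarray(loo_deltas[m], dtype=float)
            rec["jackknife_var"] = (
                np.nan if np.isnan(loo).any() else jackknife_from_loo(loo))
        out[m] = rec
    return out


def _coverage_and_power(deltas, variances, I, alpha, dist, targets):
    cov = {t: [] for t in targets}
    power = []
    for d, v in zip(deltas, variances):
        if not np.isfinite(v):
            continue
        lo, hi, reject = wald_interval(d, v, I, alpha, dist)
        for name, val in targets.items():
            cov[name].append(lo <= val <= hi)
        power.append(reject)
    ncp = len(power)
    res = {}
    for name in targets:
        res[f"cp_{name}"] = np.mean(cov[name]) if ncp else np.nan
    res["power"] = np.mean(power) if ncp else np.nan
    res["n_ci"] = ncp
    return res


def run_scenario(config: ScenarioConfig) -> SimSummary:
    """Run all replicates of a scenario and aggregate the performance table."""
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_reps)
    worker = delayed(run_replicate)
    reps = Parallel(n_jobs=config.n_jobs)(
        worker(config.dgp, s, config.estimators, config.variance_methods,
               config.alpha, config.dist)
        for s in seeds
    )

    est = true_estimands(config.dgp)
    targets = {"iate": est.iate, "cate": est.cate}
    R = config.n_reps
    I = config.dgp.I
    rows = []
    failures: dict[str, int] = {}
    flagged = []
    rep_rows = []
    for m in (x.lower() for x in config.estimators):
        recs = [r[m] for r in reps]
        ok = [r for r in recs if "error" not in r]
        failures[m] = R - len(ok)
        if failures[m] > 0.05 * R:
            flagged.append(m)
        d = np.array([r["delta"] for r in ok])
        if config.keep_replicates:
            for idx, r in enumerate(recs):
                rep_rows.append({"replicate": idx, "method": m, **{
                    k: v for k, v in r.items() if k != "warnings"}})
        row = {"method": m, "n_ok": len(d), "mean_est": d.mean(),
               "mc_var": d.var(ddof=1) if len(d) > 1 else np.nan,
               "mc_se_mean": d.std(ddof=1) / np.sqrt(len(d)) if len(d) > 1 else np.nan}
        for name, val in targets.items():
            row[f"pct_bias_{name}"] = 100.0 * (d.mean() - val) / val if val else np.nan
            row[f"rmse_{name}"] = float(np.sqrt(np.mean((d - val) ** 2)))
            if val and len(d) > 1:
                row[f"mc_se_pct_bias_{name}"] = 100.0 * row["mc_se_mean"] / abs(val)
        for vm, key in (("model", "model_var"), ("jackknife", "jackknife_var")):
            if vm not in config.variance_methods:
                continue
            v = np.array([r.get(key, np.nan) for r in ok], dtype=float)
            row[f"mean_{key}"] = np.nanmean(v) if np.isfinite(v).any() else np.nan
            cp = _coverage_and_power(d, v, I, config.alpha, config.dist, targets)
            row[f"cp_{vm}_iate"] = cp["cp_iate"]
            row[f"cp_{vm}_cate"] = cp["cp_cate"]
            row[f"power_{vm}"] = cp["power"]
            n_ci = cp["n_ci"]
            for name in targets:
                p = cp[f"cp_{name}"]
                row[f"mc_se_cp_{vm}_{name}"] = (
                    np.sqrt(p * (1 - p) / n_ci) if n_ci else np.nan)
        rows.append(row)

    table = pd.DataFrame(rows).set_index("method")
    return SimSummary(
        table=table, estimands=est, n_reps=R, failures=failures,
        flagged=flagged,
        replicates=pd.DataFrame(rep_rows) if config.keep_replicates else None,
    )
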