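"""Synthetic data generator for two-period PB-CRTs with informative cluster sizes.

The generative model draws each cluster from one of a small number of
subpopulations ``u``.  A subpopulation fixes the Poisson mean of the
cluster-period cell size ``K_i`` (held equal across the two periods within a
cluster) and the subpopulation-specific treatment effect ``delta_u``; making
``delta_u`` covary with the size mean is exactly what produces informative
cluster sizes.  Potential outcomes are

    Y_ijk(0) = mu + phi1*j + alpha_i + gamma_ij + e_ijk
    Y_i1k(1) = Y_i1k(0) + delta_u

with cluster intercepts ``alpha_i ~ N(0, tau_alpha2)``, cluster-period
interactions ``gamma_ij ~ N(0, tau_gamma2)`` and residuals
``e_ijk ~ N(0, sigma_w2)``.  Both arms share the same latent draws, so the
per-cluster potential-outcome contrast is exactly ``delta_u``.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .core_data import PBCRTData

__all__ = [
    "Subpopulation",
    "DGPConfig",
    "SimulatedTrial",
    "simulate_pbcrt",
    "true_effect_surface",
]


@dataclass(frozen=True)
class Subpopulation:
    """One cluster subpopulation: sampling probability, Poisson size mean, effect."""

    prob: float
    size_mean: float
    delta: float


@dataclass
class DGPConfig:
    """All generative parameters of the simulation model.

    Defaults reproduce the informative-cluster-size study condition: a
    10-cluster, two-period trial, grand mean 1, period effect 0.2,
    within-period ICC ~0.06 and cluster auto-correlation 0.8
    (tau_alpha2=0.053, tau_gamma2=0.013, sigma_w2=1), and two equally likely
    subpopulations with Poisson size means 20 and 100 carrying treatment
    effects 0.2 and 0.5.
    """

    I: int = 10
    mu: float = 1.0
    phi1: float = 0.2
    subpops: Sequence[Subpopulation] = (
        Subpopulation(0.5, 20.0, 0.2),
        Subpopulation(0.5, 100.0, 0.5),
    )
    tau_alpha2: float = 0.053
    tau_gamma2: float = 0.013
    sigma_w2: float = 1.0
    treated_fraction: float = 0.5
    stratify: bool = False

    def __post_init__(self):
        self.subpops = tuple(
            sp if isinstance(sp, Subpopulation) else Subpopulation(*sp)
            for sp in self.subpops
        )
        probs = [sp.prob for sp in self.subpops]
        if abs(sum(probs) - 1.0) > 1e-12:
            raise ValueError("subpopulation probabilities must sum to 1")
        if any(p < 0 for p in probs):
            raise ValueError("subpopulation probabilities must be nonnegative")
        if any(sp.size_mean <= 0 for sp in self.subpops):
            raise ValueError("Poisson size means must be positive")
        if self.tau_alpha2 < 0 or self.tau_gamma2 < 0 or self.sigma_w2 < 0:
            raise ValueError("variance components must be nonnegative")
        n_treated = self.I * self.treated_fraction
        if abs(n_treated - round(n_treated)) > 1e-9:
            raise ValueError(
                f"I*treated_fraction = {n_treated} is not an integer; "
                "with treated_fraction 1/2 the cluster count must be even"
            )

    @property
    def n_treated(self) -> int:
        return round(self.I * self.treated_fraction)

    # -- named study conditions -----------------------------------------
    @classmethod
    def informative(cls, I: int = 10) -> "DGPConfig":
        """Heterogeneous effects (delta = 0.2 / 0.5): iATE 0.45, cATE 0.35."""
        return cls(I=I)

    @classmethod
    def homogeneous(cls, I: int = 10) -> "DGPConfig":
        """Homogeneous effect delta = 0.35 in both subpopulations."""
        return cls(
            I=I,
            subpops=(Subpopulation(0.5, 20.0, 0.35), Subpopulation(0.5, 100.0, 0.35)),
        )

    # -- (de)serialization ----------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["subpops"] = [list(asdict(sp).values()) for sp in self.subpops]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DGPConfig":
        d = dict(d)
        d["subpops"] = [Subpopulation(*sp) for sp in d["subpops"]]
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "DGPConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class SimulatedTrial:
    """A simulated trial plus the latent state needed for oracle quantities."""

    data: PBCRTData
    latent: pd.DataFrame  # per-cluster: subpop u, K, delta_u, alpha, gamma0, gamma1
    seed: object = None


def _draw_subpops(config: DGPConfig, rng: np.random.Generator) -> np.ndarray:
    """Subpopulation index per cluster; exact allocation when I*p is integral."""
    probs = np.array([sp.prob for sp in config.subpops])
    counts = config.I * probs
    if np.allclose(counts, np.round(counts), atol=1e-9):
        u = np.repeat(np.arange(len(probs)), np.round(counts).astype(int))
        return rng.permutation(u)
    return rng.choice(len(probs), size=config.I, p=probs)


def _draw_sizes(config: DGPConfig, u: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    means = np.array([sp.size_mean for sp in config.subpops])[u]
    K = rng.poisson(means)
    while (K == 0).any():  # redraw empty clusters; P ~ 2e-9 at mean 20
        zero = K == 0
        K[zero] = rng.poisson(means[zero])
    return K


def _assign_treatment(config: DGPConfig, u: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    S = np.zeros(config.I, dtype=np.int64)
    if config.stratify:
        for g in np.unique(u):
            idx = np.flatnonzero(u == g)
            m = len(idx) * config.treated_fraction
            if abs(m - round(m)) > 1e-9:
                raise ValueError(
                    "stratified assignment needs an integer treated count per subpopulation"
                )
            S[rng.choice(idx, size=round(m), replace=False)] = 1
    else:
        S[rng.choice(config.I, size=config.n_treated, replace=False)] = 1
    return S


def simulate_pbcrt(config: DGPConfig, seed) -> SimulatedTrial:
    """Simulate one PB-CRT under the configured generative model.

    ``seed`` may be an int, a ``numpy.random.SeedSequence`` or a
    ``numpy.random.Generator``; a fixed seed yields a bitwise-identical trial.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    u = _draw_subpops(config, rng)
    K = _draw_sizes(config, u, rng)
    S = _assign_treatment(config, u, rng)
    delta_u = np.array([sp.delta for sp in config.subpops])[u]

    alpha = rng.normal(0.0, np.sqrt(config.tau_alpha2), size=config.I)
    gamma = rng.normal(0.0, np.sqrt(config.tau_gamma2), size=(config.I, 2))

    # one row per individual outcome, cells ordered cluster-major with the
    # baseline period first within each cluster
    cell_cluster = np.repeat(np.arange(config.I), 2)
    cell_period = np.tile(np.array([0, 1]), config.I)
    cell_K = np.repeat(K, 2)
    row_cluster = np.repeat(cell_cluster, cell_K)
    row_period = np.repeat(cell_period, cell_K)
    e = rng.normal(0.0, np.sqrt(config.sigma_w2), size=int(cell_K.sum()))
    x = S[row_cluster] * row_period
    # Y = X*Y(1) + (1-X)*Y(0) and Y(1)-Y(0) = delta_u under the additive model
    y = (config.mu + config.phi1 * row_period + alpha[row_cluster]
         + gamma[row_cluster, row_period] + e + x * delta_u[row_cluster])
    df = pd.DataFrame({
        "cluster": row_cluster, "period": row_period,
        "sequence": S[row_cluster], "treatment": x,
        "subpop": u[row_cluster], "y": y,
    })
    latent = pd.DataFrame({
        "cluster": np.arange(config.I), "subpop": u, "K": K, "sequence": S,
        "delta_u": delta_u, "alpha": alpha,
        "gamma0": gamma[:, 0], "gamma1": gamma[:, 1],
    }).set_index("cluster")
    return SimulatedTrial(data=PBCRTData(df, validate=False), latent=latent, seed=seed)


def true_effect_surface(trial: SimulatedTrial) -> pd.Series:
    """Per-cluster mean potential-outcome contrast ``E[Y_i1k(1) - Y_i1k(0)]``.

    Exact under the additive generative model: the latent draws cancel and the
    contrast is the cluster's subpopulation effect ``delta_u``.
    """
    if trial.latent is None or "delta_u" not in trial.latent:
        raise ValueError("trial does not retain its latent state")
    return trial.latent["delta_u"].rename("true_effect")
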