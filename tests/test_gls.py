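"""GLS block inverses and point estimators against dense-matrix oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pbcrt import (
    PBCRTData, VarianceComponents, block_inverse_eme, block_inverse_neme,
    gls_point_estimate, EstimationError)
from conftest import make_data


def dense_block(K, vc, structure, weighted):
    """Independent dense construction of w * R for one cluster."""
    t_w = vc.tau_alpha2 + (vc.tau_gamma2 if structure == "NEME" else 0.0)
    t_b = vc.tau_alpha2
    R = np.empty((2 * K, 2 * K))
    for r in range(2 * K):
        for s in range(2 * K):
            if r == s:
                R[r, s] = vc.sigma_w2 + t_w
            elif r // K == s // K:
                R[r, s] = t_w
            else:
                R[r, s] = t_b
    return (K if weighted else 1.0) * R


vc_strategy = st.builds(
    VarianceComponents,
    st.floats(0.0, 2.0), st.floats(0.0, 1.0), st.floats(0.05, 3.0))


@settings(deadline=None, max_examples=60, derandomize=True)
@given(K=st.integers(1, 5), vc=vc_strategy, weighted=st.booleans(),
       structure=st.sampled_from(["EME", "NEME"]))
def test_block_inverse_matches_dense_inverse(K, vc, weighted, structure):
    fn = block_inverse_eme if structure == "EME" else block_inverse_neme
    blk = fn(K, vc, weighted)
    W = dense_block(K, vc, structure, weighted)
    assert np.abs(blk.dense() @ W - np.eye(2 * K)).max() < 1e-9


def test_eme_block_k1_hand_value():
    blk = block_inverse_eme(1, VarianceComponents(1.0, 0.0, 1.0))
    # inverse of [[2,1],[1,2]] has diagonal 2/3 and off-diagonal -1/3
    assert blk.D == pytest.approx(2 / 3)
    assert blk.F_between == pytest.approx(-1 / 3)


def test_neme_block_k1_matches_brute_force():
    vc = VarianceComponents(0.053, 0.013, 1.0)
    blk = block_inverse_neme(1, vc)
    brute = np.linalg.inv(np.array([[1.066, 0.053], [0.053, 1.066]]))
    assert blk.D == pytest.approx(brute[0, 0], abs=1e-12)
    assert blk.F_between == pytest.approx(brute[0, 1], abs=1e-12)


def test_independence_limit():
    blk = block_inverse_eme(4, VarianceComponents(0.0, 0.0, 2.0))
    assert blk.D == pytest.approx(0.5)
    assert blk.F == 0.0 and blk.F_between == 0.0


def test_weighted_k1_equals_unweighted():
    vc = VarianceComponents(0.3, 0.1, 1.0)
    a, b = block_inverse_neme(1, vc, False), block_inverse_neme(1, vc, True)
    assert (a.D, a.F_between) == (b.D, b.F_between)


def test_neme_collapses_to_eme_when_tau_gamma_zero():
    vc = VarianceComponents(0.4, 0.0, 1.3)
    for K in (1, 3, 5):
        e, n = block_inverse_eme(K, vc), block_inverse_neme(K, vc)
        assert n.D == pytest.approx(e.D) and n.F == pytest.approx(e.F)
        assert n.F_between == pytest.approx(e.F_between)
        assert n.A == pytest.approx(e.A)


def test_sigma_zero_rejected():
    with pytest.raises(ValueError):
        VarianceComponents(0.1, 0.0, 0.0)


# ----------------------------------------------------------------------
def _dense_gls_oracle(data, structure, weighted, vc):
    """Full-matrix GLS oracle built independently of the package internals."""
    M = np.zeros((3, 3))
    rhs = np.zeros(3)
    df = data.df
    for cl in df["cluster"].unique():
        grp = df[df["cluster"] == cl].sort_values("period")
        K = (grp["period"] == 0).sum()
        y = grp["y"].to_numpy(dtype=float)
        Z = np.column_stack([
            np.ones(len(grp)), grp["treatment"].to_numpy(dtype=float),
            grp["period"].to_numpy(dtype=float)])
        W = dense_block(K, vc, structure, weighted)
        Wi = np.linalg.inv(W)
        M += Z.T @ Wi @ Z
        rhs += Z.T @ Wi @ y
    return np.linalg.solve(M, rhs)[1]


@pytest.mark.parametrize("structure", ["EME", "NEME"])
@pytest.mark.parametrize("weighted", [False, True])
def test_point_estimate_matches_dense_oracle(random_trial, structure, weighted):
    vc = VarianceComponents(0.2, 0.07, 1.1)
    got = gls_point_estimate(random_trial, structure, weighted, vc).delta_hat
    want = _dense_gls_oracle(random_trial, structure, weighted, vc)
    assert got == pytest.approx(want, abs=1e-9)


def test_closed_and_dense_paths_agree(random_trial):
    vc = VarianceComponents(0.15, 0.05, 0.9)
    for structure in ("EME", "NEME"):
        a = gls_point_estimate(random_trial, structure, False, vc, path="closed")
        b = gls_point_estimate(random_trial, structure, False, vc, path="dense")
        assert a.delta_hat == pytest.approx(b.delta_hat, abs=1e-9)


def test_zero_icc_equals_pooled_ols(random_trial):
    vc = VarianceComponents(0.0, 0.0, 1.0)
    got = gls_point_estimate(random_trial, "EME", False, vc).delta_hat
    df = random_trial.df
    Z = np.column_stack([np.ones(len(df)), df["treatment"], df["period"]])
    beta, *_ = np.linalg.lstsq(Z, df["y"].to_numpy(dtype=float), rcond=None)
    assert got == pytest.approx(beta[1], abs=1e-10)


def test_equal_cluster_sizes_weighted_equals_unweighted():
    rng = np.random.default_rng(8)
    d = make_data({cl: (cl % 2, rng.normal(size=4), rng.normal(size=4))
                   for cl in range(6)})
    vc = VarianceComponents(0.2, 0.05, 1.0)
    for structure in ("EME", "NEME"):
        w = gls_point_estimate(d, structure, True, vc).delta_hat
        u = gls_point_estimate(d, structure, False, vc).delta_hat
        assert w == pytest.approx(u, abs=1e-10)


def test_unequal_cells_dense_fallback_and_weighted_refusal(random_trial_unequal):
    vc = VarianceComponents(0.2, 0.05, 1.0)
    res = gls_point_estimate(random_trial_unequal, "NEME", False, vc)
    assert np.isfinite(res.delta_hat)
    with pytest.raises(EstimationError, match="IEEw|FEw"):
        gls_point_estimate(random_trial_unequal, "NEME", True, vc)


def test_one_arm_rejected():
    d = make_data({1: (1, [0], [1]), 2: (1, [0], [2]), 3: (1, [1], [2])})
    with pytest.raises(EstimationError):
        gls_point_estimate(d, "EME", False, VarianceComponents(0.1, 0, 1))
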