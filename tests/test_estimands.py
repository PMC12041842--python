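"""Estimand values, probability limits, and estimand-weight algebra."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pbcrt import (
    DGPConfig, Subpopulation, VarianceComponents, true_iate, true_cate,
    true_estimands, icc_summary, prob_limit, lambda_emew, lambda_nemew,
    rho_star, p_star)
from pbcrt.estimands import _g_eme, _g_neme

ICS = DGPConfig()                      # delta 0.2/0.5, sizes 20/100
HOMOG = DGPConfig.homogeneous()        # delta 0.35 everywhere
VC = VarianceComponents(0.053, 0.013, 1.0)


def test_true_estimand_values():
    assert true_iate(ICS) == pytest.approx((10 * 0.2 + 50 * 0.5) / 60)
    assert true_iate(ICS) == pytest.approx(0.45)
    assert true_cate(ICS) == pytest.approx(0.35)
    assert true_iate(HOMOG) == pytest.approx(0.35)
    assert true_cate(HOMOG) == pytest.approx(0.35)


def test_estimands_coincide_without_ics():
    # equal sizes with heterogeneous effects
    cfg = DGPConfig(subpops=((0.5, 40.0, 0.2), (0.5, 40.0, 0.5)))
    est = true_estimands(cfg)
    assert est.iate == pytest.approx(est.cate)
    # single subpopulation
    single = DGPConfig(subpops=((1.0, 30.0, 0.7),))
    assert true_iate(single) == pytest.approx(0.7)
    assert true_cate(single) == pytest.approx(0.7)


def test_icc_summary_paper_values():
    rho, rho_wp, rho_bp, cac = icc_summary(VC)
    assert round(rho_wp, 2) == 0.06
    assert round(rho_bp, 2) == 0.05
    assert cac == pytest.approx(0.803, abs=5e-4)
    # collapses
    assert icc_summary(VarianceComponents(0.1, 0.0, 1.0))[3] == 1.0
    assert icc_summary(VarianceComponents(0.0, 0.0, 1.0))[:3] == (0, 0, 0)


def test_prob_limit_nemew_value():
    # direct evaluation of the nested-exchangeable weighted limit at the
    # generating ICCs: g(K) = (1+(K-1)rwp)/((1+(K-1)rwp)^2 - K^2 rbp^2)
    lim = prob_limit("nemew", ICS, VC)
    rwp, rbp = VC.rho_wp, VC.rho_bp
    g = lambda K: (1 + (K - 1) * rwp) / ((1 + (K - 1) * rwp) ** 2 - (K * rbp) ** 2)
    want = (g(20) * 0.2 + g(100) * 0.5) / (g(20) + g(100))
    assert lim == pytest.approx(want, abs=1e-12)
    assert lim == pytest.approx(0.2960, abs=5e-4)
    # about -15.4% relative to the cATE
    assert 100 * (lim - 0.35) / 0.35 == pytest.approx(-15.4, abs=0.2)


def test_prob_limits_collapse_under_homogeneous_effect():
    for m in ("iee", "ieew", "fe", "few", "eme", "emew", "neme", "nemew"):
        assert prob_limit(m, HOMOG, VC) == pytest.approx(0.35, abs=1e-12)


def test_table_sufficient_conditions_grid():
    """Each estimator reaches its natural estimand under the stated condition."""
    est = true_estimands(ICS)
    # unweighted IEE/FE always hit the iATE; weighted IEEw/FEw the cATE
    for m, target in (("iee", est.iate), ("fe", est.iate),
                      ("ieew", est.cate), ("few", est.cate)):
        assert prob_limit(m, ICS, VC) == pytest.approx(target, abs=1e-12)
    # EME at rho = 0 or 1 recovers the iATE; EMEw the cATE
    for rho_vc in (VarianceComponents(0.0, 0.0, 1.0),
                   VarianceComponents(1e9, 0.0, 1e-9)):
        assert prob_limit("eme", ICS, rho_vc) == pytest.approx(est.iate, abs=1e-6)
        assert prob_limit("emew", ICS, rho_vc) == pytest.approx(est.cate, abs=1e-6)
    # NEME/NEMEw at rho_wp = rho_bp = 0
    zero = VarianceComponents(0.0, 0.0, 1.0)
    assert prob_limit("neme", ICS, zero) == pytest.approx(est.iate, abs=1e-12)
    assert prob_limit("nemew", ICS, zero) == pytest.approx(est.cate, abs=1e-12)
    # no-ICS grid: every method collapses to the shared estimand
    for sizes in ((30.0, 30.0), (80.0, 80.0)):
        cfg = DGPConfig(subpops=(
            Subpopulation(0.5, sizes[0], 0.2), Subpopulation(0.5, sizes[1], 0.5)))
        for m in ("iee", "ieew", "fe", "few", "eme", "emew", "neme", "nemew"):
            assert prob_limit(m, cfg, VC) == pytest.approx(0.35, abs=1e-10)


def test_poisson_expectation_close_to_plugin():
    # the exact zero-truncated Poisson expectation differs only slightly from
    # the plug-in at the study sizes (smooth weight functions)
    a = prob_limit("nemew", ICS, VC, size_dist="plugin")
    b = prob_limit("nemew", ICS, VC, size_dist="poisson")
    assert a == pytest.approx(b, abs=0.01)
    assert a != b


def test_lambda_emew_values_and_normalization():
    prof = lambda_emew([20, 100], [0.5, 0.5], 0.0619)
    assert prof.lambdas == pytest.approx([1.087, 0.913], abs=1e-3)
    assert float(prof.probs @ prof.lambdas) == pytest.approx(1.0, abs=1e-12)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(rho=st.floats(0.0, 1.0), K1=st.integers(1, 200), K2=st.integers(1, 200),
       p=st.floats(0.05, 0.95))
def test_lambda_emew_properties(rho, K1, K2, p):
    prof = lambda_emew([K1, K2], [p, 1 - p], rho)
    assert float(prof.probs @ prof.lambdas) == pytest.approx(1.0, abs=1e-9)
    if rho in (0.0, 1.0) or K1 == K2:
        assert np.allclose(prof.lambdas, 1.0)


def test_lambda_nemew_edge_cases():
    assert np.allclose(lambda_nemew([20, 100], [0.5, 0.5], 0.0, 0.0).lambdas, 1.0)
    assert np.allclose(lambda_nemew([50, 50], [0.5, 0.5], 0.3, 0.2).lambdas, 1.0)
    with pytest.raises(ValueError):
        lambda_nemew([20, 100], [0.5, 0.5], 0.2, 0.5)  # rho_bp > rho_wp


def test_nemew_weights_more_unbalanced_than_emew_at_matched_icc():
    # with cluster auto-correlation 0.8 the nested-exchangeable weights are
    # strictly more spread out than the exchangeable ones over an ICC grid
    for rho in np.linspace(0.01, 0.5, 20):
        gap_e = np.ptp(lambda_emew([20, 100], [0.5, 0.5], rho).lambdas)
        gap_n = np.ptp(lambda_nemew([20, 100], [0.5, 0.5], rho, 0.8 * rho).lambdas)
        assert gap_n > gap_e


def test_g_decreasing_in_rho_for_k_above_one():
    rhos = np.linspace(0.0, 1.0, 101)
    for K in (2, 20, 100):
        g = _g_eme(K, rhos)
        assert np.all(np.diff(g) < 0)


def test_rho_star_matches_grid_maximizer():
    # grid oracle over the (unnormalized) weight gap g(K1) - g(K2); the
    # normalizer is common to both subpopulations and held fixed
    for K1, K2 in ((20, 100), (5, 50), (2, 3)):
        rhos = np.arange(1e-5, 1.0, 1e-5)
        gap = np.abs(_g_eme(K1, rhos) - _g_eme(K2, rhos))
        grid = rhos[np.argmax(gap)]
        assert rho_star(K1, K2) == pytest.approx(grid, abs=1e-4)


def test_rho_star_properties():
    assert rho_star(20, 100) == pytest.approx(1 / (1 + 2 * np.sqrt(2000)), abs=1e-12)
    val, degenerate = rho_star(7, 7, degenerate_flag=True)
    assert degenerate and 0 < val < 1
    # decreasing in the size product
    prods = [rho_star(k, 2 * k) for k in (2, 5, 20, 80)]
    assert all(a > b for a, b in zip(prods, prods[1:]))


def test_p_star_values():
    assert p_star(50, 50, 0.3) == pytest.approx(0.5)
    r = rho_star(20, 100)
    val = p_star(20, 100, r)
    assert 0 < val < 1
    # close to one half, as the bias-maximizing sampling probability is
    assert val == pytest.approx(0.5, abs=0.1)
    g1, g2 = _g_eme(20, r), _g_eme(100, r)
    assert val == pytest.approx(g2 / (g1 + g2), abs=1e-12)
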