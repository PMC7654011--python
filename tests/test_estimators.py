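"""Wald ratios and the five causal estimators."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrflow import (
    EstimationError,
    InsufficientDataError,
    egger,
    ivw,
    mode_based,
    raps,
    wald_ratio,
    weighted_median,
)
from mrflow.estimators import _weighted_median_point

from conftest import make_hrec, make_hset, random_hset


# ------------------------------------------------------------------ Wald ratio

def test_wald_ratio_first_order_arithmetic():
    r = wald_ratio(make_hrec("rs1", 0.2, 0.02, 0.04, 0.01))
    assert r.ratio == pytest.approx(0.2)
    assert r.se_ratio == pytest.approx(0.05)  # se_out / |beta_exp|
    assert r.weight == pytest.approx(400.0)


def test_wald_ratio_zero_outcome_beta():
    r = wald_ratio(make_hrec("rs1", 0.2, 0.02, 0.0, 0.01))
    assert r.ratio == 0.0 and r.se_ratio == pytest.approx(0.05)


def test_wald_ratio_second_order_matches_hand_expanded_delta_formula():
    # se^2 = se_out^2/bx^2 + by^2 se_exp^2 / bx^4
    #      = 0.01^2/0.2^2 + 0.04^2 0.02^2 / 0.2^4 = 0.0025 + 0.0004 = 0.0029
    r = wald_ratio(make_hrec("rs1", 0.2, 0.02, 0.04, 0.01), order="second")
    assert r.se_ratio == pytest.approx(np.sqrt(0.0029), rel=1e-12)


def test_degenerate_instrument_raises():
    with pytest.raises(EstimationError):
        wald_ratio(make_hrec("rs1", 0.0, 0.02, 0.04, 0.01))


# ------------------------------------------------------------------------- IVW

def test_single_snp_ivw_collapses_to_wald_ratio():
    hset = make_hset([0.2], [0.02], [0.04], [0.01])
    est = ivw(hset)
    wr = wald_ratio(hset.retained[0])
    assert est.beta == pytest.approx(wr.ratio, abs=0)
    assert est.se == pytest.approx(wr.se_ratio, abs=0)
    assert est.extras["model"] == "fixed"


def test_equal_weight_symmetric_ratios_average():
    # ratios 1 and 3 with identical weights -> 2
    hset = make_hset([0.1, 0.1], [0.01, 0.01], [0.1, 0.3], [0.02, 0.02])
    assert ivw(hset, model="fixed").beta == pytest.approx(2.0)


def test_ivw_matches_weighted_mean_oracle(rng):
    for _ in range(20):
        hset = random_hset(rng, int(rng.integers(2, 11)))
        ratios = np.array([r.beta_out / r.beta_exp for r in hset.retained])
        weights = np.array([(r.beta_exp / r.se_out) ** 2 for r in hset.retained])
        est = ivw(hset, model="fixed")
        assert est.beta == pytest.approx((weights * ratios).sum() / weights.sum(), abs=1e-12)
        assert est.se == pytest.approx(weights.sum() ** -0.5, abs=1e-12)


def test_ivw_auto_switches_to_random_under_heterogeneity():
    # wildly inconsistent ratios with tiny SEs -> Q p < 0.05 -> random model
    hset = make_hset([0.2] * 4, [0.01] * 4, [0.02, 0.2, -0.15, 0.4], [0.001] * 4)
    est = ivw(hset, model="auto")
    assert est.extras["model"] == "random"
    assert est.se > ivw(hset, model="fixed").se
    # homogeneous data stays fixed
    hom = make_hset([0.2] * 4, [0.01] * 4, [0.04] * 4, [0.01] * 4)
    assert ivw(hom, model="auto").extras["model"] == "fixed"


def test_ivw_empty_set_raises():
    with pytest.raises(EstimationError):
        ivw(make_hset([], [], [], []))


# ------------------------------------------------------------------------ Egger

def test_egger_recovers_exact_line_from_noiseless_data():
    a, b = 0.013, -0.42
    x = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
    y = a + b * x
    hset = make_hset(x, [0.01] * 5, y, [0.01] * 5)
    est = egger(hset)
    assert est.beta == pytest.approx(b, abs=1e-10)
    assert est.extras["intercept"] == pytest.approx(a, abs=1e-10)


def test_egger_invariant_to_joint_reorientation_of_snps():
    rng = np.random.default_rng(3)
    x = rng.uniform(0.1, 0.5, 8)
    y = 0.01 + 0.3 * x + rng.normal(0, 0.01, 8)
    hset1 = make_hset(x, [0.02] * 8, y, [0.01] * 8)
    flip = np.array([1, -1, 1, -1, -1, 1, 1, -1.0])
    hset2 = make_hset(x * flip, [0.02] * 8, y * flip, [0.01] * 8)
    e1, e2 = egger(hset1), egger(hset2)
    assert e1.beta == pytest.approx(e2.beta, rel=1e-12)
    assert e1.extras["intercept"] == pytest.approx(e2.extras["intercept"], rel=1e-12)


def test_egger_needs_three_snps_and_varying_exposure_betas():
    with pytest.raises(InsufficientDataError):
        egger(make_hset([0.1, 0.2], [0.01] * 2, [0.1, 0.2], [0.01] * 2))
    with pytest.raises(EstimationError):
        egger(make_hset([0.2] * 4, [0.01] * 4, [0.1, 0.2, 0.3, 0.4], [0.01] * 4))


def test_egger_null_intercept_calibrated_under_no_pleiotropy(rng):
    """With balanced data (no directional pleiotropy) the intercept test
    should stay quiet in the vast majority of replicates."""
    hits = 0
    n_rep = 200
    for _ in range(n_rep):
        x = rng.uniform(0.1, 0.5, 30)
        sy = np.full(30, 0.01)
        y = rng.normal(0.3 * x, sy)
        est = egger(make_hset(x, [0.02] * 30, y, sy))
        hits += est.extras["intercept_p"] < 0.05
    assert hits <= 0.10 * n_rep


# -------------------------------------------------------------- weighted median

def test_equal_weights_reduce_to_simple_median():
    hset = make_hset([0.1] * 3, [0.01] * 3, [0.1, 0.2, 0.9], [0.02] * 3)
    est = weighted_median(hset, n_boot=50, seed=1)
    assert est.beta == pytest.approx(2.0)  # ratios {1, 2, 9} -> median 2


def test_identical_ratios_give_tiny_bootstrap_se():
    hset = make_hset([0.2] * 4, [1e-6] * 4, [0.06] * 4, [1e-6] * 4)
    est = weighted_median(hset, n_boot=100, seed=0)
    assert est.beta == pytest.approx(0.3)
    assert est.se < 1e-4


def test_weighted_median_matches_hand_computed_interpolation():
    # ratios {1,2,3,4}, weights {1,2,3,4}: percentiles 0.05,0.2,0.45,0.8;
    # interpolating 0.5 between (0.45, 3) and (0.8, 4) gives 3 + 0.05/0.35
    est = _weighted_median_point(
        np.array([1.0, 2.0, 3.0, 4.0]), np.array([1.0, 2.0, 3.0, 4.0])
    )
    assert est == pytest.approx(3.0 + 0.05 / 0.35, rel=1e-12)


def test_weighted_median_needs_three_snps():
    with pytest.raises(InsufficientDataError):
        weighted_median(make_hset([0.1], [0.01], [0.1], [0.01]))


# ------------------------------------------------------------------- mode-based

def test_mode_of_identical_ratios_is_the_common_value():
    hset = make_hset([0.2] * 4, [0.01] * 4, [0.08] * 4, [0.01] * 4)
    est = mode_based(hset, n_boot=20, seed=0)
    assert est.beta == pytest.approx(0.4)


def test_mode_picks_the_majority_cluster():
    # ratios {1,1,1,1,5} -> mode near 1, never the outlying 5
    hset = make_hset([0.1] * 5, [0.01] * 5, [0.1, 0.1, 0.1, 0.1, 0.5], [0.01] * 5)
    est = mode_based(hset, phi=1.0, weighted=False, n_boot=20, seed=0)
    assert 0.5 < est.beta < 1.5


def test_mode_stays_inside_ratio_range_for_any_bandwidth():
    hset = make_hset(
        [0.1] * 6, [0.01] * 6, [0.1, 0.12, 0.11, 0.5, 0.52, 0.1], [0.01] * 6
    )
    ratios = [r.beta_out / r.beta_exp for r in hset.retained]
    for phi in (0.25, 0.5, 1.0, 2.0, 4.0):
        est = mode_based(hset, phi=phi, n_boot=5, seed=0)
        assert min(ratios) <= est.beta <= max(ratios)


# ------------------------------------------------------------------------- RAPS

def test_raps_recovers_true_effect_within_three_se(rng):
    beta_true = 0.3
    j = 50
    x = rng.uniform(0.1, 0.5, j)
    sx = np.full(j, 0.02)
    sy = np.full(j, 0.01)
    xo = rng.normal(x, sx)
    yo = rng.normal(beta_true * x, sy)
    est = raps(make_hset(xo, sx, yo, sy), loss="l2", overdispersion=True)
    assert abs(est.beta - beta_true) < 3 * est.se
    assert est.extras["tau2"] < 5e-4  # no pleiotropy was simulated


def test_huber_loss_resists_gross_outliers_better_than_l2(rng):
    beta_true = 0.3
    j = 40
    x = rng.uniform(0.1, 0.5, j)
    sx = np.full(j, 0.01)
    sy = np.full(j, 0.01)
    y = rng.normal(beta_true * x, sy)
    y[:5] += 0.5  # five gross, directional outliers
    hset = make_hset(rng.normal(x, sx), sx, y, sy)
    bias_huber = abs(raps(hset, loss="huber").beta - beta_true)
    bias_l2 = abs(raps(hset, loss="l2").beta - beta_true)
    assert bias_huber < bias_l2


def test_raps_scale_equivariance():
    rng = np.random.default_rng(11)
    x = rng.uniform(0.1, 0.5, 20)
    y = rng.normal(0.3 * x, 0.01)
    h1 = make_hset(x, [0.02] * 20, y, [0.01] * 20)
    c = 3.7
    h2 = make_hset(c * x, [c * 0.02] * 20, c * y, [c * 0.01] * 20)
    assert raps(h2).beta == pytest.approx(raps(h1).beta, rel=1e-5)


def test_raps_needs_three_snps():
    with pytest.raises(InsufficientDataError):
        raps(make_hset([0.1, 0.2], [0.01] * 2, [0.1, 0.2], [0.01] * 2))


# ---------------------------------------------------------- shared invariants

def test_sign_equivariance_of_all_estimators(rng):
    hset = random_hset(rng, 12)
    neg = make_hset(
        [r.beta_exp for r in hset.retained],
        [r.se_exp for r in hset.retained],
        [-r.beta_out for r in hset.retained],
        [r.se_out for r in hset.retained],
    )
    assert ivw(neg).beta == pytest.approx(-ivw(hset).beta, rel=1e-12)
    assert egger(neg).beta == pytest.approx(-egger(hset).beta, rel=1e-10)
    assert weighted_median(neg, n_boot=10, seed=0).beta == pytest.approx(
        -weighted_median(hset, n_boot=10, seed=0).beta, rel=1e-12
    )
    assert mode_based(neg, n_boot=5, seed=0).beta == pytest.approx(
        -mode_based(hset, n_boot=5, seed=0).beta, rel=1e-9
    )
    assert raps(neg).beta == pytest.approx(-raps(hset).beta, rel=1e-4)


@settings(deadline=None, derandomize=True, max_examples=50)
@given(
    ratios=st.lists(st.floats(-5, 5), min_size=2, max_size=10),
    raw_weights=st.lists(st.floats(0.01, 100), min_size=10, max_size=10),
)
def test_pooled_estimates_lie_within_the_ratio_range(ratios, raw_weights):
    """IVW and the weighted median are convex combinations of the per-SNP
    ratios, so they can never leave [min ratio, max ratio]."""
    weights = np.array(raw_weights[: len(ratios)])
    r = np.array(ratios)
    from mrflow.estimators import ivw_from_ratios

    beta = ivw_from_ratios(r, weights, "fixed")[0]
    assert min(ratios) - 1e-12 <= beta <= max(ratios) + 1e-12
    wm = _weighted_median_point(r, weights)
    assert min(ratios) - 1e-12 <= wm <= max(ratios) + 1e-12


def test_only_ivw_is_defined_at_a_single_snp():
    hset = make_hset([0.2], [0.02], [0.04], [0.01])
    assert ivw(hset).beta == pytest.approx(0.2)
    for fn in (egger, weighted_median, mode_based, raps):
        with pytest.raises(InsufficientDataError):
            fn(hset)
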