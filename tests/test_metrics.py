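"""Per-cohort performance measures: oracles, identities, edge cases."""

import math
import subprocess

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit, logit

from pmvalsim import (
    CalibrationParams,
    LPDistribution,
    MiscalibrationFactor,
    NetBenefitSpec,
    ScenarioSpec,
    SmootherConfig,
    ValidationDataset,
    c_statistic,
    calibration_in_the_large,
    calibration_slope,
    generate_dataset,
    ici,
    net_benefit,
    oe_ratio,
    sigma_from_target_c,
    true_c_statistic,
)
from pmvalsim.metrics import Z95, net_benefit_components

DVT_LP = LPDistribution(-1.75, 1.47)


def dataset_from_lp(lp_values, outcomes):
    lp_values = np.asarray(lp_values, dtype=float)
    return ValidationDataset(
        lp_values=lp_values, pred_prob=expit(lp_values), outcomes=np.asarray(outcomes)
    )


def brute_force_auc(y, p):
    """Exhaustive all-pairs concordance count, ties at 1/2."""
    pos = p[y == 1]
    neg = p[y == 0]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))


# --------------------------------------------------------------------------
# C-statistic
# --------------------------------------------------------------------------

def test_c_statistic_single_concordant_pair():
    data = dataset_from_lp(logit([0.2, 0.8]), [0, 1])
    assert c_statistic(data).estimate == pytest.approx(1.0)


def test_c_statistic_all_tied_predictions():
    data = dataset_from_lp([0.3] * 10, [0, 1] * 5)
    assert c_statistic(data).estimate == pytest.approx(0.5)


def test_c_statistic_equals_brute_force_on_small_fixture():
    rng = np.random.default_rng(4)
    lp = rng.normal(-1.0, 1.0, 6)
    y = np.array([1, 1, 0, 0, 0, 0])
    data = dataset_from_lp(lp, y)
    assert c_statistic(data).estimate == pytest.approx(
        brute_force_auc(y, data.pred_prob), abs=1e-12
    )


@settings(max_examples=30, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000), n=st.integers(4, 200))
def test_c_statistic_matches_pairwise_oracle(seed, n):
    rng = np.random.default_rng(seed)
    lp = np.round(rng.normal(0, 1, n), 1)  # rounding forces ties
    y = rng.integers(0, 2, n)
    if y.min() == y.max():
        y[0] = 1 - y[0]
    data = dataset_from_lp(lp, y)
    assert c_statistic(data).estimate == pytest.approx(
        brute_force_auc(y, data.pred_prob), abs=1e-12
    )


def test_c_statistic_degenerate_outcomes_flagged():
    data = dataset_from_lp([0.1, 0.2, 0.3], [1, 1, 1])
    res = c_statistic(data)
    assert not res.converged and math.isnan(res.estimate)


def test_c_statistic_delong_matches_pROC(tmp_path, random_cohorts):
    """Estimate and DeLong SE agree with the pROC reference implementation."""
    data = random_cohorts[0]
    csv = tmp_path / "cohort.csv"
    data.to_csv(csv)
    script = (
        'suppressMessages(library(pROC));'
        f'd <- read.csv("{csv}");'
        'r <- roc(d$outcome, d$pred_prob, quiet=TRUE, direction="<");'
        'cat(sprintf("%.12f %.12f", as.numeric(auc(r)), sqrt(var(r))))'
    )
    out = subprocess.run(
        ["Rscript", "-e", script], capture_output=True, text=True, check=True
    )
    ref_auc, ref_se = map(float, out.stdout.split())
    res = c_statistic(data)
    assert res.estimate == pytest.approx(ref_auc, abs=1e-10)
    assert res.se == pytest.approx(ref_se, abs=1e-10)


# --------------------------------------------------------------------------
# Calibration slope / calibration-in-the-large
# --------------------------------------------------------------------------

def test_calibration_slope_recovers_generator_slope():
    for slope in (1.0, 0.9):
        spec = ScenarioSpec(
            lp=DVT_LP, calib=CalibrationParams(0.0, slope), n=200_000, seed=8
        )
        res = calibration_slope(generate_dataset(spec))
        assert res.converged
        assert res.estimate == pytest.approx(slope, abs=0.02)


def test_calibration_slope_zero_lp_variance_raises():
    data = dataset_from_lp([0.4] * 60, [0, 1] * 30)
    with pytest.raises(ValueError):
        calibration_slope(data)


def test_calibration_slope_separation_flagged():
    lp = np.linspace(-3, 3, 50)
    data = dataset_from_lp(lp, (lp > 0).astype(int))  # perfectly separated
    res = calibration_slope(data)
    assert not res.converged


def test_cal_in_large_recovers_generator_intercept():
    spec = ScenarioSpec(
        lp=DVT_LP, calib=CalibrationParams(0.5, 1.0), n=200_000, seed=8
    )
    res = calibration_in_the_large(generate_dataset(spec))
    assert res.estimate == pytest.approx(0.5, abs=0.02)


def test_cal_in_large_closed_form_degenerate_lp():
    # sigma=0: one-parameter logistic with constant offset mu has the
    # closed form intercept = logit(observed proportion) - mu
    mu = logit(0.3)
    y = np.array([1] * 27 + [0] * 73)
    data = dataset_from_lp([mu] * 100, y)
    res = calibration_in_the_large(data)
    assert res.estimate == pytest.approx(logit(0.27) - mu, abs=1e-6)


# --------------------------------------------------------------------------
# O/E ratio
# --------------------------------------------------------------------------

def test_oe_ratio_trivial_balanced():
    data = dataset_from_lp([0.0] * 10, [0, 1] * 5)
    assert oe_ratio(data).estimate == pytest.approx(1.0)


def test_oe_ratio_hand_computed_ci():
    # O = 0.2, mean predicted = 0.25, N = 100
    lp = np.full(100, logit(0.25))
    y = np.array([1] * 20 + [0] * 80)
    res = oe_ratio(dataset_from_lp(lp, y))
    se = math.sqrt(0.8 / 20)
    assert res.estimate == pytest.approx(0.8)
    assert res.se == pytest.approx(se)
    assert res.ci_lower == pytest.approx(0.8 * math.exp(-Z95 * se))
    assert res.ci_upper == pytest.approx(0.8 * math.exp(Z95 * se))
    assert res.log_ci_width == pytest.approx(2 * Z95 * se, abs=1e-10)


def test_oe_ratio_zero_events_flagged():
    data = dataset_from_lp([-2.0] * 30, [0] * 30)
    assert not oe_ratio(data).converged


# --------------------------------------------------------------------------
# ICI
# --------------------------------------------------------------------------

def test_ici_near_zero_when_perfectly_calibrated():
    spec = ScenarioSpec(lp=DVT_LP, n=20_000, seed=2)
    res = ici(generate_dataset(spec), SmootherConfig(n_boot=20))
    assert res.converged
    assert res.estimate < 0.01


def test_ici_matches_shift_distortion_oracle():
    # generator shifts the logit by delta; the ICI should approach the
    # average absolute risk distortion E|expit(LP+delta) - expit(LP)|
    delta = 0.5
    spec = ScenarioSpec(
        lp=DVT_LP, calib=CalibrationParams(delta, 1.0), n=30_000, seed=2
    )
    data = generate_dataset(spec)
    oracle = np.mean(np.abs(expit(data.lp_values + delta) - data.pred_prob))
    res = ici(data, SmootherConfig(n_boot=20))
    assert res.estimate == pytest.approx(oracle, abs=0.01)


def test_ici_requires_minimum_sample():
    spec = ScenarioSpec(lp=DVT_LP, n=30, seed=2)
    with pytest.raises(ValueError):
        ici(generate_dataset(spec))


def test_ici_percentile_ci_option(perfect_cohort):
    rng = np.random.default_rng(0)
    res = ici(perfect_cohort, SmootherConfig(n_boot=50, ci_method="percentile"), rng=rng)
    assert res.ci_lower <= res.estimate <= res.ci_upper


# --------------------------------------------------------------------------
# Net benefit
# --------------------------------------------------------------------------

def test_net_benefit_threshold_limits(perfect_cohort):
    prevalence = perfect_cohort.outcomes.mean()
    low = net_benefit(perfect_cohort, NetBenefitSpec(1e-9))
    assert low.estimate == pytest.approx(prevalence, abs=1e-9)
    high = net_benefit(perfect_cohort, NetBenefitSpec(0.999999))
    assert high.estimate == 0.0


@settings(max_examples=40, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000), pt=st.floats(0.01, 0.9))
def test_net_benefit_formula_equals_contribution_mean(seed, pt):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(10, 300))
    lp = rng.normal(-0.5, 1.5, n)
    y = rng.integers(0, 2, n)
    data = dataset_from_lp(lp, y)
    res = net_benefit(data, NetBenefitSpec(pt))
    sens, spec_, prev = net_benefit_components(data, NetBenefitSpec(pt))
    if prev in (0.0, 1.0):
        return
    formula = sens * prev - (1 - spec_) * (1 - prev) * pt / (1 - pt)
    assert res.estimate == pytest.approx(formula, abs=1e-12)


# --------------------------------------------------------------------------
# Population helpers
# --------------------------------------------------------------------------

def test_true_c_statistic_no_discrimination_when_sigma_zero():
    assert true_c_statistic(LPDistribution(0.3, 0.0)) == 0.5


def test_sigma_from_target_c_round_trip():
    for target in (0.6, 0.7, 0.8):
        sigma = sigma_from_target_c(target, lp_mu=logit(0.2), n_mc=300_000)
        back = true_c_statistic(
            LPDistribution(logit(0.2), sigma), n_mc=400_000, seed=123
        )
        assert back == pytest.approx(target, abs=0.005)


def test_sigma_from_target_c_rejects_invalid_target():
    with pytest.raises(ValueError):
        sigma_from_target_c(0.5, lp_mu=0.0)
    with pytest.raises(ValueError):
        sigma_from_target_c(1.0, lp_mu=0.0)


# --------------------------------------------------------------------------
# CI construction identities
# --------------------------------------------------------------------------

def test_ci_width_identity_on_original_scale(perfect_cohort):
    rng = np.random.default_rng(0)
    results = [
        c_statistic(perfect_cohort),
        calibration_slope(perfect_cohort),
        calibration_in_the_large(perfect_cohort),
        net_benefit(perfect_cohort, NetBenefitSpec(0.1)),
        ici(perfect_cohort, SmootherConfig(n_boot=30), rng=rng),
    ]
    for res in results:
        assert res.converged
        assert res.ci_lower <= res.estimate <= res.ci_upper
        assert res.ci_width == pytest.approx(2 * Z95 * res.se, abs=1e-10)
    oe = oe_ratio(perfect_cohort)
    assert oe.log_ci_width == pytest.approx(2 * Z95 * oe.se, abs=1e-10)
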