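import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from erndim import erp
from erndim.containers import DEFAULT_GRID, EpochSet

from conftest import make_epochs, make_waveform

CFG = erp.ScoringConfig()


# ----------------------------------------------------------- baseline


def test_baseline_removes_constant():
    epochs = make_epochs(np.array([[3.0]]))
    corrected = erp.baseline_correct(epochs, CFG)
    assert np.allclose(corrected.data, 0.0)


def test_baseline_identity_when_zero_mean():
    w = make_waveform({40.0: -5.0})  # zero in the baseline window
    corrected = erp.baseline_correct(make_epochs(w[None, :]), CFG)
    assert np.allclose(corrected.data[0], w)


def test_baseline_ramp_arithmetic():
    """Ramp uv(t) = t/100: baseline mean is −3 μV, so t=0 becomes +3 μV."""
    w = DEFAULT_GRID.times / 100.0
    corrected = erp.baseline_correct(make_epochs(w[None, :]), CFG)
    t0 = int(np.argmin(np.abs(DEFAULT_GRID.times)))
    assert corrected.data[0, t0] == pytest.approx(3.0, abs=1e-12)


# ----------------------------------------------------------- rejection


@pytest.mark.parametrize(
    "peak_uv,kept", [(51.0, False), (50.0, True), (49.9, True), (-50.0001, False)]
)
def test_rejection_boundary(peak_uv, kept):
    good = make_waveform({0.0: 1.0})
    bad = make_waveform({40.0: peak_uv})
    epochs = make_epochs(np.stack([good, bad]))
    surviving, n_rejected = erp.reject_epochs(epochs, CFG)
    assert surviving.n_epochs == (2 if kept else 1)
    assert n_rejected == (0 if kept else 1)


def test_rejection_all_epochs_fails_loudly():
    epochs = make_epochs(make_waveform({40.0: 60.0})[None, :])
    with pytest.raises(erp.NoSurvivingEpochsError):
        erp.reject_epochs(epochs, CFG)


# ----------------------------------------------------------- averaging


def test_average_single_epoch_is_identity():
    w = make_waveform({40.0: -5.0, -100.0: 2.0})
    assert np.array_equal(erp.average_epochs(make_epochs(w[None, :])), w)


def test_average_symmetry_cancels():
    w = make_waveform({40.0: -5.0})
    avg = erp.average_epochs(make_epochs(np.stack([w, -w])))
    assert np.allclose(avg, 0.0)


# ----------------------------------------------------------- scoring


def test_adaptive_mean_single_spike():
    w = make_waveform({40.0: -5.0})
    est = erp.adaptive_mean(w, CFG)
    assert est.peak_latency_ms == 40.0
    assert est.value_uv == pytest.approx(-5.0 / 21.0, abs=1e-12)


def test_adaptive_mean_constant_earliest_tie():
    est = erp.adaptive_mean(np.full(DEFAULT_GRID.n_samples, -2.0), CFG)
    assert est.peak_latency_ms == -20.0
    assert est.value_uv == pytest.approx(-2.0, abs=1e-12)


def test_adaptive_mean_ramp():
    """Linear ramp −t/10: peak at 120 ms, windowed mean equals the centre
    value −12 μV by linearity."""
    est = erp.adaptive_mean(-DEFAULT_GRID.times / 10.0, CFG)
    assert est.peak_latency_ms == 120.0
    assert est.value_uv == pytest.approx(-12.0, abs=1e-12)


def test_window_mean_single_spike():
    w = make_waveform({40.0: -5.0})
    est = erp.window_mean(w, CFG)
    assert est.value_uv == pytest.approx(-5.0 / 26.0, abs=1e-12)


def test_min_amplitude_single_spike():
    est = erp.min_amplitude(make_waveform({40.0: -5.0}), CFG)
    assert est.value_uv == -5.0
    assert est.peak_latency_ms == 40.0


def test_trough_to_peak_subtraction():
    w = make_waveform({-52.0: 2.0, 40.0: -5.0})
    est = erp.trough_to_peak(w, CFG)
    assert est.value_uv == pytest.approx(-7.0, abs=1e-12)


def test_flat_waveform_scores_zero_everywhere():
    w = np.zeros(DEFAULT_GRID.n_samples)
    for method in erp.METHODS:
        assert erp.score_waveform(w, CFG, method).value_uv == 0.0


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_min_amplitude_bounds_adaptive_mean(seed):
    """The mean around the minimum can never lie below the minimum."""
    rng = np.random.default_rng(seed)
    w = rng.normal(0, 5, DEFAULT_GRID.n_samples)
    assert erp.min_amplitude(w, CFG).value_uv <= erp.adaptive_mean(w, CFG).value_uv + 1e-12


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_scoring_invariant_to_epoch_order(seed):
    rng = np.random.default_rng(seed)
    data = rng.normal(0, 5, (7, DEFAULT_GRID.n_samples))
    a = erp.score_epochs(make_epochs(data), CFG)
    b = erp.score_epochs(make_epochs(data[::-1]), CFG)
    assert a.value_uv == pytest.approx(b.value_uv, abs=1e-12)


# ------------------------------------------------------ residualisation


def test_residualise_constant_crn_centers_ern():
    cohort = [
        erp.SubjectERP(f"s{i}", erp.AmplitudeEstimate(v, "adaptive_mean"),
                       erp.AmplitudeEstimate(1.0, "adaptive_mean"))
        for i, v in enumerate([-1.0, -3.0, -5.0])
    ]
    with pytest.warns(UserWarning):
        erp.residualise_ern(cohort)
    resid = np.array([s.ern_resid_uv for s in cohort])
    assert np.allclose(resid, [2.0, 0.0, -2.0])


def test_residualise_perfect_fit_zeroes():
    crn = [0.1, 0.5, -0.2, 0.8, 0.3]
    cohort = [
        erp.SubjectERP(f"s{i}", erp.AmplitudeEstimate(2.0 * c, "adaptive_mean"),
                       erp.AmplitudeEstimate(c, "adaptive_mean"))
        for i, c in enumerate(crn)
    ]
    erp.residualise_ern(cohort)
    assert np.allclose([s.ern_resid_uv for s in cohort], 0.0, atol=1e-12)


def test_residualise_matches_ols_oracle():
    rng = np.random.default_rng(5)
    crn = rng.normal(0.3, 1.9, 5)
    ern = -3 + 0.7 * crn + rng.normal(0, 1, 5)
    cohort = [
        erp.SubjectERP(f"s{i}", erp.AmplitudeEstimate(e, "adaptive_mean"),
                       erp.AmplitudeEstimate(c, "adaptive_mean"))
        for i, (e, c) in enumerate(zip(ern, crn))
    ]
    erp.residualise_ern(cohort)
    slope, intercept = np.polyfit(crn, ern, 1)  # independent OLS oracle
    expected = ern - (intercept + slope * crn)
    resid = np.array([s.ern_resid_uv for s in cohort])
    assert np.allclose(resid, expected, atol=1e-10)
    assert abs(resid.sum()) < 1e-10
    assert abs(np.corrcoef(resid, crn)[0, 1]) < 1e-12


def test_delta_ern_identity():
    s = erp.SubjectERP("s1", erp.AmplitudeEstimate(-3.2, "adaptive_mean"),
                       erp.AmplitudeEstimate(0.4, "adaptive_mean"))
    assert s.delta_ern_uv == -3.2 - 0.4


# ---------------------------------------------------------- reliability


def test_split_half_perfect_when_halves_identical():
    rng = np.random.default_rng(0)
    cohort = {}
    for i in range(5):
        w = rng.normal(0, 3, DEFAULT_GRID.n_samples)
        cohort[f"s{i}"] = make_epochs(np.stack([w, w, w, w]), subject=f"s{i}")
    rel = erp.split_half_reliability(cohort, CFG)
    assert rel["r_half"] == pytest.approx(1.0, abs=1e-12)
    assert rel["r_sb"] == pytest.approx(1.0, abs=1e-12)


def test_split_half_needs_three_subjects():
    cohort = {f"s{i}": make_epochs(np.zeros((2, DEFAULT_GRID.n_samples))) for i in range(2)}
    with pytest.raises(ValueError):
        erp.split_half_reliability(cohort, CFG)


@pytest.mark.parametrize("r_half,expected", [(0.5, 2 / 3), (0.8182, 0.9000)])
def test_spearman_brown_values(r_half, expected):
    assert erp.spearman_brown(r_half) == pytest.approx(expected, abs=1e-4)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.floats(min_value=-0.99, max_value=0.99), st.floats(min_value=-0.99, max_value=0.99))
def test_spearman_brown_monotone_with_fixed_points(a, b):
    lo, hi = sorted((a, b))
    assert erp.spearman_brown(lo) <= erp.spearman_brown(hi) + 1e-12
    assert erp.spearman_brown(0.0) == 0.0
    assert erp.spearman_brown(1.0) == 1.0
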