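import numpy as np
import pandas as pd
import pytest

from erndim import screening

from conftest import make_behaviour


def _report(n_missed=96, n_errors=150, catch="A little", survival=0.96):
    beh = make_behaviour(n_missed=n_missed, n_errors=n_errors)
    return screening.apply_exclusions(beh, survival, catch)


def test_boundary_subject_retained():
    """96 missed, 56% accuracy, correct catch, 96% survival: all strict
    comparators pass and the subject stays in."""
    beh = make_behaviour(n_missed=96, n_errors=168)  # 216/384 correct = 0.5625
    r = screening.apply_exclusions(beh, 0.96, "A little")
    assert not r.excluded and r.flags == set()


@pytest.mark.parametrize(
    "kwargs,flag",
    [
        (dict(n_missed=97), "missed_gt_20pct"),
        (dict(n_errors=180), "accuracy_lt_55"),  # 204/384 = 0.53
        (dict(catch="Not at all"), "catch_failed"),
        (dict(survival=0.94), "epoch_survival_lt_95"),
    ],
)
def test_single_rule_violations_excluded(kwargs, flag):
    base = dict(n_missed=96, n_errors=168, catch="A little", survival=0.96)
    base.update(kwargs)
    beh = make_behaviour(n_missed=base["n_missed"], n_errors=base["n_errors"])
    r = screening.apply_exclusions(beh, base["survival"], base["catch"])
    assert r.excluded and r.flags == {flag}


def test_exact_survival_boundary_retained():
    assert not _report(survival=0.95).excluded


def test_corrupted_flag_passthrough():
    beh = make_behaviour()
    r = screening.apply_exclusions(beh, 0.99, "A little", corrupted=True)
    assert r.excluded and r.first_failed == "corrupted"


def test_exclusion_monotone_in_missed_trials():
    """Adding missed trials can never un-exclude a subject."""
    excluded_before = False
    for n_missed in range(90, 110):
        r = _report(n_missed=n_missed, n_errors=100)
        if excluded_before:
            assert r.excluded
        excluded_before = r.excluded


def test_behaviour_summary_toy_arithmetic():
    """Hand-computed means on a 6-trial table."""
    df = pd.DataFrame(
        {
            "subject": "s001",
            "block": [1, 1, 1, 2, 2, 2],
            "trial": [1, 2, 3, 1, 2, 3],
            "congruency": ["congruent", "incongruent", "incongruent",
                           "congruent", "incongruent", "incongruent"],
            "target": "left",
            "response": ["left", "right", "left", "left", "missed", "left"],
            "rt_ms": [200.0, 250.0, 300.0, 220.0, np.nan, 280.0],
            "correct": [1.0, 0.0, 1.0, 1.0, np.nan, 1.0],
            "missed": [0, 0, 0, 0, 1, 0],
        }
    )
    s = screening.behaviour_summary(df)
    assert s["error_rate"] == pytest.approx(1 / 5)
    assert s["error_rate_congruent"] == 0.0
    assert s["error_rate_incongruent"] == pytest.approx(1 / 3)
    assert s["rt_mean_ms"] == pytest.approx((200 + 250 + 300 + 220 + 280) / 5)
    assert s["rt_mean_error"] == 250.0
    assert s["rt_mean_correct"] == pytest.approx((200 + 300 + 220 + 280) / 4)
    # post-error: only trial 3 of block 1 follows the error at trial 2
    assert s["rt_post_error"] == 300.0
    # post-correct: block-1 trial 2; block-2 trial 2 is missed, and block-2
    # trial 3 follows a missed trial so it is dropped from the strata
    assert s["rt_post_correct"] == 250.0


def test_behaviour_summary_empty_stratum_warns():
    df = make_behaviour(n_trials=20, n_errors=0)
    with pytest.warns(UserWarning, match="post_error"):
        s = screening.behaviour_summary(df)
    assert np.isnan(s["rt_post_error"])


def test_behaviour_summary_constant_rts():
    df = make_behaviour(n_trials=30, n_errors=5, rt_ms=333.0)
    s = screening.behaviour_summary(df)
    for key in ("rt_mean_ms", "rt_mean_error", "rt_mean_correct",
                "rt_post_error", "rt_post_correct"):
        assert s[key] == 333.0


def test_paired_contrast_matches_closed_form():
    """N = 4 paired t computed from the textbook formula."""
    a = np.array([0.2, 0.3, 0.25, 0.4])
    b = np.array([0.1, 0.15, 0.2, 0.1])
    d = a - b
    t_expected = d.mean() / (d.std(ddof=1) / np.sqrt(4))
    df = pd.DataFrame({"error_rate_incongruent": a, "error_rate_congruent": b})
    res = screening.paired_contrasts(df).set_index("contrast")
    row = res.loc["error_rate_incongruent_vs_congruent"]
    assert row["t"] == pytest.approx(t_expected, abs=1e-10)
    assert row["df"] == 3
    assert row["ci_low"] < d.mean() < row["ci_high"]


def test_paired_contrast_zero_variance_edge():
    df = pd.DataFrame({"rt_mean_error": [1.0, 2.0, 3.0],
                       "rt_mean_correct": [1.0, 2.0, 3.0]})
    with pytest.warns(UserWarning):
        res = screening.paired_contrasts(df).set_index("contrast")
    row = res.loc["rt_error_vs_correct"]
    assert row["t"] == 0.0 and row["p"] == 1.0


def test_exclusion_log_accounting():
    reports = [
        _report(),                       # retained
        _report(n_missed=97),            # missed rule
        _report(catch="wrong"),          # catch rule
        _report(n_missed=97, catch="wrong"),  # first failed: missed
    ]
    log = screening.exclusion_log(reports)
    assert log["n_total"] == 4
    assert log["n_excluded"] == 3
    assert log["excluded_per_rule"]["missed_gt_20pct"] == 2
    assert log["excluded_per_rule"]["catch_failed"] == 1
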