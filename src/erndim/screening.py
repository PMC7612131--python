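"""Exclusion cascade and behavioural summaries for the flanker cohort.

Exclusion rules (evaluated in the published order, each with the printed
strict comparator): corrupted/incomplete EEG; fewer than 95% of
error-locked epochs surviving the ±50 μV criterion; more than 96 missed
trials (>20% of 480); accuracy below 55%; wrong answer to the embedded
catch question ("A little").  Behavioural summaries are computed over
non-missed trials only.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import erp
from .containers import EpochSet

MISSED_TRIAL_LIMIT = 96  # >20% of 480
ACCURACY_FLOOR = 0.55
CATCH_ANSWER = "A little"
EPOCH_SURVIVAL_FLOOR = 0.95

#: rule evaluation order as published
RULE_ORDER = (
    "corrupted",
    "epoch_survival_lt_95",
    "missed_gt_20pct",
    "accuracy_lt_55",
    "catch_failed",
)


@dataclass
class ExclusionReport:
    subject_id: str
    flags: set[str] = field(default_factory=set)
    order_applied: tuple[str, ...] = RULE_ORDER
    first_failed: str | None = None

    @property
    def excluded(self) -> bool:
        return bool(self.flags)


def _epoch_survival(epochs: EpochSet, cfg: erp.ScoringConfig) -> float:
    corrected = erp.baseline_correct(epochs, cfg)
    try:
        surviving, n_rejected = erp.reject_epochs(corrected, cfg)
        return surviving.n_epochs / epochs.n_epochs
    except erp.NoSurvivingEpochsError:
        return 0.0


def apply_exclusions(
    behaviour: pd.DataFrame,
    epochs: EpochSet | float | None,
    catch_response: str,
    corrupted: bool = False,
    cfg: erp.ScoringConfig = erp.ScoringConfig(),
) -> ExclusionReport:
    """Evaluate the exclusion cascade for one subject.

    ``epochs`` is the subject's error-locked EpochSet (survival is computed
    by running the ±50 μV rejection) or a precomputed survival fraction;
    None skips the rule.  ``corrupted`` is an input flag — corruption is
    not detected from raw files.
    """
    sid = str(behaviour["subject"].iloc[0]) if "subject" in behaviour else "unknown"
    report = ExclusionReport(subject_id=sid)

    if isinstance(epochs, EpochSet):
        survival = _epoch_survival(epochs, cfg)
    else:
        survival = epochs

    n_missed = int(behaviour["missed"].sum())
    responded = behaviour.loc[behaviour["missed"] == 0, "correct"]
    accuracy = float(responded.mean()) if len(responded) else 0.0

    checks = {
        "corrupted": corrupted,
        "epoch_survival_lt_95": survival is not None and survival < EPOCH_SURVIVAL_FLOOR,
        "missed_gt_20pct": n_missed > MISSED_TRIAL_LIMIT,
        "accuracy_lt_55": accuracy < ACCURACY_FLOOR,
        "catch_failed": catch_response != CATCH_ANSWER,
    }
    for rule in RULE_ORDER:
        if checks[rule]:
            report.flags.add(rule)
            if report.first_failed is None:
                report.first_failed = rule
    return report


def behaviour_summary(behaviour: pd.DataFrame) -> dict[str, float]:
    """Per-subject behavioural summary over non-missed trials.

    Post-error/post-correct strata classify trial t by the correctness of
    trial t−1 within the same block; trials following a missed trial and
    the first trial of each block are dropped from those strata.  An empty
    stratum yields NaN with a warning.
    """
    df = behaviour.reset_index(drop=True)
    ok = df["missed"] == 0
    if not ok.any():
        raise ValueError("no non-missed trials")
    correct = df["correct"] == 1
    error = ok & ~correct
    incong = df["congruency"] == "incongruent"
    rt = df["rt_ms"]

    prev_ok = ok.shift(1, fill_value=False)
    same_block = df["block"] == df["block"].shift(1)
    prev_correct = correct.shift(1, fill_value=False)
    post_correct = ok & prev_ok & same_block & prev_correct
    post_error = ok & prev_ok & same_block & ~prev_correct

    def _rate(mask_err: pd.Series, mask_all: pd.Series) -> float:
        n = int((ok & mask_all).sum())
        return float((mask_err & mask_all).sum() / n) if n else np.nan

    def _mean_rt(mask: pd.Series, name: str) -> float:
        if not mask.any():
            warnings.warn(f"empty stratum: {name}")
            return np.nan
        return float(rt[mask].mean())

    all_trials = pd.Series(True, index=df.index)
    return {
        "error_rate": _rate(error, all_trials),
        "error_rate_congruent": _rate(error, ~incong),
        "error_rate_incongruent": _rate(error, incong),
        "rt_mean_ms": _mean_rt(ok, "all"),
        "rt_mean_congruent": _mean_rt(ok & ~incong, "congruent"),
        "rt_mean_incongruent": _mean_rt(ok & incong, "incongruent"),
        "rt_mean_error": _mean_rt(error, "error"),
        "rt_mean_correct": _mean_rt(ok & correct, "correct"),
        "rt_post_error": _mean_rt(post_error, "post_error"),
        "rt_post_correct": _mean_rt(post_correct, "post_correct"),
    }


#: (name, column A, column B) paired contrasts reported for the cohort
CONTRASTS = (
    ("error_rate_incongruent_vs_congruent", "error_rate_incongruent", "error_rate_congruent"),
    ("rt_congruent_vs_incongruent", "rt_mean_congruent", "rt_mean_incongruent"),
    ("rt_error_vs_correct", "rt_mean_error", "rt_mean_correct"),
    ("rt_post_error_vs_post_correct", "rt_post_error", "rt_post_correct"),
    ("ern_vs_crn", "ern_uv", "crn_uv"),
)


def paired_contrasts(cohort_summaries: pd.DataFrame) -> pd.DataFrame:
    """Paired t-tests (A − B) for the standard cohort contrasts.

    Reports t, df = N−1, the 95% CI of the mean difference and the
    two-sided p for every contrast whose columns are present.  Zero
    variance of the differences is reported as a no-difference edge case
    with a warning.
    """
    if len(cohort_summaries) < 3:
        raise ValueError("paired contrasts need at least 3 subjects")
    rows = []
    for name, col_a, col_b in CONTRASTS:
        if col_a not in cohort_summaries or col_b not in cohort_summaries:
            continue
        pair = cohort_summaries[[col_a, col_b]].dropna()
        diff = (pair[col_a] - pair[col_b]).to_numpy()
        n = len(diff)
        df = n - 1
        sd = diff.std(ddof=1)
        if sd == 0.0:
            warnings.warn(f"zero-variance differences for {name}")
            mean = float(diff.mean())
            rows.append(
                {
                    "contrast": name, "t": 0.0 if mean == 0 else np.inf * np.sign(mean),
                    "df": df, "ci_low": mean, "ci_high": mean,
                    "p": 1.0 if mean == 0 else 0.0, "mean_diff": mean,
                }
            )
            continue
        t, p = stats.ttest_rel(pair[col_a], pair[col_b])
        se = sd / np.sqrt(n)
        half = stats.t.ppf(0.975, df) * se
        rows.append(
            {
                "contrast": name, "t": float(t), "df": df,
                "ci_low": float(diff.mean() - half), "ci_high": float(diff.mean() + half),
                "p": float(p), "mean_diff": float(diff.mean()),
            }
        )
    return pd.DataFrame(rows)


def exclusion_log(reports: list[ExclusionReport]) -> dict:
    """Cohort accounting: subjects excluded per (first-failed) rule."""
    counts = {rule: 0 for rule in RULE_ORDER}
    for r in reports:
        if r.first_failed is not None:
            counts[r.first_failed] += 1
    return {
        "n_total": len(reports),
        "n_excluded": sum(1 for r in reports if r.excluded),
        "n_retained": sum(1 for r in reports if not r.excluded),
        "excluded_per_rule": counts,
    }


def write_exclusion_log(reports: list[ExclusionReport], path) -> None:
    with open(path, "w") as f:
        json.dump(exclusion_log(reports), f, indent=2)
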