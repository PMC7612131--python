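import numpy as np
import pandas as pd
import pytest

from erndim.containers import DEFAULT_GRID, EpochSet


@pytest.fixture
def grid():
    return DEFAULT_GRID


def make_waveform(values_by_time_ms: dict[float, float]) -> np.ndarray:
    """Waveform of zeros with specified μV values at given times."""
    w = np.zeros(DEFAULT_GRID.n_samples)
    t = DEFAULT_GRID.times
    for ms, uv in values_by_time_ms.items():
        idx = int(np.argmin(np.abs(t - ms)))
        assert abs(t[idx] - ms) < 1e-9, f"{ms} ms is not on the grid"
        w[idx] = uv
    return w


def make_epochs(rows: np.ndarray, subject="s001", condition="error") -> EpochSet:
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    if rows.shape[1] != DEFAULT_GRID.n_samples:
        rows = np.tile(rows, (1, DEFAULT_GRID.n_samples))
    return EpochSet(subject_id=subject, condition=condition, data=rows)


def make_behaviour(
    n_trials: int = 480,
    n_missed: int = 0,
    n_errors: int = 0,
    rt_ms: float = 300.0,
    subject: str = "s001",
) -> pd.DataFrame:
    """Minimal behaviour table: first n_missed trials missed, next
    n_errors trials erroneous, the rest correct."""
    half = n_trials // 2
    congr = np.where(np.arange(n_trials) % 3 == 0, "congruent", "incongruent")
    df = pd.DataFrame(
        {
            "subject": subject,
            "block": np.repeat([1, 2], [half, n_trials - half]),
            "trial": np.concatenate([np.arange(1, half + 1), np.arange(1, n_trials - half + 1)]),
            "congruency": congr,
            "target": "left",
        }
    )
    missed = np.zeros(n_trials, dtype=int)
    missed[:n_missed] = 1
    correct = np.ones(n_trials, dtype=float)
    correct[n_missed : n_missed + n_errors] = 0.0
    correct[missed == 1] = np.nan
    df["response"] = np.where(missed == 1, "missed", np.where(correct == 0, "right", "left"))
    df["rt_ms"] = np.where(missed == 1, np.nan, rt_ms)
    df["correct"] = correct
    df["missed"] = missed
    return df
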