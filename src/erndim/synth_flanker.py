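"""Flanker-task schedules and simulated per-trial behaviour.

The task is the speeded arrow flanker: two blocks of 240 trials each
(80 congruent, 160 incongruent per block; 480 total), a 1050 ms response
deadline, and end-of-block feedback chosen from the miss rate and accuracy.
The behaviour generator reproduces the qualitative effects expected of the
task: more errors on incongruent trials, faster errors than correct
responses, slower responses on incongruent trials, and post-error slowing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

N_BLOCKS = 2
TRIALS_PER_BLOCK = 240
CONGRUENT_PER_BLOCK = 80
INCONGRUENT_PER_BLOCK = 160
N_TRIALS = N_BLOCKS * TRIALS_PER_BLOCK
RESPONSE_DEADLINE_MS = 1050.0

#: lower bound of the shifted log-normal RT distribution (ms)
RT_SHIFT_MS = 100.0


@dataclass(frozen=True)
class BehaviourParams:
    """Parameters of the behaviour generator.

    Defaults mimic the observed cohort means: error rates of ~3.6% on
    congruent and ~15.6% on incongruent trials, ~2.4% missed trials,
    correct/error mean RTs of 283/212 ms with SD ~68 ms, a ~62 ms
    congruency slowing and ~20 ms post-error slowing.
    """

    p_error_congruent: float = 0.036
    p_error_incongruent: float = 0.156
    p_miss: float = 0.024
    rt_mean_correct_ms: float = 283.0
    rt_mean_error_ms: float = 212.0
    rt_sd_ms: float = 67.6
    post_error_slowing_ms: float = 20.0
    congruency_rt_effect_ms: float = 62.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_error_congruent", "p_error_incongruent", "p_miss"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.rt_sd_ms <= 0:
            raise ValueError("rt_sd_ms must be positive")


def generate_schedule(seed: int) -> pd.DataFrame:
    """Build a randomly ordered task schedule.

    Returns a frame with columns ``block`` (1|2), ``trial`` (1-based within
    block), ``congruency`` ('congruent'|'incongruent') and ``target``
    ('left'|'right').  Each block holds exactly 80 congruent and 160
    incongruent trials in uniformly shuffled order.
    """
    rng = np.random.default_rng(seed)
    blocks = []
    for block in range(1, N_BLOCKS + 1):
        congruency = np.array(
            ["congruent"] * CONGRUENT_PER_BLOCK + ["incongruent"] * INCONGRUENT_PER_BLOCK
        )
        rng.shuffle(congruency)
        target = rng.choice(["left", "right"], size=TRIALS_PER_BLOCK)
        blocks.append(
            pd.DataFrame(
                {
                    "block": block,
                    "trial": np.arange(1, TRIALS_PER_BLOCK + 1),
                    "congruency": congruency,
                    "target": target,
                }
            )
        )
    return pd.concat(blocks, ignore_index=True)


def _lognormal_rts(rng: np.random.Generator, means_ms: np.ndarray, sd_ms: float) -> np.ndarray:
    """Draw shifted log-normal RTs with given per-trial means and common SD."""
    m = np.maximum(means_ms - RT_SHIFT_MS, 1.0)
    sigma2 = np.log1p(sd_ms**2 / m**2)
    mu = np.log(m) - sigma2 / 2.0
    return RT_SHIFT_MS + rng.lognormal(mean=mu, sigma=np.sqrt(sigma2))


def simulate_behaviour(schedule: pd.DataFrame, params: BehaviourParams) -> pd.DataFrame:
    """Simulate responses, RTs and misses for one subject on a schedule.

    Error probability depends on congruency only; error-trial RTs are drawn
    with a faster mean; trials following an error (within block) receive
    the post-error slowing increment; RTs exceeding the 1050 ms deadline
    are converted to misses, as are random lapses at ``p_miss``.
    """
    rng = np.random.default_rng(params.seed)
    df = schedule.reset_index(drop=True).copy()
    n = len(df)
    incong = (df["congruency"] == "incongruent").to_numpy()
    p_err = np.where(incong, params.p_error_incongruent, params.p_error_congruent)
    is_error = rng.random(n) < p_err
    lapse = rng.random(n) < params.p_miss

    # post-error: previous trial in the same block was a committed error
    prev_error = np.zeros(n, dtype=bool)
    prev_error[1:] = is_error[:-1] & ~lapse[:-1]
    same_block = np.ones(n, dtype=bool)
    same_block[1:] = df["block"].to_numpy()[1:] == df["block"].to_numpy()[:-1]
    post_error = prev_error & same_block

    means = np.where(is_error, params.rt_mean_error_ms, params.rt_mean_correct_ms).astype(float)
    means += np.where(incong, 0.5, -0.5) * params.congruency_rt_effect_ms
    means += post_error * params.post_error_slowing_ms
    rt = _lognormal_rts(rng, means, params.rt_sd_ms)

    missed = lapse | (rt > RESPONSE_DEADLINE_MS)
    target = df["target"].to_numpy()
    other = np.where(target == "left", "right", "left")
    response = np.where(is_error, other, target)
    response = np.where(missed, "missed", response)

    df["response"] = response
    df["rt_ms"] = np.where(missed, np.nan, rt)
    df["correct"] = np.where(missed, np.nan, (~is_error).astype(float))
    df["missed"] = missed.astype(int)
    return df


def block_feedback(block_stats: dict) -> str:
    """End-of-block feedback message category.

    ``faster`` when more than 25% of trials were missed or accuracy exceeded
    90%; otherwise ``more_accurate`` when accuracy fell below 75%; otherwise
    ``great_job``.  The speed message takes precedence when both apply.
    """
    missed_pct = block_stats["missed_pct"]
    accuracy = block_stats["accuracy"]
    if not (0.0 <= missed_pct <= 1.0 and 0.0 <= accuracy <= 1.0):
        raise ValueError("missed_pct and accuracy must lie in [0, 1]")
    if missed_pct > 0.25 or accuracy > 0.90:
        return "faster"
    if accuracy < 0.75:
        return "more_accurate"
    return "great_job"


def behaviour_to_csv(df: pd.DataFrame, path, subject: str = "s01") -> None:
    """Write a behaviour table in the standard long CSV layout."""
    out = df.copy()
    out.insert(0, "subject", subject)
    out.to_csv(path, index=False, float_format="%.3f")
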