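"""Hybrid model-based / model-free agents on the two-step task.

The task: a first-stage binary choice leads to one of two second stages
through fixed probabilistic transitions (common 70% / rare 30%); each
second-stage option pays out with a probability performing a bounded
Gaussian random walk.  The agent is the canonical hybrid: SARSA(λ)
model-free values mixed with model-based values (transition matrix ×
best second-stage value) by weight w_mb, softmax choice with
perseveration.  Pure model-based agents (w_mb = 1) show the classic
reward × transition interaction in stay behaviour; pure model-free agents
(w_mb = 0) show a reward main effect instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synth_cohort import DIMENSIONS, default_factor_corr


@dataclass(frozen=True)
class TwoStepConfig:
    n_trials: int = 200
    p_common: float = 0.70
    reward_walk_bounds: tuple[float, float] = (0.25, 0.75)
    reward_walk_sd: float = 0.025

    def __post_init__(self) -> None:
        if not 0.0 < self.p_common < 1.0:
            raise ValueError("p_common must lie in (0, 1)")
        lo, hi = self.reward_walk_bounds
        if not 0.0 <= lo < hi <= 1.0:
            raise ValueError("reward_walk_bounds must satisfy 0 <= lo < hi <= 1")

    @property
    def p_rare(self) -> float:
        return 1.0 - self.p_common


@dataclass(frozen=True)
class AgentParams:
    w_mb: float = 0.5
    alpha1: float = 0.5
    alpha2: float = 0.5
    lam: float = 0.6
    beta1: float = 4.0
    beta2: float = 4.0
    stickiness: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("w_mb", "alpha1", "alpha2", "lam"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.beta1 < 0 or self.beta2 < 0:
            raise ValueError("inverse temperatures must be non-negative")


def _softmax_choice(rng: np.random.Generator, logits: np.ndarray) -> int:
    v = logits - logits.max()
    p = np.exp(v)
    p /= p.sum()
    return int(rng.random() < p[1])


def simulate_agent(
    cfg: TwoStepConfig,
    params: AgentParams,
    subject_id: str = "s001",
    initial_q2: np.ndarray | None = None,
    freeze_q2: bool = False,
    return_walk: bool = False,
) -> pd.DataFrame:
    """Simulate one agent; returns a per-trial frame.

    Columns: trial, choice1 (0|1), transition ('common'|'rare'), state2
    (0|1), choice2 (0|1), reward (0|1).  ``initial_q2`` (2×2) sets the
    starting second-stage values; ``freeze_q2`` disables their update
    (useful for closed-form choice checks).  Deterministic given
    ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    lo, hi = cfg.reward_walk_bounds
    p_reward = rng.uniform(lo, hi, size=(2, 2))
    q_mf1 = np.zeros(2)
    q2 = np.zeros((2, 2)) if initial_q2 is None else np.array(initial_q2, dtype=float)
    prev_choice1: int | None = None
    rows = []
    walk_trace = []
    for t in range(cfg.n_trials):
        # model-based first-stage values from the known transition matrix:
        # action a commonly reaches state a
        best2 = q2.max(axis=1)
        q_mb = cfg.p_common * best2 + cfg.p_rare * best2[::-1]
        q_net = params.w_mb * q_mb + (1.0 - params.w_mb) * q_mf1
        rep = np.zeros(2)
        if prev_choice1 is not None:
            rep[prev_choice1] = 1.0
        c1 = _softmax_choice(rng, params.beta1 * q_net + params.stickiness * rep)
        common = rng.random() < cfg.p_common
        s2 = c1 if common else 1 - c1
        c2 = _softmax_choice(rng, params.beta2 * q2[s2])
        reward = int(rng.random() < p_reward[s2, c2])

        # SARSA(λ) model-free updates
        delta1 = q2[s2, c2] - q_mf1[c1]
        q_mf1[c1] += params.alpha1 * delta1
        delta2 = reward - q2[s2, c2]
        if not freeze_q2:
            q2[s2, c2] += params.alpha2 * delta2
        q_mf1[c1] += params.alpha1 * params.lam * delta2

        rows.append(
            {
                "subject": subject_id,
                "trial": t + 1,
                "choice1": c1,
                "transition": "common" if common else "rare",
                "state2": s2,
                "choice2": c2,
                "reward": reward,
            }
        )
        prev_choice1 = c1
        if return_walk:
            walk_trace.append(p_reward.copy())
        # drifting reward probabilities, clipped at the bounds
        p_reward += rng.normal(0.0, cfg.reward_walk_sd, size=(2, 2))
        p_reward = np.clip(p_reward, lo, hi)
    df = pd.DataFrame(rows)
    if return_walk:
        return df, np.array(walk_trace)
    return df


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def simulate_cohort(
    cfg: TwoStepConfig,
    n_subjects: int,
    coupling: dict | None = None,
    seed: int = 0,
    dimension_scores: pd.DataFrame | None = None,
) -> dict[str, pd.DataFrame]:
    """Simulate a cohort of agents, optionally coupling w_mb to a dimension.

    ``coupling = {"dimension": "CIT", "slope": -0.5, "base": 0.0}`` sets
    per-subject w_mb = logistic(base + slope · z(dimension)).  Dimension
    scores are drawn from the default correlated factor model when not
    supplied.  Returns {"trials", "truth"}; truth holds per-subject agent
    parameters and dimension scores.
    """
    rng = np.random.default_rng(seed)
    if dimension_scores is not None:
        subjects = list(dimension_scores.index)[:n_subjects]
        if len(subjects) < n_subjects:
            raise ValueError("dimension_scores has fewer rows than n_subjects")
    else:
        subjects = [f"s{i + 1:03d}" for i in range(n_subjects)]
    if dimension_scores is None:
        chol = np.linalg.cholesky(default_factor_corr())
        dims = rng.standard_normal((n_subjects, 3)) @ chol.T
        dimension_scores = pd.DataFrame(dims, index=subjects, columns=list(DIMENSIONS))
    base = 0.0
    slope = 0.0
    dim_name = None
    if coupling:
        dim_name = coupling["dimension"]
        slope = float(coupling.get("slope", 0.0))
        base = float(coupling.get("base", 0.0))

    trial_frames, truth_rows = [], []
    for i, sid in enumerate(subjects):
        if dim_name is not None:
            d = dimension_scores[dim_name].to_numpy()
            z = (d - d.mean()) / d.std(ddof=0)
            w_mb = float(_logistic(base + slope * z[i]))
        else:
            w_mb = float(rng.beta(2, 2))
        params = AgentParams(
            w_mb=w_mb,
            alpha1=float(rng.beta(4, 4)),
            alpha2=float(rng.beta(4, 4)),
            lam=0.6,
            beta1=4.0,
            beta2=4.0,
            stickiness=0.2,
            seed=int(rng.integers(2**31 - 1)),
        )
        trial_frames.append(simulate_agent(cfg, params, subject_id=sid))
        truth_rows.append(
            {
                "subject": sid,
                "w_mb": params.w_mb,
                "alpha1": params.alpha1,
                "alpha2": params.alpha2,
                **dimension_scores.loc[sid].to_dict(),
            }
        )
    return {
        "trials": pd.concat(trial_frames, ignore_index=True),
        "truth": pd.DataFrame(truth_rows).set_index("subject"),
    }
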