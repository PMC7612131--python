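"""Stay-probability logistic analysis of goal-directed learning.

Each trial t ≥ 2 contributes a record: stay (first-stage choice repeated),
the previous trial's reward and transition type, both effect-coded ±1.
The reward × transition interaction coefficient indexes model-based
(goal-directed) control; the association with psychopathology is the
dimension × reward × transition coefficient in the pooled model with the
three z-scored transdiagnostic dimensions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .synth_cohort import DIMENSIONS


@dataclass
class MBEstimate:
    interaction: float
    interaction_se: float
    coefficients: pd.DataFrame
    dimension_effects: pd.DataFrame | None = None
    converged: bool = True

    @property
    def mb_index(self) -> float:
        return self.interaction


def code_stays(
    data: pd.DataFrame,
    dimension_scores: pd.DataFrame | None = None,
    effect_coding: bool = True,
) -> pd.DataFrame:
    """Build stay records from a trial table (per subject, trials ordered).

    Drops each subject's first trial; ``stay`` is 1 when choice1 repeats
    the previous trial's; ``prev_reward`` and ``prev_transition`` are the
    previous trial's reward and transition, effect-coded ±1 (+1 = rewarded
    / common) unless ``effect_coding`` is False (0/1 dummy coding).
    """
    frames = []
    for sid, grp in data.groupby("subject", sort=False):
        if len(grp) < 2:
            raise ValueError(f"subject {sid} has fewer than 2 trials")
        g = grp.sort_values("trial").reset_index(drop=True)
        stay = (g["choice1"].to_numpy()[1:] == g["choice1"].to_numpy()[:-1]).astype(int)
        reward = g["reward"].to_numpy()[:-1]
        common = (g["transition"].to_numpy()[:-1] == "common").astype(int)
        if effect_coding:
            reward = 2 * reward - 1
            common = 2 * common - 1
        rec = pd.DataFrame(
            {
                "subject": sid,
                "stay": stay,
                "prev_reward": reward,
                "prev_transition": common,
            }
        )
        if dimension_scores is not None:
            for dim in DIMENSIONS:
                rec[dim] = dimension_scores.loc[sid, dim]
        frames.append(rec)
    out = pd.concat(frames, ignore_index=True)
    if dimension_scores is not None:
        present = dimension_scores.loc[data["subject"].unique()]
        for dim in DIMENSIONS:  # z-score across the analysed subjects
            out[f"{dim}_z"] = (out[dim] - present[dim].mean()) / present[dim].std(ddof=0)
    return out


def _fit_logit(y: np.ndarray, X: np.ndarray, names: list[str]) -> tuple[pd.DataFrame, bool]:
    model = sm.Logit(y, X)
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = model.fit(disp=0, maxiter=200)
            converged = bool(fit.mle_retvals.get("converged", True))
        except Exception:
            fit = model.fit(method="bfgs", disp=0, maxiter=500)
            converged = False
    if not converged:
        warnings.warn("logistic fit did not fully converge (possible separation)")
    coef = pd.DataFrame(
        {
            "term": names,
            "coef": np.asarray(fit.params, dtype=float),
            "se": np.asarray(fit.bse, dtype=float),
            "z": np.asarray(fit.tvalues, dtype=float),
            "p": np.asarray(fit.pvalues, dtype=float),
        }
    )
    return coef, converged


def fit_stay_model(records: pd.DataFrame, with_dimensions: bool = False) -> MBEstimate:
    """Pooled logistic regression of stay behaviour.

    Base terms: prev_reward, prev_transition and their product (the
    model-based index).  Without dimensions, subject heterogeneity is
    absorbed by per-subject intercepts (fixed effects) when more than one
    subject is present.  With dimensions, a single pooled model adds each
    z-scored dimension and its interactions with the three base terms; the
    headline association is each dimension × reward × transition term.
    """
    y = records["stay"].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both stay outcomes must be present")
    r = records["prev_reward"].to_numpy(dtype=float)
    t = records["prev_transition"].to_numpy(dtype=float)
    base = [r, t, r * t]
    base_names = ["prev_reward", "prev_transition", "reward_x_transition"]

    subjects = records["subject"].unique() if "subject" in records else ["s001"]
    if with_dimensions:
        cols, names = list(base), list(base_names)
        for dim in DIMENSIONS:
            z = records[f"{dim}_z"].to_numpy(dtype=float)
            cols += [z, z * r, z * t, z * r * t]
            names += [dim, f"{dim}_x_reward", f"{dim}_x_transition", f"{dim}_x_reward_x_transition"]
        X = sm.add_constant(np.column_stack(cols))
        names = ["intercept"] + names
    elif len(subjects) > 1:
        sub_dummies = pd.get_dummies(records["subject"], dtype=float)
        X = np.column_stack([sub_dummies.to_numpy()] + base)
        names = [f"subj[{s}]" for s in sub_dummies.columns] + base_names
    else:
        X = sm.add_constant(np.column_stack(base))
        names = ["intercept"] + base_names

    coef, converged = _fit_logit(y, X, names)
    inter = coef.set_index("term").loc["reward_x_transition"]
    dim_effects = None
    if with_dimensions:
        rows = coef[coef["term"].str.endswith("_x_reward_x_transition")].copy()
        rows["dimension"] = rows["term"].str.replace("_x_reward_x_transition", "", regex=False)
        dim_effects = rows.set_index("dimension")[["coef", "se", "z", "p"]]
    return MBEstimate(
        interaction=float(inter["coef"]),
        interaction_se=float(inter["se"]),
        coefficients=coef,
        dimension_effects=dim_effects,
        converged=converged,
    )


def per_subject_mb_index(records: pd.DataFrame) -> pd.DataFrame:
    """Per-subject reward × transition coefficients (model-based index).

    Fits the base logistic separately per subject; non-converged fits are
    flagged.  The resulting column can be merged into a cohort table as
    ``mb_index``.
    """
    rows = []
    for sid, grp in records.groupby("subject", sort=False):
        try:
            est = fit_stay_model(grp, with_dimensions=False)
            rows.append(
                {
                    "subject": sid,
                    "mb_index": est.interaction,
                    "se": est.interaction_se,
                    "converged": est.converged,
                }
            )
        except ValueError:
            rows.append({"subject": sid, "mb_index": np.nan, "se": np.nan, "converged": False})
    return pd.DataFrame(rows).set_index("subject")
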