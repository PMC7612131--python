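"""Item-level questionnaire responses from a correlated three-factor model.

Generates ordinal responses to the 209 items of the nine instruments
(plus one catch item) from latent anxious-depression (AD), compulsive
behaviour and intrusive thought (CIT) and social-withdrawal (SW) factors
that correlate moderately (0.33–0.39), so that dimension projection and
the regression battery can be tested against known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

DIMENSIONS = ("AD", "CIT", "SW")
CATCH_ANSWER = "A little"

#: published instrument lengths; they sum to the 209 items used for
#: dimension scoring (LSAS counted as its 24 situations; SSMS 43 items)
SCALE_ITEMS = {
    "AUDIT": 10,
    "AES": 18,
    "SDS": 20,
    "EAT26": 26,
    "BIS11": 30,
    "OCIR": 18,
    "SSMS": 43,
    "LSAS": 24,
    "STAI": 20,
}
N_ITEMS = sum(SCALE_ITEMS.values())  # 209

#: dominant factor per instrument (synthetic loading structure)
SCALE_FACTOR = {
    "STAI": "AD",
    "SDS": "AD",
    "OCIR": "CIT",
    "SSMS": "CIT",
    "EAT26": "CIT",
    "AUDIT": "CIT",
    "BIS11": "CIT",
    "LSAS": "SW",
    "AES": "SW",
}

#: response coding: (n_levels, minimum response value)
SCALE_CODING = {
    "OCIR": (5, 0),   # 0–4 per item, total 0–72 (clinical cut-off 21)
    "STAI": (4, 1),   # 1–4 per item, total 20–80 (clinical cut-off 41)
}
DEFAULT_CODING = (4, 0)


def default_manifest() -> pd.DataFrame:
    """Synthetic item manifest: item_id, scale, n_levels, min_response,
    reverse_scored.

    The manifest is the single source of truth for item order and coding;
    it mirrors the published instrument lengths but its reverse-scoring
    pattern is synthetic (every 5th item of AES, BIS-11 and STAI), not the
    canonical instruments' keys.
    """
    rows = []
    for scale, n in SCALE_ITEMS.items():
        levels, lo = SCALE_CODING.get(scale, DEFAULT_CODING)
        for i in range(1, n + 1):
            rows.append(
                {
                    "item_id": f"{scale}_{i:02d}",
                    "scale": scale,
                    "n_levels": levels,
                    "min_response": lo,
                    "reverse_scored": scale in ("AES", "BIS11", "STAI") and i % 5 == 0,
                }
            )
    return pd.DataFrame(rows)


def default_factor_corr() -> np.ndarray:
    """Inter-factor correlations inside the reported 0.33–0.39 band."""
    return np.array(
        [
            [1.00, 0.36, 0.39],
            [0.36, 1.00, 0.33],
            [0.39, 0.33, 1.00],
        ]
    )


def default_loadings(manifest: pd.DataFrame | None = None) -> pd.DataFrame:
    """209 × 3 loading matrix: each item loads 0.6 on its scale's factor."""
    manifest = manifest if manifest is not None else default_manifest()
    load = pd.DataFrame(0.0, index=manifest["item_id"], columns=list(DIMENSIONS))
    for _, row in manifest.iterrows():
        load.loc[row["item_id"], SCALE_FACTOR[row["scale"]]] = 0.6
    return load


@dataclass
class LatentModel:
    factor_corr: np.ndarray = field(default_factory=default_factor_corr)
    loadings: pd.DataFrame = field(default_factory=default_loadings)
    noise_sd: float = 0.8
    #: ordinal discretisation thresholds on the standardised propensity
    thresholds: tuple[float, ...] = (-1.0, 0.0, 1.0)
    catch_fail_rate: float = 0.03
    #: when False, emit the standardised continuous propensities instead of
    #: ordinal responses (degenerate limit used for recovery checks)
    discretise: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        c = np.asarray(self.factor_corr, dtype=float)
        if c.shape != (3, 3) or not np.allclose(c, c.T) or not np.allclose(np.diag(c), 1.0):
            raise ValueError("factor_corr must be a symmetric 3×3 correlation matrix")
        try:
            np.linalg.cholesky(c)
        except np.linalg.LinAlgError as exc:
            raise ValueError("factor_corr must be positive-definite") from exc


def simulate_items(
    model: LatentModel,
    n_subjects: int,
    manifest: pd.DataFrame | None = None,
) -> dict[str, pd.DataFrame]:
    """Draw correlated factors, form item propensities, discretise.

    Returns ``{"responses", "truth", "manifest"}``: an (n_subjects × 209)
    response table plus a catch-item column, the ground-truth factor
    scores, and the manifest used.  Item propensity = loadings·f + noise,
    discretised at the model thresholds and mapped onto each item's coding
    (reverse-scored items are flipped at generation so that the *recorded*
    response is the raw answer a flipped item would receive).
    """
    manifest = manifest if manifest is not None else default_manifest()
    if len(manifest) != N_ITEMS:
        raise ValueError(f"manifest must have {N_ITEMS} items, got {len(manifest)}")
    rng = np.random.default_rng(model.seed)
    chol = np.linalg.cholesky(np.asarray(model.factor_corr, dtype=float))
    factors = rng.standard_normal((n_subjects, 3)) @ chol.T
    load = model.loadings.loc[manifest["item_id"]].to_numpy()
    propensity = factors @ load.T + rng.normal(0.0, model.noise_sd, (n_subjects, N_ITEMS))
    # standardise propensities per item before thresholding
    sd = np.sqrt((load @ np.asarray(model.factor_corr) * load).sum(axis=1) + model.noise_sd**2)
    z = propensity / sd

    levels = manifest["n_levels"].to_numpy()
    lo = manifest["min_response"].to_numpy()
    reverse = manifest["reverse_scored"].to_numpy()

    subjects = [f"s{i + 1:03d}" for i in range(n_subjects)]
    if not model.discretise:
        responses = pd.DataFrame(z, index=subjects, columns=manifest["item_id"])
        responses["catch_response"] = CATCH_ANSWER
        truth = pd.DataFrame(factors, index=subjects, columns=list(DIMENSIONS))
        return {"responses": responses, "truth": truth, "manifest": manifest}

    resp = np.zeros_like(z, dtype=int)
    for j in range(N_ITEMS):
        n_lev = int(levels[j])
        if n_lev == len(model.thresholds) + 1:
            cuts = np.asarray(model.thresholds)
        else:  # evenly spaced standard-normal quantile cuts for other levels
            cuts = norm.ppf(np.linspace(0, 1, n_lev + 1)[1:-1])
        ordinal = np.searchsorted(cuts, z[:, j])  # 0 … n_lev−1
        if reverse[j]:
            ordinal = (n_lev - 1) - ordinal
        resp[:, j] = ordinal + lo[j]

    responses = pd.DataFrame(resp, index=subjects, columns=manifest["item_id"])
    failed = rng.random(n_subjects) < model.catch_fail_rate
    responses["catch_response"] = np.where(failed, "Not at all", CATCH_ANSWER)
    truth = pd.DataFrame(factors, index=subjects, columns=list(DIMENSIONS))
    return {"responses": responses, "truth": truth, "manifest": manifest}


def simulate_demographics(n_subjects: int, seed: int = 0) -> pd.DataFrame:
    """Age (18–65), gender and medication status; no planted effects."""
    rng = np.random.default_rng(seed)
    age = np.clip(rng.normal(30.8, 11.5, n_subjects), 18, 65)
    gender = rng.choice(["female", "male"], size=n_subjects, p=[0.59, 0.41])
    medicated = rng.random(n_subjects) < 0.158
    return pd.DataFrame(
        {"age": age, "gender": gender, "medicated": medicated.astype(int)},
        index=[f"s{i + 1:03d}" for i in range(n_subjects)],
    )


def plant_association(
    cohort: pd.DataFrame,
    target: str,
    dimension: str,
    beta: float,
) -> pd.DataFrame:
    """Add beta × z(ground-truth factor) to a target column.

    ``cohort`` must hold the target variable and ground-truth factor
    columns; beta = 0 returns the cohort unchanged.
    """
    if target not in ("ern", "mb_index"):
        raise ValueError(f"unknown target {target!r}; expected 'ern' or 'mb_index'")
    if dimension not in DIMENSIONS:
        raise ValueError(f"unknown dimension {dimension!r}")
    out = cohort.copy()
    if beta == 0.0:
        return out
    f = out[dimension].to_numpy(dtype=float)
    z = (f - f.mean()) / f.std(ddof=0)
    out[target] = out[target].to_numpy(dtype=float) + beta * z
    return out
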