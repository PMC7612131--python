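"""Questionnaire scoring and transdiagnostic dimension projection.

Scale totals are simple sums with reverse-scored items flipped; clinical
flags use the instruments' standard cut-offs (OCI-R total ≥ 21, trait
STAI total > 41).  Dimension scores are weighted sums of the 209 raw item
responses under a fixed 209 × 3 weight matrix (anxious-depression,
compulsivity, social withdrawal), z-scored across the analysed cohort.
No factor analysis is performed here — the weights are an input.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .synth_cohort import DIMENSIONS, N_ITEMS, default_loadings, default_manifest

OCIR_CUTOFF = 21  # flag when total >= 21
STAI_CUTOFF = 41  # flag when total > 41 (strict)


def load_weights(path) -> pd.DataFrame:
    """Read a user-supplied weights CSV: item_id, w_AD, w_CIT, w_SW."""
    df = pd.read_csv(path)
    expected = {"item_id", "w_AD", "w_CIT", "w_SW"}
    if not expected.issubset(df.columns):
        raise ValueError(f"weights CSV must have columns {sorted(expected)}")
    w = df.set_index("item_id")[["w_AD", "w_CIT", "w_SW"]]
    w.columns = list(DIMENSIONS)
    if len(w) != N_ITEMS:
        raise ValueError(f"weights must have {N_ITEMS} rows, got {len(w)}")
    return w


def synthetic_default_weights() -> pd.DataFrame:
    """Generator-loading weights — a synthetic stand-in, not the published
    matrix (which is not reproduced here)."""
    return default_loadings()


def score_scales(
    responses: pd.DataFrame, manifest: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Per-subject scale totals and clinical flags.

    Reverse-scored items are flipped within their coding range before
    summation.  A missing manifest item raises an error naming it (no
    imputation is performed).
    """
    manifest = manifest if manifest is not None else default_manifest()
    for item in manifest["item_id"]:
        if item not in responses.columns:
            raise KeyError(f"missing response column for item {item!r}")
        if responses[item].isna().any():
            raise ValueError(f"missing responses for item {item!r}")

    totals = pd.DataFrame(index=responses.index)
    for scale, grp in manifest.groupby("scale", sort=False):
        vals = responses[grp["item_id"]].to_numpy(dtype=float)
        lo = grp["min_response"].to_numpy()
        hi = lo + grp["n_levels"].to_numpy() - 1
        rev = grp["reverse_scored"].to_numpy()
        vals[:, rev] = (lo + hi)[rev] - vals[:, rev]
        totals[scale] = vals.sum(axis=1)
    totals["ocir_ge_21"] = totals["OCIR"] >= OCIR_CUTOFF
    totals["stai_gt_41"] = totals["STAI"] > STAI_CUTOFF
    return totals


def project_dimensions(
    responses: pd.DataFrame,
    weights: pd.DataFrame | None = None,
    zscore: bool = True,
) -> pd.DataFrame:
    """Project raw item responses onto the three dimensions.

    Raw score per factor f is Σ_i w_if · x_i over the 209 items in weight
    order.  With ``zscore`` the projected columns are additionally
    standardised across the included subjects (``AD_z`` etc.).
    """
    weights = weights if weights is not None else synthetic_default_weights()
    if len(weights) != N_ITEMS:
        raise ValueError(f"weights must have {N_ITEMS} rows, got {len(weights)}")
    missing = [i for i in weights.index if i not in responses.columns]
    if missing:
        raise KeyError(f"responses lack items: {missing[:5]}…" if len(missing) > 5 else
                       f"responses lack items: {missing}")
    x = responses[weights.index].to_numpy(dtype=float)
    raw = x @ weights.to_numpy(dtype=float)
    out = pd.DataFrame(raw, index=responses.index, columns=list(DIMENSIONS))
    if zscore:
        for dim in DIMENSIONS:
            v = out[dim].to_numpy()
            sd = v.std(ddof=0)
            out[f"{dim}_z"] = (v - v.mean()) / sd if sd > 0 else 0.0
    return out
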