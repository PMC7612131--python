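"""Response-locked ERP amplitude quantification.

Implements the scoring chain used for the error-related negativity (ERN)
and correct-related negativity (CRN): per-epoch baseline correction over
−400…−200 ms, ±50 μV threshold rejection, within-subject averaging, and
four amplitude measures — the adaptive mean (mean amplitude ±40 ms around
the most negative peak found in −20…120 ms post-response), a fixed-window
mean, the minimum amplitude, and trough-to-peak.  Also provides ΔERN,
across-subject residualisation of ERN on CRN, and even/odd split-half
reliability with the Spearman–Brown correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import DEFAULT_GRID, EpochSet, TimeGrid

METHODS = ("adaptive_mean", "window_mean", "min_amplitude", "trough_to_peak")


class NoSurvivingEpochsError(RuntimeError):
    """Raised when threshold rejection removes every epoch of a subject."""


@dataclass(frozen=True)
class ScoringConfig:
    baseline_window_ms: tuple[float, float] = (-400.0, -200.0)
    reject_threshold_uv: float = 50.0
    search_window_ms: tuple[float, float] = (-20.0, 120.0)
    halfwidth_ms: float = 40.0
    fixed_window_ms: tuple[float, float] = (0.0, 100.0)
    #: samples at exactly |x| == threshold are kept ("exceeds" rejects)
    reject_boundary_kept: bool = True
    #: start of the preceding-positivity window for trough_to_peak
    trough_to_peak_pre_ms: float = -100.0

    def __post_init__(self) -> None:
        if self.reject_threshold_uv <= 0:
            raise ValueError("reject_threshold_uv must be positive")


@dataclass
class AmplitudeEstimate:
    value_uv: float
    method: str
    peak_latency_ms: float | None = None
    n_epochs_used: int = 1


@dataclass
class SubjectERP:
    subject_id: str
    ern: AmplitudeEstimate
    crn: AmplitudeEstimate
    ern_resid_uv: float | None = None

    @property
    def delta_ern_uv(self) -> float:
        return self.ern.value_uv - self.crn.value_uv


# ---------------------------------------------------------------- epochs


def baseline_correct(epochs: EpochSet, cfg: ScoringConfig = ScoringConfig()) -> EpochSet:
    """Subtract each epoch's mean over the baseline window from every sample."""
    if epochs.n_epochs == 0:
        raise ValueError("empty epoch set")
    idx = epochs.grid.window_indices(*cfg.baseline_window_ms)
    if idx.size == 0:
        raise ValueError("baseline window lies outside the epoch grid")
    baseline = epochs.data[:, idx].mean(axis=1, keepdims=True)
    return epochs.replace_data(epochs.data - baseline)


def reject_epochs(
    epochs: EpochSet, cfg: ScoringConfig = ScoringConfig()
) -> tuple[EpochSet, int]:
    """Drop epochs whose absolute amplitude exceeds the threshold anywhere.

    Uses a strict comparison: a sample exactly at the threshold does not
    trigger rejection (configurable via ``reject_boundary_kept``).
    """
    peak = np.abs(epochs.data).max(axis=1)
    if cfg.reject_boundary_kept:
        keep = peak <= cfg.reject_threshold_uv
    else:
        keep = peak < cfg.reject_threshold_uv
    n_rejected = int((~keep).sum())
    if not keep.any():
        raise NoSurvivingEpochsError(
            f"all {epochs.n_epochs} epochs of subject {epochs.subject_id} "
            f"exceed ±{cfg.reject_threshold_uv} μV"
        )
    return epochs.replace_data(epochs.data[keep]), n_rejected


def average_epochs(epochs: EpochSet) -> np.ndarray:
    """Pointwise arithmetic mean across epochs."""
    if epochs.n_epochs == 0:
        raise ValueError("empty epoch set")
    return epochs.data.mean(axis=0)


# -------------------------------------------------------------- waveforms


def _as_waveform(waveform: np.ndarray, grid: TimeGrid) -> np.ndarray:
    w = np.asarray(waveform, dtype=float)
    if w.shape != (grid.n_samples,):
        raise ValueError(f"waveform must have {grid.n_samples} samples")
    return w


def _find_negative_peak(
    waveform: np.ndarray, cfg: ScoringConfig, grid: TimeGrid
) -> tuple[int, float]:
    idx = grid.window_indices(*cfg.search_window_ms)
    # np.argmin returns the first (earliest) index on ties
    peak = idx[int(np.argmin(waveform[idx]))]
    return peak, float(grid.times[peak])


def adaptive_mean(
    waveform: np.ndarray,
    cfg: ScoringConfig = ScoringConfig(),
    grid: TimeGrid = DEFAULT_GRID,
) -> AmplitudeEstimate:
    """Mean amplitude ±halfwidth around the most negative peak in the search window.

    The peak is the minimum sample within the inclusive search window
    (earliest latency wins ties); the averaging window is inclusive at both
    ends (21 samples at 250 Hz for ±40 ms) and clipped to the epoch bounds.
    """
    w = _as_waveform(waveform, grid)
    peak_idx, peak_ms = _find_negative_peak(w, cfg, grid)
    win = grid.window_indices(peak_ms - cfg.halfwidth_ms, peak_ms + cfg.halfwidth_ms)
    return AmplitudeEstimate(
        value_uv=float(w[win].mean()), method="adaptive_mean", peak_latency_ms=peak_ms
    )


def window_mean(
    waveform: np.ndarray,
    cfg: ScoringConfig = ScoringConfig(),
    grid: TimeGrid = DEFAULT_GRID,
) -> AmplitudeEstimate:
    """Mean amplitude over the fixed (non-adaptive) window."""
    w = _as_waveform(waveform, grid)
    win = grid.window_indices(*cfg.fixed_window_ms)
    return AmplitudeEstimate(value_uv=float(w[win].mean()), method="window_mean")


def min_amplitude(
    waveform: np.ndarray,
    cfg: ScoringConfig = ScoringConfig(),
    grid: TimeGrid = DEFAULT_GRID,
) -> AmplitudeEstimate:
    """Minimum sample within the search window."""
    w = _as_waveform(waveform, grid)
    peak_idx, peak_ms = _find_negative_peak(w, cfg, grid)
    return AmplitudeEstimate(
        value_uv=float(w[peak_idx]), method="min_amplitude", peak_latency_ms=peak_ms
    )


def trough_to_peak(
    waveform: np.ndarray,
    cfg: ScoringConfig = ScoringConfig(),
    grid: TimeGrid = DEFAULT_GRID,
) -> AmplitudeEstimate:
    """Trough minus preceding positive peak, as a negative-signed magnitude.

    The trough is the search-window minimum; the preceding positivity is the
    maximum over [trough_to_peak_pre_ms, trough latency].
    """
    w = _as_waveform(waveform, grid)
    peak_idx, peak_ms = _find_negative_peak(w, cfg, grid)
    pre = grid.window_indices(cfg.trough_to_peak_pre_ms, peak_ms)
    value = float(w[peak_idx] - w[pre].max())
    return AmplitudeEstimate(value_uv=value, method="trough_to_peak", peak_latency_ms=peak_ms)


_SCORERS = {
    "adaptive_mean": adaptive_mean,
    "window_mean": window_mean,
    "min_amplitude": min_amplitude,
    "trough_to_peak": trough_to_peak,
}


def score_waveform(
    waveform: np.ndarray,
    cfg: ScoringConfig = ScoringConfig(),
    method: str = "adaptive_mean",
    grid: TimeGrid = DEFAULT_GRID,
) -> AmplitudeEstimate:
    if method not in _SCORERS:
        raise ValueError(f"unknown scoring method {method!r}; choose from {METHODS}")
    return _SCORERS[method](waveform, cfg, grid)


def score_epochs(
    epochs: EpochSet,
    cfg: ScoringConfig = ScoringConfig(),
    method: str = "adaptive_mean",
    reject: bool = True,
) -> AmplitudeEstimate:
    """Full single-subject chain: baseline-correct, (optionally) reject,
    average, score."""
    corrected = baseline_correct(epochs, cfg)
    if reject:
        corrected, _ = reject_epochs(corrected, cfg)
    est = score_waveform(average_epochs(corrected), cfg, method, epochs.grid)
    est.n_epochs_used = corrected.n_epochs
    return est


# ----------------------------------------------------------- cohort level


def residualise_ern(cohort: list[SubjectERP]) -> list[SubjectERP]:
    """Fill ``ern_resid_uv`` with OLS residuals of ERN regressed on CRN.

    Residuals sum to zero and are sample-uncorrelated with CRN.  With a
    zero-variance CRN the regressor is degenerate and the residuals reduce
    to the centered ERN (a warning is emitted).
    """
    if len(cohort) < 3:
        raise ValueError("residualisation needs at least 3 subjects")
    ern = np.array([s.ern.value_uv for s in cohort])
    crn = np.array([s.crn.value_uv for s in cohort])
    if not (np.all(np.isfinite(ern)) and np.all(np.isfinite(crn))):
        raise ValueError("non-finite ERN/CRN values")
    crn_c = crn - crn.mean()
    denom = float(crn_c @ crn_c)
    if denom == 0.0:
        warnings.warn("CRN has zero variance; residuals are the centered ERN")
        resid = ern - ern.mean()
    else:
        slope = float(crn_c @ (ern - ern.mean())) / denom
        resid = ern - (ern.mean() + slope * crn_c)
    for s, r in zip(cohort, resid):
        s.ern_resid_uv = float(r)
    return cohort


def spearman_brown(r_half: float) -> float:
    """Project a split-half correlation to full length: 2r / (1 + r)."""
    return 2.0 * r_half / (1.0 + r_half)


def split_half_reliability(
    cohort_epochs: dict[str, EpochSet],
    cfg: ScoringConfig = ScoringConfig(),
    method: str = "adaptive_mean",
) -> dict[str, float]:
    """Even/odd split-half reliability of a scoring method across subjects.

    Each subject's epochs are split by epoch index (even indices vs odd; an
    odd count leaves the extra epoch in the even half), each half is
    averaged and scored, the two score vectors are Pearson-correlated
    across subjects, and the Spearman–Brown formula projects the
    correlation to full length.  Expects baseline-corrected (and, where
    wanted, already rejected) epochs.
    """
    if len(cohort_epochs) < 3:
        raise ValueError("split-half reliability needs at least 3 subjects")
    even_scores, odd_scores = [], []
    for subject, epochs in cohort_epochs.items():
        if epochs.n_epochs < 2:
            raise ValueError(f"subject {subject} has fewer than 2 epochs")
        even = epochs.replace_data(epochs.data[0::2])
        odd = epochs.replace_data(epochs.data[1::2])
        even_scores.append(
            score_waveform(average_epochs(even), cfg, method, epochs.grid).value_uv
        )
        odd_scores.append(
            score_waveform(average_epochs(odd), cfg, method, epochs.grid).value_uv
        )
    r_half = float(np.corrcoef(even_scores, odd_scores)[0, 1])
    return {"r_half": r_half, "r_sb": spearman_brown(r_half)}


def scores_to_csv(scores: list[tuple[str, str, AmplitudeEstimate]], path) -> None:
    """Write (subject, condition, estimate) rows as a flat CSV."""
    rows = [
        {
            "subject": subject,
            "method": est.method,
            "condition": condition,
            "value_uv": est.value_uv,
            "peak_latency_ms": est.peak_latency_ms,
            "n_epochs_used": est.n_epochs_used,
        }
        for subject, condition, est in scores
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
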