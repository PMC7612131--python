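"""Synthetic response-locked EEG epochs with known ground-truth amplitudes.

The generator produces single-trial epochs whose noiseless subject-average
adaptive-mean score equals a requested true amplitude exactly, for either
sign.  Each trial is

    epoch(t) = (A·g + ρ·D)·b(t − c − j)  −  D·b_n(t − c − j)  +  ε(t)

where ``b`` is a wide half-cosine bump (the ERN/CRN component shape,
default 100 ms width centred at 37.61 ms, the grand-average peak latency),
``g`` the calibrated gain making the adaptive-mean score of the component
equal one per μV of true amplitude ``A``, ``j`` per-trial latency jitter
and ``ε`` i.i.d. Gaussian sample noise.  The second term is a fixed
*morphology anchor* — a narrower half-cosine notch ``b_n`` of depth ``D``
with a compensating multiple ``ρ·D`` of the wide bump chosen so that the
anchor contributes exactly zero to the score.  It emulates the morphology
of real response-locked waveforms, where the negativity is a dip relative
to surrounding positivity: it pins the detected negative peak at the
component latency for positive as well as negative amplitudes, which is
what lets a +0.3 μV CRN be recovered by a minimum-picking estimator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

from . import erp
from .containers import DEFAULT_GRID, EpochSet, TimeGrid

GRAND_AVERAGE_PEAK_MS = 37.61


class CalibrationError(ValueError):
    """Kernel cannot be calibrated against the adaptive-mean estimator."""


@dataclass(frozen=True)
class ComponentKernel:
    """Negative-going ERP component: unit amplitude −1 at its centre."""

    shape: str = "half_cosine"
    center_ms: float = GRAND_AVERAGE_PEAK_MS
    width_ms: float = 100.0

    def __post_init__(self) -> None:
        if self.shape != "half_cosine":
            raise ValueError(f"unknown kernel shape {self.shape!r}")
        if self.width_ms <= 0:
            raise ValueError("width_ms must be positive")

    def bump(self, times_ms: np.ndarray) -> np.ndarray:
        """Positive unit bump (−kernel): cos half-wave on its support."""
        x = np.asarray(times_ms, dtype=float) - self.center_ms
        half = self.width_ms / 2.0
        out = np.where(np.abs(x) <= half, np.cos(np.pi * x / self.width_ms), 0.0)
        return out

    def evaluate(self, times_ms: np.ndarray) -> np.ndarray:
        return -self.bump(times_ms)


#: narrow notch anchoring the negative peak at the component latency
DEFAULT_NOTCH_WIDTH_MS = 40.0
DEFAULT_ANCHOR_DEPTH_UV = 28.0


@dataclass(frozen=True)
class EEGGenParams:
    """Cohort-level generator parameters.

    Population means/SDs default to the grand-average error-trial
    (−3.11 ± 2.79 μV) and correct-trial (0.30 ± 1.89 μV) adaptive-mean
    amplitudes, with per-subject epoch counts dispersed around 51.88
    (SD 33.09) error and 404 (SD 58.78) correct trials, floored at the
    minimum retained count of 9.
    """

    n_subjects: int = 196
    pop_mean_ern_uv: float = -3.11
    pop_sd_ern_uv: float = 2.79
    pop_mean_crn_uv: float = 0.30
    pop_sd_crn_uv: float = 1.89
    epochs_error_mean: float = 51.88
    epochs_error_sd: float = 33.09
    epochs_correct_mean: float = 404.0
    epochs_correct_sd: float = 58.78
    epoch_noise_sd_uv: float = 10.0
    latency_jitter_sd_ms: float = 10.0
    min_epochs: int = 9
    anchor_depth_uv: float = DEFAULT_ANCHOR_DEPTH_UV
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "pop_sd_ern_uv",
            "pop_sd_crn_uv",
            "epochs_error_sd",
            "epochs_correct_sd",
            "epoch_noise_sd_uv",
            "latency_jitter_sd_ms",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_subjects < 0:
            raise ValueError("n_subjects must be non-negative")


def calibrate_kernel_gain(
    kernel: ComponentKernel | np.ndarray,
    grid: TimeGrid = DEFAULT_GRID,
    cfg: erp.ScoringConfig = erp.ScoringConfig(),
) -> float:
    """Gain g making the adaptive-mean score of g·kernel equal −1.

    Scoring a noiseless subject whose true amplitude is A then yields A.
    A kernel whose extremum lies outside the adaptive-mean search window
    cannot be calibrated.
    """
    if isinstance(kernel, ComponentKernel):
        lo, hi = cfg.search_window_ms
        if not (lo <= kernel.center_ms <= hi):
            raise CalibrationError(
                f"kernel centre {kernel.center_ms} ms outside search window {lo}…{hi} ms"
            )
        waveform = kernel.evaluate(grid.times)
    else:
        waveform = np.asarray(kernel, dtype=float)
    score = erp.adaptive_mean(waveform, cfg, grid).value_uv
    if score >= 0:
        raise CalibrationError("kernel has no negative mass in the search window")
    return -1.0 / score


def _gauss_blur_weights(jitter_sd_ms: float, n_nodes: int = 33) -> tuple[np.ndarray, np.ndarray]:
    """Gauss–Hermite quadrature nodes/weights for N(0, jitter_sd²)."""
    if jitter_sd_ms == 0:
        return np.zeros(1), np.ones(1)
    nodes, weights = np.polynomial.hermite_e.hermegauss(n_nodes)
    return nodes * jitter_sd_ms, weights / weights.sum()


def _blurred(fn, grid: TimeGrid, jitter_sd_ms: float) -> np.ndarray:
    """Expected waveform of fn(t − j) under Gaussian latency jitter."""
    shifts, weights = _gauss_blur_weights(jitter_sd_ms)
    acc = np.zeros(grid.n_samples)
    for s, w in zip(shifts, weights):
        acc += w * fn(grid.times - s)
    return acc


def _anchor_ratio(
    kernel: ComponentKernel,
    notch: ComponentKernel,
    grid: TimeGrid,
    cfg: erp.ScoringConfig,
    jitter_sd_ms: float,
) -> float:
    """Compensation ratio ρ zeroing the anchor's expected score contribution.

    ρ is the ratio of the windowed means of the jitter-blurred notch and
    bump around the detected peak; with zero jitter the anchor's windowed
    mean is exactly zero, preserving the noiseless round trip.
    """
    b = _blurred(kernel.bump, grid, jitter_sd_ms)
    bn = _blurred(notch.bump, grid, jitter_sd_ms)
    peak_idx, peak_ms = erp._find_negative_peak(-bn, cfg, grid)
    win = grid.window_indices(peak_ms - cfg.halfwidth_ms, peak_ms + cfg.halfwidth_ms)
    return float(bn[win].mean() / b[win].mean())


def _epoch_count(rng: np.random.Generator, mean: float, sd: float, floor: int) -> int:
    """Dispersed per-subject epoch count: gamma-distributed, rounded, floored."""
    if sd == 0:
        return max(int(round(mean)), floor)
    shape = (mean / sd) ** 2
    scale = sd**2 / mean
    return max(int(round(rng.gamma(shape, scale))), floor)


def _simulate_subject_condition(
    rng: np.random.Generator,
    subject_id: str,
    condition: str,
    amplitude_uv: float,
    n_epochs: int,
    params: EEGGenParams,
    kernel: ComponentKernel,
    notch: ComponentKernel,
    gain: float,
    rho: float,
    grid: TimeGrid,
) -> EpochSet:
    jitter = (
        rng.normal(0.0, params.latency_jitter_sd_ms, size=(n_epochs, 1))
        if params.latency_jitter_sd_ms > 0
        else np.zeros((n_epochs, 1))
    )
    t = grid.times[None, :] - jitter  # (n_epochs, n_samples)
    depth = params.anchor_depth_uv
    data = (amplitude_uv * gain + rho * depth) * kernel.bump(t) - depth * notch.bump(t)
    if params.epoch_noise_sd_uv > 0:
        data = data + rng.normal(0.0, params.epoch_noise_sd_uv, size=data.shape)
    return EpochSet(
        subject_id=subject_id,
        condition=condition,
        data=data,
        grid=grid,
        true_amplitude_uv=amplitude_uv,
    )


def simulate_epochs(
    params: EEGGenParams,
    kernel: ComponentKernel | None = None,
    grid: TimeGrid = DEFAULT_GRID,
    cfg: erp.ScoringConfig = erp.ScoringConfig(),
) -> list[EpochSet]:
    """Simulate error- and correct-condition epoch sets for a cohort.

    Per subject, true ERN/CRN amplitudes are drawn from the population
    normals and each trial is the calibrated component plus the morphology
    anchor, latency-jittered and noise-corrupted.  Deterministic given
    ``params.seed``; ground truth is recorded on every EpochSet.
    """
    kernel = kernel or ComponentKernel()
    notch = ComponentKernel(center_ms=kernel.center_ms, width_ms=DEFAULT_NOTCH_WIDTH_MS)
    gain = calibrate_kernel_gain(kernel, grid, cfg)
    rho = _anchor_ratio(kernel, notch, grid, cfg, params.latency_jitter_sd_ms)
    rng = np.random.default_rng(params.seed)
    out: list[EpochSet] = []
    for i in range(params.n_subjects):
        sid = f"s{i + 1:03d}"
        a_ern = rng.normal(params.pop_mean_ern_uv, params.pop_sd_ern_uv)
        a_crn = rng.normal(params.pop_mean_crn_uv, params.pop_sd_crn_uv)
        n_err = _epoch_count(rng, params.epochs_error_mean, params.epochs_error_sd, params.min_epochs)
        n_cor = _epoch_count(rng, params.epochs_correct_mean, params.epochs_correct_sd, params.min_epochs)
        out.append(
            _simulate_subject_condition(
                rng, sid, "error", a_ern, n_err, params, kernel, notch, gain, rho, grid
            )
        )
        out.append(
            _simulate_subject_condition(
                rng, sid, "correct", a_crn, n_cor, params, kernel, notch, gain, rho, grid
            )
        )
    return out


# ------------------------------------------------------------ reliability


def simulate_split_half(
    noise_sd_uv: float,
    n_epochs: int,
    between_sd_uv: float,
    pop_mean_uv: float = -3.11,
    n_subjects: int = 196,
    seed: int = 0,
    kernel: ComponentKernel | None = None,
    anchor_depth_uv: float = DEFAULT_ANCHOR_DEPTH_UV,
    grid: TimeGrid = DEFAULT_GRID,
    cfg: erp.ScoringConfig | None = None,
) -> dict[str, float]:
    """Forward simulation of even/odd split-half reliability.

    Simulates a cohort with the given per-epoch sample-noise SD and fixed
    per-subject epoch count, scores even- and odd-indexed epoch averages
    with the adaptive mean, and returns the Pearson split-half correlation
    with its Spearman–Brown projection.  The threshold-rejection step is
    not applied here: the derived noise is a score-level abstraction of
    total trial-to-trial variability, not raw-EEG artifact amplitude.
    """
    cfg = cfg or erp.ScoringConfig()
    params = EEGGenParams(
        n_subjects=n_subjects,
        pop_mean_ern_uv=pop_mean_uv,
        pop_sd_ern_uv=between_sd_uv,
        epochs_error_mean=float(n_epochs),
        epochs_error_sd=0.0,
        epochs_correct_mean=float(n_epochs),
        epochs_correct_sd=0.0,
        epoch_noise_sd_uv=noise_sd_uv,
        latency_jitter_sd_ms=0.0,
        anchor_depth_uv=anchor_depth_uv,
        seed=seed,
    )
    epoch_sets = simulate_epochs(params, kernel, grid, cfg)
    cohort = {
        e.subject_id: erp.baseline_correct(e, cfg)
        for e in epoch_sets
        if e.condition == "error"
    }
    return erp.split_half_reliability(cohort, cfg, "adaptive_mean")


def derive_noise_for_reliability(
    target_r: float,
    n_epochs: float,
    between_sd_uv: float,
    pop_mean_uv: float = -3.11,
    kernel: ComponentKernel | None = None,
    anchor_depth_uv: float = DEFAULT_ANCHOR_DEPTH_UV,
    seed: int = 12345,
    n_sims: int = 600,
    grid: TimeGrid = DEFAULT_GRID,
) -> float:
    """Per-epoch sample-noise SD hitting a target split-half reliability.

    Solves σ such that the classical reliability r = σ_b² / (σ_b² + v_half)
    of the half-average score matches the Spearman–Brown-corrected target,
    where v_half — the effective score-noise variance of the adaptive-mean
    estimator applied to an (n_epochs/2)-epoch average — is estimated by a
    small internal Monte-Carlo, since peak picking is nonlinear.
    """
    if not 0.0 < target_r < 1.0:
        raise ValueError("target_r must lie strictly between 0 and 1")
    if n_epochs < 2:
        raise ValueError("n_epochs must be at least 2")
    r_half_target = target_r / (2.0 - target_r)  # invert Spearman–Brown
    v_target = between_sd_uv**2 * (1.0 / r_half_target - 1.0)
    if v_target <= 0:
        return 0.0

    kernel = kernel or ComponentKernel()
    notch = ComponentKernel(center_ms=kernel.center_ms, width_ms=DEFAULT_NOTCH_WIDTH_MS)
    cfg = erp.ScoringConfig()
    gain = calibrate_kernel_gain(kernel, grid, cfg)
    rho = _anchor_ratio(kernel, notch, grid, cfg, 0.0)
    n_half = int(math.ceil(n_epochs / 2.0))

    def score_noise_var(sigma: float) -> float:
        rng = np.random.default_rng(seed)  # common random numbers
        base = (pop_mean_uv * gain + rho * anchor_depth_uv) * kernel.bump(
            grid.times
        ) - anchor_depth_uv * notch.bump(grid.times)
        scores = np.empty(n_sims)
        for k in range(n_sims):
            avg = base + rng.normal(0.0, sigma / np.sqrt(n_half), size=grid.n_samples)
            # per-epoch baseline correction of white noise adds the baseline
            # mean back onto every sample; reproduce that on the average
            bl = avg[grid.window_indices(-400.0, -200.0)].mean()
            scores[k] = erp.adaptive_mean(avg - bl, cfg, grid).value_uv
        return float(scores.var(ddof=1))

    # v(σ) is very nearly proportional to σ²; two multiplicative updates
    sigma = float(np.sqrt(v_target * n_half * 21))  # white-noise first guess
    for _ in range(3):
        v = score_noise_var(sigma)
        sigma *= float(np.sqrt(v_target / v))
    return sigma


# ------------------------------------------------------------------- I/O


def write_epochs_h5(path, epoch_sets: list[EpochSet]) -> None:
    """Write a cohort to HDF5: /subjects/<id>/<condition> datasets (float32 μV)."""
    with h5py.File(path, "w") as f:
        root = f.create_group("subjects")
        for e in epoch_sets:
            grp = root.require_group(e.subject_id)
            ds = grp.create_dataset(e.condition, data=e.data.astype(np.float32))
            ds.attrs["rate_hz"] = e.grid.rate_hz
            ds.attrs["start_ms"] = e.grid.start_ms
            if e.true_amplitude_uv is not None:
                ds.attrs["true_amplitude_uv"] = e.true_amplitude_uv


def read_epochs_h5(path) -> list[EpochSet]:
    out: list[EpochSet] = []
    with h5py.File(path, "r") as f:
        for sid in sorted(f["subjects"]):
            for condition in sorted(f["subjects"][sid]):
                ds = f["subjects"][sid][condition]
                grid = TimeGrid(
                    start_ms=float(ds.attrs["start_ms"]),
                    end_ms=float(ds.attrs["start_ms"])
                    + (ds.shape[1] - 1) * 1000.0 / float(ds.attrs["rate_hz"]),
                    rate_hz=float(ds.attrs["rate_hz"]),
                )
                out.append(
                    EpochSet(
                        subject_id=sid,
                        condition=condition,
                        data=np.asarray(ds, dtype=float),
                        grid=grid,
                        true_amplitude_uv=float(ds.attrs["true_amplitude_uv"])
                        if "true_amplitude_uv" in ds.attrs
                        else None,
                    )
                )
    return out


def epochs_to_long_df(epoch_sets: list[EpochSet]) -> pd.DataFrame:
    """Long CSV-friendly layout: subject, condition, trial, time_ms, uv."""
    frames = []
    for e in epoch_sets:
        n, m = e.data.shape
        frames.append(
            pd.DataFrame(
                {
                    "subject": np.repeat(e.subject_id, n * m),
                    "condition": e.condition,
                    "trial": np.repeat(np.arange(n), m),
                    "time_ms": np.tile(e.grid.times, n),
                    "uv": e.data.ravel(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
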