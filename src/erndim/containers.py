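"""Shared in-memory containers for response-locked EEG epochs."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class TimeGrid:
    """Fixed response-locked epoch grid: −400…500 ms at 250 Hz (4 ms step)."""

    start_ms: float = -400.0
    end_ms: float = 500.0
    rate_hz: float = 250.0

    @property
    def step_ms(self) -> float:
        return 1000.0 / self.rate_hz

    @property
    def n_samples(self) -> int:
        return int(round((self.end_ms - self.start_ms) / self.step_ms)) + 1

    @property
    def times(self) -> np.ndarray:
        return self.start_ms + self.step_ms * np.arange(self.n_samples)

    def window_indices(self, lo_ms: float, hi_ms: float) -> np.ndarray:
        """Indices of samples with lo_ms <= t <= hi_ms (inclusive ends)."""
        t = self.times
        return np.nonzero((t >= lo_ms - 1e-9) & (t <= hi_ms + 1e-9))[0]


DEFAULT_GRID = TimeGrid()


@dataclass
class EpochSet:
    """Single-trial response-locked epochs for one subject and condition.

    ``data`` is an (n_trials, n_samples) amplitude matrix in μV on ``grid``.
    ``true_amplitude_uv`` carries the generator's ground truth when the
    epochs are simulated; it is absent (None) for real data.
    """

    subject_id: str
    condition: str  # "error" | "correct"
    data: np.ndarray
    grid: TimeGrid = field(default_factory=TimeGrid)
    true_amplitude_uv: float | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("EpochSet.data must be 2-D (n_trials × n_samples)")
        if self.data.shape[1] != self.grid.n_samples:
            raise ValueError(
                f"EpochSet.data has {self.data.shape[1]} samples; "
                f"grid defines {self.grid.n_samples}"
            )
        if self.data.shape[0] < 1:
            raise ValueError("EpochSet needs at least one epoch")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("EpochSet.data contains non-finite values")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    def replace_data(self, data: np.ndarray) -> "EpochSet":
        return EpochSet(
            subject_id=self.subject_id,
            condition=self.condition,
            data=data,
            grid=self.grid,
            true_amplitude_uv=self.true_amplitude_uv,
        )
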