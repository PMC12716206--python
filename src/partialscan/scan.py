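"""Slow-axis scan signal, acquisition timing, and partial acquisition.

Skipping lines is realised on the instrument by modifying the slow-axis
(Y) waveform: instead of stepping over skipped lines (which excites piezo
creep), the Y ramp simply becomes steeper — across a run of ``k`` skipped
lines the stage advances ``k + 1`` line pitches within a single line
period.  Acquisition time is proportional to the number of scanned
lines, so the time saving fraction equals the masked fraction.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import DimensionError, ParameterError, StateError
from .heightmap import UNIT_NORMALIZED, HeightMap, MaskRaster
from .masks import LineMask, expand_mask

__all__ = [
    "ScanSignal",
    "TimingModel",
    "build_y_signal",
    "partial_scan_time",
    "acquire_partial",
]

SKIP_PLACEHOLDER = 0.0  # value written into skipped rows (normalized units)


@dataclass
class ScanSignal:
    """Piecewise-linear slow-axis waveform.

    ``times``/``y_positions`` are the breakpoints of the ramp: during the
    line period starting at ``times[i]`` the stage scans the line at
    ``y_positions[i]`` while ramping toward ``y_positions[i+1]``.
    """

    times: np.ndarray  # seconds, length n_segments + 1
    y_positions: np.ndarray  # line units, length n_segments + 1
    line_period: float
    ramp_policy: str = "ramped"

    @property
    def n_segments(self) -> int:
        """Number of dwell segments = number of scanned lines."""
        return self.times.size - 1

    @property
    def total_time(self) -> float:
        return float(self.times[-1])

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        np.savetxt(path, np.column_stack([self.times, self.y_positions]),
                   delimiter=",", header="t_seconds,y_line_units", comments="")
        return path


@dataclass
class TimingModel:
    """Proportional acquisition-time model."""

    full_scan_time: float  # seconds for the all-lines scan
    proportional: bool = True

    def __post_init__(self) -> None:
        if self.full_scan_time <= 0:
            raise ParameterError("full_scan_time must be positive")


def build_y_signal(lm: LineMask, line_period: float) -> ScanSignal:
    """Compute the modified slow-axis waveform for a line mask.

    One dwell segment per scanned line; across a run of skipped lines the
    position advances by (run length + 1) within one line period.
    """
    if line_period <= 0:
        raise ParameterError("line_period must be positive")
    scanned = np.flatnonzero(lm.keep).astype(float)
    n_s = scanned.size
    times = np.arange(n_s + 1, dtype=float) * line_period
    y = np.concatenate([scanned, [scanned[-1] + 1.0]])
    return ScanSignal(times=times, y_positions=y, line_period=line_period)


def partial_scan_time(lm: LineMask, tm: TimingModel, from_counts: bool = False) -> int:
    """Partial-scan acquisition time in whole seconds.

    Proportional model: ``full_scan_time * (1 - p)`` with ``p`` the
    requested masked fraction (the fraction the instrument is configured
    with).  ``from_counts=True`` uses the realized scanned-line count
    instead.
    """
    if from_counts:
        frac_scanned = (lm.n_lines - lm.n_skipped) / lm.n_lines
    else:
        frac_scanned = 1.0 - lm.fraction
    return round(tm.full_scan_time * frac_scanned)


def acquire_partial(h: HeightMap, lm: LineMask) -> tuple[HeightMap, MaskRaster]:
    """Simulate partial acquisition: keep scanned rows, zero skipped rows.

    Scanned rows are copied verbatim (bit-exact); skipped rows are set to
    the placeholder value 0 in normalized units.
    """
    if h.norm_state != UNIT_NORMALIZED:
        raise StateError("acquire_partial expects a unit-normalized map")
    if lm.n_lines != h.n_rows:
        raise DimensionError(
            f"mask has {lm.n_lines} lines but image has {h.n_rows} rows"
        )
    out = h.values.copy()
    out[~lm.keep, :] = SKIP_PLACEHOLDER
    partial = HeightMap(values=out, pixel_size=h.pixel_size, unit=h.unit,
                        norm_state=h.norm_state, norm_params=h.norm_params)
    return partial, expand_mask(lm, h.n_cols)
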