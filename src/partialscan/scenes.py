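"""Synthetic SICM-like topography scenes.

Real training data for the reconstruction models are topography frames of
cultured cells (fibroblast-like cells, melanoma, neuroblastoma, cortical
neurons).  This module emulates their morphology so every downstream
stage is trainable and testable without instrument data:

* a gently tilted substrate plane,
* smooth compact elevations 1–5 µm high (cell bodies / somata),
* curvilinear sub-micrometre ridges (neurites, filopodia) drawn as
  smoothed random walks,
* band-limited surface texture,
* per-line offset noise (SICM acquires line by line, so each row carries
  its own small height offset — this is what makes median-line
  baselines meaningful),
* independent pixel noise,
* optionally, "scar" rows displaced by feedback-overshoot-like offsets.

Scenes are deterministic per seed, and datasets derive per-scene
sub-seeds with a counter-based scheme so a dataset can be extended
without reshuffling existing scenes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import ParameterError, StateError
from .heightmap import HeightMap
from .masks import LineMask

__all__ = ["SceneParams", "ScarSpec", "generate_scene", "add_scars", "generate_dataset"]


@dataclass
class SceneParams:
    """Morphology and noise parameters of a synthetic scene (heights in µm)."""

    image_size: tuple[int, int] = (96, 96)
    n_cell_bodies: int = 3
    body_height_range: tuple[float, float] = (1.0, 5.0)
    body_radius_range: tuple[float, float] = (10.0, 28.0)  # pixels
    n_ridges: int = 6
    ridge_height_range: tuple[float, float] = (0.1, 0.4)
    ridge_width_range: tuple[float, float] = (1.0, 2.5)  # pixels (Gaussian sigma)
    background_tilt: float = 0.004  # max plane slope, µm per pixel
    texture_amplitude: float = 0.04
    line_noise_sd: float = 0.02  # per-row offset, µm
    pixel_noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.image_size) < 16:
            raise ParameterError(f"image_size must be >= 16 per side, got {self.image_size}")
        for name in ("body_height_range", "body_radius_range",
                     "ridge_height_range", "ridge_width_range"):
            lo, hi = getattr(self, name)
            if lo < 0 or hi < lo:
                raise ParameterError(f"{name} must be a non-negative (lo, hi) pair")
        for name in ("background_tilt", "texture_amplitude",
                     "line_noise_sd", "pixel_noise_sd"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be non-negative")


@dataclass
class ScarSpec:
    """Placement of scan-line artifacts (scars)."""

    n_scars: int = 4
    scar_rows: list[int] | None = None
    scar_length_range: tuple[int, int] | None = None  # None -> full row
    scar_offset_range: tuple[float, float] = (0.3, 1.0)  # µm, sign randomized
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_scars < 0:
            raise ParameterError("n_scars must be non-negative")
        lo, hi = self.scar_offset_range
        if lo <= 0 or hi < lo:
            raise ParameterError("scar_offset_range must be a positive (lo, hi) pair")


def _sample(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(rng.uniform(lo, hi)) if hi > lo else float(lo)


def _ridge_path(rng: np.random.Generator, m: int, n: int) -> np.ndarray:
    """Smoothed random-walk path of (row, col) points, unit step length."""
    length = int(rng.integers(min(m, n) // 2, int(1.2 * max(m, n))))
    pos = np.array([rng.uniform(0, m - 1), rng.uniform(0, n - 1)])
    theta = rng.uniform(0, 2 * np.pi)
    pts = [pos.copy()]
    for _ in range(length):
        theta += rng.normal(0.0, 0.25)
        pos = pos + np.array([np.sin(theta), np.cos(theta)])
        if not (0 <= pos[0] <= m - 1 and 0 <= pos[1] <= n - 1):
            break
        pts.append(pos.copy())
    return np.array(pts)


def generate_scene(p: SceneParams) -> HeightMap:
    """Render one synthetic raw-unit topography frame, deterministic per seed."""
    m, n = p.image_size
    rng = np.random.default_rng(p.seed)
    rows = np.arange(m, dtype=float)[:, None]
    cols = np.arange(n, dtype=float)[None, :]

    sy = _sample(rng, -p.background_tilt, p.background_tilt) if p.background_tilt else 0.0
    sx = _sample(rng, -p.background_tilt, p.background_tilt) if p.background_tilt else 0.0
    z = sy * rows + sx * cols + np.zeros((m, n))

    for _ in range(p.n_cell_bodies):
        # integer centres so the sampled peak amplitude is attained exactly
        cy = int(rng.integers(0, m))
        cx = int(rng.integers(0, n))
        amp = _sample(rng, *p.body_height_range)
        radius = _sample(rng, *p.body_radius_range)
        if amp <= 0 or radius <= 0:
            continue
        sigma = radius / 2.0
        z += amp * np.exp(-((rows - cy) ** 2 + (cols - cx) ** 2) / (2 * sigma**2))

    for _ in range(p.n_ridges):
        amp = _sample(rng, *p.ridge_height_range)
        width = _sample(rng, *p.ridge_width_range)
        path = _ridge_path(rng, m, n)
        if amp <= 0 or width <= 0 or len(path) < 2:
            continue
        stamp = np.zeros((m, n))
        ry = np.clip(np.rint(path[:, 0]).astype(int), 0, m - 1)
        rx = np.clip(np.rint(path[:, 1]).astype(int), 0, n - 1)
        stamp[ry, rx] = 1.0
        ridge = gaussian_filter(stamp, width)
        peak = ridge.max()
        if peak > 0:
            z += amp * ridge / peak

    if p.texture_amplitude > 0:
        tex = gaussian_filter(rng.standard_normal((m, n)), 3.0)
        span = tex.std()
        if span > 0:
            z += p.texture_amplitude * tex / (3 * span)

    if p.line_noise_sd > 0:
        z += rng.normal(0.0, p.line_noise_sd, size=m)[:, None]
    if p.pixel_noise_sd > 0:
        z += rng.normal(0.0, p.pixel_noise_sd, size=(m, n))

    return HeightMap(values=z, pixel_size=None, unit="um")


def add_scars(h: HeightMap, s: ScarSpec) -> tuple[HeightMap, LineMask]:
    """Displace selected rows (or row segments) and return the ground-truth mask.

    Untouched pixels are bit-identical to the input; the returned LineMask
    has keep=0 exactly on the scarred rows.  Scars are acquisition
    artifacts with physical (µm) offsets, so the input must be a
    raw-state map (normalize afterwards).
    """
    if h.norm_state != "raw":
        raise StateError("add_scars expects a raw-state map (scars precede normalization)")
    m, n = h.shape
    rng = np.random.default_rng(s.seed)
    if s.scar_rows is not None:
        rows = list(s.scar_rows)
        if any(r < 0 or r >= m for r in rows):
            raise ParameterError(f"scar rows {rows} out of range for {m} lines")
    else:
        k = min(s.n_scars, m - 2)
        rows = sorted(rng.choice(np.arange(1, m - 1), size=k, replace=False).tolist())

    out = h.values.copy()
    for r in rows:
        offset = _sample(rng, *s.scar_offset_range) * (1 if rng.random() < 0.5 else -1)
        if s.scar_length_range is None:
            out[r, :] += offset
        else:
            lo, hi = s.scar_length_range
            length = int(rng.integers(lo, hi + 1))
            length = max(1, min(length, n))
            start = int(rng.integers(0, n - length + 1))
            out[r, start : start + length] += offset

    keep = np.ones(m, dtype=bool)
    keep[rows] = False
    lm = LineMask(keep, float(len(rows)) / m, "scar", seed=s.seed)
    scarred = HeightMap(values=out, pixel_size=h.pixel_size, unit=h.unit,
                        norm_state=h.norm_state, norm_params=h.norm_params)
    return scarred, lm


def scene_seed(base_seed: int, index: int) -> int:
    """Counter-based sub-seed: stable under dataset extension."""
    return int((base_seed * 1_000_003 + index) % (2**31 - 1))


def generate_dataset(n: int, p: SceneParams, seed: int = 0) -> list[HeightMap]:
    """Generate ``n`` independent scenes from counter-derived sub-seeds."""
    if n < 1:
        raise ParameterError("need n >= 1 scenes")
    out = []
    for k in range(n):
        pk = SceneParams(**{**p.__dict__, "seed": scene_seed(seed, k)})
        out.append(generate_scene(pk))
    return out
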