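"""Line masks: which slow-axis scan lines are acquired versus skipped.

A line mask is a per-row boolean plan (1 = scan, 0 = skip) for a raster
of ``m`` lines.  The masked-line count is an exact function of the
requested fraction ``p``: ``round_half_up(p * m)`` lines are skipped, and
the first and last lines are always scanned so that both interpolation
and the inpainting models have anchored boundaries.

Patterns
--------
random
    Uniform choice among interior lines.
random_limited
    Uniform choice rejected until no run of consecutive skips exceeds
    ``max_consecutive`` (default 5).
fixed_distance
    Single skipped lines spaced as evenly as possible.
geometric
    Gaps between successive skipped lines grow geometrically.
block
    Skips grouped into contiguous runs of a given block length.

The controlled patterns are this package's own definitions of the named
ideas; instruments disagree on the fine print and only the exact-count
and kept-border invariants are load-bearing downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import InfeasibleMaskError, ParameterError
from .heightmap import HeightMap, MaskRaster

__all__ = [
    "LineMask",
    "round_half_up",
    "random_line_mask",
    "patterned_line_mask",
    "expand_mask",
    "extract_scar_mask",
]

PATTERNS = ("random", "random_limited", "fixed_distance", "geometric", "block", "scar")


def round_half_up(x: float) -> int:
    """Round with ties away from zero toward +inf (0.5 -> 1)."""
    return int(math.floor(x + 0.5))


@dataclass
class LineMask:
    """Boolean keep/skip vector for the slow axis with provenance."""

    keep: np.ndarray
    fraction: float
    pattern: str
    max_consecutive: int | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        self.keep = np.asarray(self.keep, dtype=bool)
        if self.keep.ndim != 1:
            raise ParameterError("keep must be a 1D boolean vector")
        if self.pattern not in PATTERNS:
            raise ParameterError(f"unknown pattern {self.pattern!r}")

    @property
    def n_lines(self) -> int:
        return self.keep.size

    @property
    def n_skipped(self) -> int:
        return int((~self.keep).sum())

    @property
    def skipped_rows(self) -> np.ndarray:
        return np.flatnonzero(~self.keep)

    def max_run(self) -> int:
        """Longest run of consecutive skipped lines."""
        run = best = 0
        for k in self.keep:
            run = 0 if k else run + 1
            best = max(best, run)
        return best


def _check_mpk(m: int, p: float) -> int:
    if m < 4:
        raise ParameterError(f"need at least 4 lines, got {m}")
    if not (0 <= p < 1):
        raise ParameterError(f"fraction must be in [0, 1), got {p}")
    k = round_half_up(p * m)
    if k > m - 2:
        raise InfeasibleMaskError(
            f"p={p} requires {k} skipped lines but only {m - 2} interior lines exist"
        )
    return k


def random_line_mask(
    m: int,
    p: float,
    max_consecutive: int | None = None,
    seed: int = 0,
    _max_attempts: int = 5000,
) -> LineMask:
    """Skip exactly round_half_up(p*m) uniformly chosen interior lines.

    With ``max_consecutive`` set, draws whose longest skip run exceeds the
    limit are rejected and redrawn (deterministic per seed).
    """
    k = _check_mpk(m, p)
    if max_consecutive is not None:
        if max_consecutive < 1:
            raise ParameterError("max_consecutive must be >= 1")
        # runs of <=c skips need a kept separator each: k + ceil(k/c) - 1 slots
        if k + math.ceil(k / max_consecutive) - 1 > m - 2:
            raise InfeasibleMaskError(
                f"max_consecutive={max_consecutive} infeasible for m={m}, p={p}"
            )
    rng = np.random.default_rng(seed)
    interior = np.arange(1, m - 1)
    for _ in range(_max_attempts):
        skip = rng.choice(interior, size=k, replace=False)
        keep = np.ones(m, dtype=bool)
        keep[skip] = False
        lm = LineMask(keep, p, "random" if max_consecutive is None else "random_limited",
                      max_consecutive, seed)
        if max_consecutive is None or lm.max_run() <= max_consecutive:
            return lm
    raise InfeasibleMaskError(
        f"no admissible draw in {_max_attempts} attempts for m={m}, p={p}, "
        f"max_consecutive={max_consecutive}"
    )


def _place_distinct(targets: np.ndarray, m: int) -> np.ndarray:
    """Map fractional interior positions to distinct integer rows in [1, m-2]."""
    pos = np.clip(np.rint(targets).astype(int), 1, m - 2)
    taken: set[int] = set()
    out = []
    for t in np.sort(pos):
        q = int(t)
        step = 0
        while True:
            for cand in (q + step, q - step):
                if 1 <= cand <= m - 2 and cand not in taken:
                    taken.add(cand)
                    out.append(cand)
                    break
            else:
                step += 1
                if step > m:
                    raise InfeasibleMaskError("cannot place requested skip count")
                continue
            break
    return np.array(sorted(out), dtype=int)


def patterned_line_mask(
    m: int,
    p: float,
    pattern: str,
    ratio: float = 1.3,
    block_length: int | None = None,
) -> LineMask:
    """Deterministic controlled-pattern mask with exactly round_half_up(p*m) skips."""
    k = _check_mpk(m, p)
    keep = np.ones(m, dtype=bool)
    if k == 0:
        return LineMask(keep, p, pattern)

    if pattern == "fixed_distance":
        # even spacing of single skips across [0, m-1] including virtual borders
        targets = (np.arange(1, k + 1) * (m - 1)) / (k + 1)
        skip = _place_distinct(targets, m)
    elif pattern == "geometric":
        if ratio <= 0:
            raise ParameterError("ratio must be positive")
        if k == 1:
            skip = np.array([(m - 1) // 2])
        else:
            cum = np.cumsum(ratio ** np.arange(k, dtype=float))
            cum = np.concatenate([[0.0], cum[:-1]])
            targets = 1 + (m - 3) * cum / cum[-1]
            skip = _place_distinct(targets, m)
    elif pattern == "block":
        bl = k if block_length is None else int(block_length)
        if bl < 1:
            raise ParameterError("block_length must be >= 1")
        n_blocks = math.ceil(k / bl)
        sizes = [bl] * (n_blocks - 1) + [k - bl * (n_blocks - 1)]
        n_keep = m - k
        if n_keep < n_blocks + 1:
            raise InfeasibleMaskError(
                f"block pattern infeasible: {n_blocks} blocks need {n_blocks + 1} kept gaps"
            )
        # distribute kept lines across the n_blocks+1 gaps as evenly as possible
        gaps = np.full(n_blocks + 1, n_keep // (n_blocks + 1), dtype=int)
        gaps[: n_keep % (n_blocks + 1)] += 1
        skip_list: list[int] = []
        row = 0
        for i, size in enumerate(sizes):
            row += gaps[i]
            skip_list.extend(range(row, row + size))
            row += size
        skip = np.array(skip_list, dtype=int)
    else:
        raise ParameterError(f"unknown controlled pattern {pattern!r}")

    if skip.size != k:
        raise InfeasibleMaskError(f"pattern produced {skip.size} skips, expected {k}")
    keep[skip] = False
    if not (keep[0] and keep[-1]):
        raise InfeasibleMaskError("pattern would skip a border line")
    return LineMask(keep, p, pattern)


def expand_mask(lm: LineMask, n: int) -> MaskRaster:
    """Broadcast a per-line mask to a 2D raster with constant rows."""
    if n < 1:
        raise ParameterError("column count must be >= 1")
    return MaskRaster(values=np.repeat(lm.keep[:, None].astype(float), n, axis=1))


def extract_scar_mask(
    h: HeightMap,
    z_thresh: float = 5.0,
    min_scar_cols: int | None = None,
    max_distance: int = 3,
) -> LineMask:
    """Detect scarred scan lines as rows that deviate from their neighbours.

    Two complementary references are computed for every pixel (i, j):

    * the median over d = 1..3 of the symmetric pair averages
      (v[i-d, j] + v[i+d, j]) / 2 — pairs cancel local slope and the
      median tolerates one scarred neighbour, which keeps narrow
      horizontal ridges from being mistaken for scars;
    * a vertical 9-row median filter — robust to clusters of up to four
      adjacent scarred rows, which keeps clean rows next to scar
      clusters from inheriting biased references.

    Each deviation map is turned into z-scores with its own global
    robust scale (1.4826 * MAD), and a pixel's score is the smaller of
    the two (a clean row is excused by whichever reference models it
    well; a scar is large against both).  A row is flagged when at least
    ``min_scar_cols`` pixels (default: a quarter of the width) exceed
    ``z_thresh``.  Full-row displacement scars from pipette overshoot
    are large against pixel and per-line offset noise, so the default
    threshold detects them without flagging clean rows.
    """
    from scipy.ndimage import median_filter

    m, n = h.shape
    if m < 5:
        raise ParameterError("need at least 5 rows for scar extraction")
    if min_scar_cols is None:
        min_scar_cols = max(4, n // 4)
    vals = h.values
    rows = np.arange(m)

    pairs = []
    for d in range(1, max_distance + 1):
        up = vals[np.clip(rows - d, 0, m - 1), :]
        dn = vals[np.clip(rows + d, 0, m - 1), :]
        pairs.append(0.5 * (up + dn))
    def zscores(dev: np.ndarray) -> np.ndarray:
        mad = np.median(np.abs(dev - np.median(dev)))
        return np.abs(dev) / (1.4826 * mad + 1e-15)

    z_pair = zscores(vals - np.median(np.stack(pairs), axis=0))
    z_vert = zscores(vals - median_filter(vals, size=(9, 1), mode="nearest"))
    z = np.minimum(z_pair, z_vert)
    scarred = (z > z_thresh).sum(axis=1) >= min_scar_cols
    return LineMask(~scarred, float(scarred.mean()), "scar")
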