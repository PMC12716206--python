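"""Image-quality metrics for original/reconstruction pairs.

MSE, PSNR, SSIM and Pearson correlation quantify pixel-wise and
structural fidelity; Canny edge density tracks preservation of fine
structure; the frequency-content ratio f_R/f_O compares high-frequency
spectral magnitude of a reconstruction against its original (values
below 1 indicate lost detail, above 1 added spurious detail).

SSIM follows the standard windowed definition (uniform window, sample
covariance, valid-region mean) with C1 = (0.01 L)^2, C2 = (0.03 L)^2 and
L = 1 for unit-normalized maps — the same algorithm as the established
scikit-image implementation, which the test suite uses as the
independent oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage.feature import canny

from .errors import DimensionError, MetricError, ParameterError
from .heightmap import HeightMap

__all__ = [
    "SSIMParams", "MetricsReport", "mse", "psnr", "ssim", "pearson",
    "edge_density", "frequency_ratio", "evaluate_pair", "evaluate_pairs",
]


def _values(x) -> np.ndarray:
    return x.values if isinstance(x, HeightMap) else np.asarray(x, dtype=np.float64)


def _pair(a, b) -> tuple[np.ndarray, np.ndarray]:
    av, bv = _values(a), _values(b)
    if av.shape != bv.shape:
        raise DimensionError(f"shape mismatch: {av.shape} vs {bv.shape}")
    return av, bv


@dataclass
class SSIMParams:
    """Window size and stabilization constants for SSIM (L = data range)."""

    window: int = 7
    data_range: float = 1.0

    def __post_init__(self) -> None:
        if self.window < 3 or self.window % 2 == 0:
            raise ParameterError("window must be odd and >= 3")
        if self.data_range <= 0:
            raise ParameterError("data_range must be positive")

    @property
    def c1(self) -> float:
        return (0.01 * self.data_range) ** 2

    @property
    def c2(self) -> float:
        return (0.03 * self.data_range) ** 2


def mse(a, b) -> float:
    """Mean squared pixel difference over all m*n pixels."""
    av, bv = _pair(a, b)
    return float(np.mean((av - bv) ** 2))


def psnr(a, b, max_i: float = 1.0) -> float:
    """Peak signal-to-noise ratio 10*log10(MAX_I^2 / MSE), in dB.

    Identical images return the +inf sentinel.
    """
    if max_i <= 0:
        raise ParameterError("max_i must be positive")
    err = mse(a, b)
    if err == 0:
        return math.inf
    return float(10.0 * np.log10(max_i**2 / err))


def _box_valid(x: np.ndarray, win: int) -> np.ndarray:
    c = np.pad(x.cumsum(0).cumsum(1), ((1, 0), (1, 0)))
    s = c[win:, win:] - c[:-win, win:] - c[win:, :-win] + c[:-win, :-win]
    return s / (win * win)


def ssim(a, b, window: int = 7, data_range: float = 1.0) -> float:
    """Mean structural similarity over sliding uniform windows."""
    av, bv = _pair(a, b)
    sp = SSIMParams(window=window, data_range=data_range)
    if window > min(av.shape):
        raise ParameterError(f"window {window} larger than image {av.shape}")
    np_win = window * window
    cov_norm = np_win / (np_win - 1)  # sample covariance
    ux, uy = _box_valid(av, window), _box_valid(bv, window)
    uxx, uyy = _box_valid(av * av, window), _box_valid(bv * bv, window)
    uxy = _box_valid(av * bv, window)
    vx = cov_norm * (uxx - ux * ux)
    vy = cov_norm * (uyy - uy * uy)
    vxy = cov_norm * (uxy - ux * uy)
    s = ((2 * ux * uy + sp.c1) * (2 * vxy + sp.c2)) / (
        (ux * ux + uy * uy + sp.c1) * (vx + vy + sp.c2))
    return float(s.mean())


def pearson(a, b) -> float:
    """Pearson correlation over flattened pixel pairs."""
    av, bv = _pair(a, b)
    x = av.ravel() - av.mean()
    y = bv.ravel() - bv.mean()
    denom = np.sqrt((x * x).sum() * (y * y).sum())
    if denom == 0:
        raise MetricError("Pearson correlation undefined for constant images")
    return float(np.clip((x * y).sum() / denom, -1.0, 1.0))


def edge_density(h, canny_sigma: float = 1.0,
                 thresholds: tuple[float, float] = (0.1, 0.2)) -> float:
    """Fraction of pixels flagged as edges by a Canny detector."""
    hv = _values(h)
    edges = canny(hv, sigma=canny_sigma,
                  low_threshold=thresholds[0], high_threshold=thresholds[1])
    return float(edges.mean())


def frequency_ratio(recon, orig, cutoff: float = 0.25) -> float:
    """High-frequency spectral magnitude ratio f_R / f_O.

    f(.) sums 2D FFT magnitudes at radial frequencies above
    ``cutoff`` * Nyquist (DC excluded); identical images give 1.0.
    """
    rv, ov = _pair(recon, orig)
    if not (0 < cutoff < 1):
        raise ParameterError("cutoff must be in (0, 1)")
    fy = np.fft.fftfreq(rv.shape[0])[:, None]
    fx = np.fft.fftfreq(rv.shape[1])[None, :]
    radial = np.sqrt(fy**2 + fx**2)
    band = radial > cutoff * 0.5  # Nyquist = 0.5 cycles/pixel
    f_r = np.abs(np.fft.fft2(rv))[band].sum()
    f_o = np.abs(np.fft.fft2(ov))[band].sum()
    if f_o == 0:
        raise MetricError("frequency content of the original is zero")
    return float(f_r / f_o)


@dataclass
class MetricsReport:
    """Per-pair (or aggregated) metric panel."""

    mse: float
    psnr: float
    ssim: float
    pearson_r: float
    edge_density_orig: float
    edge_density_recon: float
    freq_ratio: float
    n_images: int = 1
    sd: dict | None = None  # per-metric SD when aggregated

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in
             ("mse", "psnr", "ssim", "pearson_r", "edge_density_orig",
              "edge_density_recon", "freq_ratio", "n_images")}
        if self.sd is not None:
            d["sd"] = dict(self.sd)
        return d


def evaluate_pair(orig, recon, ssim_window: int = 7,
                  freq_cutoff: float = 0.25) -> MetricsReport:
    """Compute the full metric panel for one original/reconstruction pair."""
    return MetricsReport(
        mse=mse(orig, recon),
        psnr=psnr(orig, recon),
        ssim=ssim(orig, recon, window=ssim_window),
        pearson_r=pearson(orig, recon),
        edge_density_orig=edge_density(orig),
        edge_density_recon=edge_density(recon),
        freq_ratio=frequency_ratio(recon, orig, cutoff=freq_cutoff),
    )


def evaluate_pairs(pairs, ssim_window: int = 7,
                   freq_cutoff: float = 0.25) -> MetricsReport:
    """Aggregate the panel over (orig, recon) pairs: mean and SD per metric."""
    reports = [evaluate_pair(o, r, ssim_window, freq_cutoff) for o, r in pairs]
    if not reports:
        raise MetricError("no pairs to evaluate")
    keys = ("mse", "psnr", "ssim", "pearson_r", "edge_density_orig",
            "edge_density_recon", "freq_ratio")
    cols = {k: np.array([getattr(r, k) for r in reports]) for k in keys}
    means = {k: float(np.mean(v)) for k, v in cols.items()}
    # identical values (incl. the +inf PSNR sentinel) have zero spread
    sds = {k: 0.0 if np.all(v == v[0]) else float(np.std(v))
           for k, v in cols.items()}
    return MetricsReport(
        mse=means["mse"], psnr=means["psnr"], ssim=means["ssim"],
        pearson_r=means["pearson_r"],
        edge_density_orig=means["edge_density_orig"],
        edge_density_recon=means["edge_density_recon"],
        freq_ratio=means["freq_ratio"],
        n_images=len(reports), sd=sds,
    )
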