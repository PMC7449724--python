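"""Normalized reflection imaging.

Each raster pixel is reduced to the amplitude of the sample-to-reference
ratio |M| at one evaluation frequency (0.3 THz by default, where the contrast
between hydrated skin and glycerol-based drug solution is strong).  To cancel
piece-to-piece variation between skin samples, the after-treatment image is
normalized by the mean pre-treatment amplitude over the central 5x5 region of
interest:

    |M|_norm(i, j) = (|M(i, j)|_after - mean_ROI |M|_before)
                     / mean_ROI |M|_before

A pixel where drug solution has displaced tissue water has lower |M|, so
|M|_norm is more negative the more solution was delivered.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectroscopy import DEFAULT_BAND
from .synthetic import ImageRaster

__all__ = [
    "NormalizedImage",
    "DEFAULT_EVAL_FREQUENCY_THZ",
    "ROI_SIZE",
    "central_block",
    "pixel_amplitude",
    "normalize",
    "roi_mean",
]

#: evaluation frequency for imaging, THz
DEFAULT_EVAL_FREQUENCY_THZ = 0.3

#: the region of interest is the central ROI_SIZE x ROI_SIZE pixel block
ROI_SIZE = 5


def central_block(
    shape: tuple[int, int], size: int = ROI_SIZE
) -> tuple[slice, slice]:
    """Slices of the central ``size`` x ``size`` block, anchored at
    floor((dim - size)/2) in each dimension (rows/cols 17-21 on the default
    40x40 grid)."""
    ny, nx = shape
    if ny < size or nx < size:
        raise ValueError(f"grid must be at least {size}x{size}")
    i0 = (ny - size) // 2
    j0 = (nx - size) // 2
    return slice(i0, i0 + size), slice(j0, j0 + size)


@dataclass(frozen=True)
class NormalizedImage:
    """A normalized |M| image: ``grid`` holds |M|_norm per pixel,
    ``m_before_bar`` the pre-treatment ROI mean used as the reference,
    ``roi`` the central-block slices, ``f_eval`` the evaluation frequency."""

    grid: np.ndarray
    m_before_bar: float
    roi: tuple[slice, slice]
    f_eval: float = DEFAULT_EVAL_FREQUENCY_THZ

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        object.__setattr__(self, "grid", grid)
        if grid.ndim != 2:
            raise ValueError("grid must be 2-D")
        if not self.m_before_bar > 0:
            raise ValueError("m_before_bar must be positive")


def pixel_amplitude(
    raster: ImageRaster,
    f_eval: float = DEFAULT_EVAL_FREQUENCY_THZ,
    band: tuple[float, float] = DEFAULT_BAND,
    window: np.ndarray | None = None,
) -> np.ndarray:
    """Per-pixel |M| at the band bin nearest ``f_eval``.

    Runs the extraction chain on every pixel at once: subtract the shared
    baseline, Fourier-transform, divide by the baseline-subtracted air
    reference, and sample the amplitude at the evaluation frequency.
    ``window`` optionally tapers every trace before transforming.
    """
    if not band[0] <= f_eval <= band[1]:
        raise ValueError(
            f"f_eval={f_eval} THz outside the valid band {band}"
        )
    dt = float(raster.t[1] - raster.t[0])
    f = np.fft.rfftfreq(raster.t.size, d=dt)
    e_samp = raster.traces - raster.baseline.e
    e_air = raster.air_reference.e - raster.baseline.e
    if window is not None:
        e_samp = e_samp * window
        e_air = e_air * window
    in_band = (f >= band[0]) & (f <= band[1])
    if not np.any(in_band):
        raise ValueError("no frequency bins inside the valid band")
    candidates = np.flatnonzero(in_band)
    k = candidates[np.argmin(np.abs(f[candidates] - f_eval))]
    # transform only the column we need: dot with the DFT kernel at bin k
    kernel = np.exp(2j * np.pi * k * np.arange(raster.t.size) / raster.t.size)
    s_pix = e_samp @ kernel  # conjugate convention: e^{+i omega t}
    s_air = e_air @ kernel
    if np.abs(s_air) == 0:
        raise ValueError("reference spectrum vanishes at the evaluation bin")
    return np.abs(s_pix / s_air)


def normalize(
    before_field: np.ndarray,
    after_field: np.ndarray,
    f_eval: float = DEFAULT_EVAL_FREQUENCY_THZ,
) -> NormalizedImage:
    """Normalize an after-treatment |M| field by the before-treatment
    central-ROI mean (scale-free: invariant to a common rescaling)."""
    before = np.asarray(before_field, dtype=float)
    after = np.asarray(after_field, dtype=float)
    if before.shape != after.shape or before.ndim != 2:
        raise ValueError("before and after fields must be equal-shape 2-D")
    roi = central_block(before.shape)
    m_before_bar = float(np.mean(before[roi]))
    if m_before_bar <= 0:
        raise ValueError("pre-treatment ROI mean must be positive")
    grid = (after - m_before_bar) / m_before_bar
    return NormalizedImage(
        grid=grid, m_before_bar=m_before_bar, roi=roi, f_eval=f_eval
    )


def roi_mean(img: NormalizedImage) -> float:
    """Mean |M|_norm over the central region of interest."""
    return float(np.mean(img.grid[img.roi]))
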