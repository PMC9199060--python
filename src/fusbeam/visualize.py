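"""Intensity-field reconstruction and display.

Converts the DAS-GCF visualization image into a normalized estimate of the
FUS beam's intensity field: the RF image is scaled per pixel by an
echogenicity normalization factor derived from a smoothed, co-registered
B-mode image, then a sliding pulse intensity integral is applied along
depth. Fields are rendered as dB overlays on the B-mode.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.ndimage import uniform_filter

from .beamform import BeamformedImage, ImageGrid

__all__ = [
    "EchogenicityMap",
    "IntensityField",
    "smooth_bmode",
    "normalization_factor",
    "intensity_field",
    "overlay",
    "average_intensity",
]

NOISE_FLOOR_DB = 60.0  # pixels this far below B_max are treated as noise


@dataclass(frozen=True)
class EchogenicityMap:
    """Smoothed envelope B-mode with its maximum and a noise mask.

    ``noise_mask`` flags pixels whose dB value sits ``NOISE_FLOOR_DB`` or
    more below the image maximum.
    """

    B: np.ndarray  # (nz, nx), >= 0
    B_max: float
    noise_mask: np.ndarray  # (nz, nx) bool
    grid: ImageGrid

    def __post_init__(self) -> None:
        if np.any(self.B < 0):
            raise ValueError("smoothed B-mode must be nonnegative")
        if self.noise_mask.shape != self.B.shape:
            raise ValueError("noise mask shape mismatch")


@dataclass(frozen=True)
class IntensityField:
    """Reconstructed (or ground-truth) beam intensity on an image grid."""

    I: np.ndarray  # (nz, nx), >= 0, linear scale
    grid: ImageGrid
    pulse_length_samples: int
    axial_sample_period: float

    def __post_init__(self) -> None:
        if np.any(self.I < 0):
            raise ValueError("intensity must be nonnegative")
        if self.I.shape != self.grid.shape:
            raise ValueError("field shape does not match grid")

    @property
    def db(self) -> np.ndarray:
        """Field in dB normalized to its maximum (max(db) == 0); zero pixels
        map to -inf."""
        peak = self.I.max()
        if peak <= 0:
            raise ValueError("empty reconstruction: intensity is zero everywhere")
        with np.errstate(divide="ignore"):
            return 10.0 * np.log10(self.I / peak)

    @property
    def peak_position(self) -> tuple[float, float]:
        iz, ix = np.unravel_index(int(np.argmax(self.I)), self.I.shape)
        return float(self.grid.x_axis[ix]), float(self.grid.z_axis[iz])


def smooth_bmode(envelope: BeamformedImage, wavelength: float,
                 lateral_span: float = 5.5, axial_span: float = 7.0) -> EchogenicityMap:
    """Moving-average the envelope with a kernel spanning ``lateral_span``
    wavelengths laterally by ``axial_span`` wavelengths axially (rounded to
    odd pixel counts, replicate-padded borders), then locate the maximum and
    the 60 dB noise mask."""
    if envelope.kind != "bmode_envelope":
        raise ValueError("smooth_bmode expects a bmode_envelope image")
    grid = envelope.grid

    def _odd(n: float) -> int:
        k = max(1, int(round(n)))
        return k if k % 2 else k + 1

    kx = _odd(lateral_span * wavelength / grid.dx)
    kz = _odd(axial_span * wavelength / grid.dz)
    nz, nx = grid.shape
    if kx > nx or kz > nz:
        raise ValueError(
            f"smoothing kernel ({kz} x {kx} px) exceeds the image ({nz} x {nx} px)"
        )
    smoothed = np.clip(
        uniform_filter(np.abs(envelope.values), size=(kz, kx), mode="nearest"),
        0.0, None)
    b_max = float(smoothed.max())
    if b_max > 0:
        mask = smoothed <= b_max * 10.0 ** (-NOISE_FLOOR_DB / 20.0)
    else:
        mask = np.ones_like(smoothed, dtype=bool)
    return EchogenicityMap(B=smoothed, B_max=b_max, noise_mask=mask, grid=grid)


def normalization_factor(emap: EchogenicityMap) -> np.ndarray:
    """Per-pixel echogenicity factor ``B_max / B``; identity (1.0) on
    noise-masked pixels so noise is never amplified. Always >= 1."""
    if emap.B_max <= 0:
        raise ValueError("empty B-mode image: B_max is zero")
    factor = np.ones_like(emap.B)
    ok = ~emap.noise_mask
    factor[ok] = emap.B_max / emap.B[ok]
    return factor


def intensity_field(y_norm: BeamformedImage, pulse_length_samples: int,
                    axial_sample_period: float | None = None) -> IntensityField:
    """Sliding pulse intensity integral along depth.

    ``I[z, x] = sum_{i=0}^{L-1} dz * |y_norm[z + i, x]|^2`` with the window
    truncated at the bottom edge; L is the transmit pulse length in samples
    and dz the axial sample period of the image grid.
    """
    if pulse_length_samples < 1:
        raise ValueError("pulse length must be >= 1 sample")
    dz = axial_sample_period if axial_sample_period is not None else y_norm.grid.dz
    power = np.abs(y_norm.values) ** 2
    nz = power.shape[0]
    csum = np.vstack([np.zeros((1, power.shape[1])), np.cumsum(power, axis=0)])
    upper = np.minimum(np.arange(nz) + pulse_length_samples, nz)
    integral = dz * (csum[upper] - csum[np.arange(nz)])
    field = IntensityField(I=integral, grid=y_norm.grid,
                           pulse_length_samples=pulse_length_samples,
                           axial_sample_period=dz)
    if integral.max() <= 0:
        raise ValueError("empty reconstruction: intensity is zero everywhere")
    return field


def overlay(emap: EchogenicityMap, field: IntensityField,
            dyn_range_db: float = 10.0, bmode_range_db: float = 60.0,
            alpha: float = 0.6, cmap_name: str = "viridis") -> np.ndarray:
    """Composite RGBA image: grayscale B-mode with the top ``dyn_range_db``
    of the intensity field blended on in a second colormap. Deterministic;
    returns an (nz, nx, 4) float array in [0, 1]."""
    from matplotlib import colormaps

    if not emap.grid.same_as(field.grid):
        raise ValueError("B-mode and intensity field grids do not match")
    b = emap.B
    b_max = emap.B_max if emap.B_max > 0 else 1.0
    with np.errstate(divide="ignore"):
        b_db = 20.0 * np.log10(np.maximum(b, 1e-300) / b_max)
    gray = np.clip((b_db + bmode_range_db) / bmode_range_db, 0.0, 1.0)
    rgba = np.repeat(gray[:, :, None], 4, axis=2)
    rgba[:, :, 3] = 1.0

    f_db = field.db
    show = f_db >= -dyn_range_db
    if dyn_range_db > 0:
        level = np.clip((f_db + dyn_range_db) / dyn_range_db, 0.0, 1.0)
    else:
        level = np.where(show, 1.0, 0.0)
    colors = colormaps[cmap_name](level)
    rgba[show, :3] = (1 - alpha) * rgba[show, :3] + alpha * colors[show, :3]
    return rgba


def save_overlay_png(path, rgba: np.ndarray, grid: ImageGrid,
                     title: str = "") -> None:
    """Render the composite with physical axes (mm) to a PNG file."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    extent = [grid.x_axis[0] * 1e3, grid.x_axis[-1] * 1e3,
              grid.z_axis[-1] * 1e3, grid.z_axis[0] * 1e3]
    ax.imshow(rgba, extent=extent, aspect="equal")
    ax.set_xlabel("lateral x (mm)")
    ax.set_ylabel("depth z (mm)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def average_intensity(fields: Sequence[IntensityField]) -> IntensityField:
    """Pixel-wise mean of per-frame max-normalized linear fields, then
    re-normalized to its own maximum."""
    if not fields:
        raise ValueError("cannot average an empty list of fields")
    grid = fields[0].grid
    accum = np.zeros(grid.shape)
    for f in fields:
        if not f.grid.same_as(grid):
            raise ValueError("all fields must share one grid")
        peak = f.I.max()
        if peak <= 0:
            raise ValueError("cannot average an all-zero field")
        accum += f.I / peak
    mean = accum / len(fields)
    return IntensityField(I=mean / mean.max(), grid=grid,
                          pulse_length_samples=fields[0].pulse_length_samples,
                          axial_sample_period=fields[0].axial_sample_period)
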