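"""Ion-image reconstruction, intensity scaling and RGB composites.

An ion image maps each pixel to the summed intensity inside a narrow
mass window around a target m/z. By default no normalization is
applied (so images reflect the raw layer performance); per-pixel TIC
normalization is available. Composites stack three scaled ion images
into RGB channels, the standard way to display co-localized ions.

Pixels absent from the dataset grid are NaN ("missing"), never 0 —
a hole in the section is not the same as zero signal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io import MSIDataset
from .preprocess import PeakMatrix

__all__ = ["IonImage", "ion_image", "scale_image", "rgb_composite", "save_image"]

#: Color used for missing pixels in RGB composites (mid gray).
MISSING_COLOR = (0.5, 0.5, 0.5)


@dataclass
class IonImage:
    """A reconstructed single-ion intensity map on the dataset grid."""

    grid: np.ndarray          # (rows, cols), NaN where the pixel is missing
    target_mz: float
    tolerance: float
    normalization: str = "none"

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.grid)


def _resolve_tol(target_mz: float, tolerance: float, tolerance_unit: str) -> float:
    if tolerance_unit == "da":
        return tolerance
    if tolerance_unit == "ppm":
        return target_mz * tolerance * 1e-6
    raise ValueError(f"unknown tolerance unit {tolerance_unit!r} (use 'da' or 'ppm')")


def ion_image(
    data: MSIDataset | PeakMatrix,
    target_mz: float,
    tolerance: float = 0.1,
    tolerance_unit: str = "da",
    normalization: str = "none",
) -> IonImage:
    """Reconstruct the spatial intensity map of one mass window.

    Profile datasets sum the raw intensity within ``target ± tol``;
    peak matrices sum matching bin heights (centroid mode). With
    ``normalization="tic"`` each pixel is divided by its total
    intensity, which bounds values to [0, 1].
    """
    if normalization not in ("none", "tic"):
        raise ValueError(f"unknown normalization {normalization!r}")
    tol = _resolve_tol(target_mz, tolerance, tolerance_unit)
    lo, hi = target_mz - tol, target_mz + tol

    if isinstance(data, PeakMatrix):
        coords = data.coordinates
        mask = (data.bin_mz >= lo) & (data.bin_mz <= hi)
        vals = data.heights[:, mask].sum(axis=1)
        totals = data.heights.sum(axis=1)
    else:
        coords = data.coordinates
        vals = np.empty(data.n_pixels)
        totals = np.empty(data.n_pixels)
        for i, (mzv, inten) in enumerate(zip(data.mzs, data.intensities)):
            if lo < mzv[0] or hi > mzv[-1]:
                raise ValueError(
                    f"mass window [{lo:.4f}, {hi:.4f}] outside axis range "
                    f"[{mzv[0]:.4f}, {mzv[-1]:.4f}]"
                )
            i0, i1 = np.searchsorted(mzv, (lo, hi))
            vals[i] = float(np.sum(inten[i0:i1]))
            totals[i] = float(np.sum(inten))

    if normalization == "tic":
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = np.where(totals > 0, vals / totals, 0.0)

    rows = int(coords[:, 1].max()) + 1
    cols = int(coords[:, 0].max()) + 1
    grid = np.full((rows, cols), np.nan)
    grid[coords[:, 1], coords[:, 0]] = vals
    return IonImage(grid, target_mz, tol, normalization)


def scale_image(image: IonImage | np.ndarray, low_pct: float = 0.0, high_pct: float = 99.0):
    """Percentile-clip an image linearly into [0, 1].

    ``[P_low, P_high]`` maps to [0, 1]; values outside are clipped.
    Clipping the top percentile keeps one hot pixel from washing out
    the rest of the map. A constant image maps to all zeros; NaNs
    (missing pixels) pass through.
    """
    if low_pct >= high_pct:
        raise ValueError(f"low percentile ({low_pct}) must be < high ({high_pct})")
    grid = image.grid if isinstance(image, IonImage) else np.asarray(image, float)
    finite = grid[np.isfinite(grid)]
    if finite.size == 0:
        scaled = np.full_like(grid, np.nan)
    else:
        lo, hi = np.percentile(finite, [low_pct, high_pct])
        if hi <= lo:
            scaled = np.where(np.isnan(grid), np.nan, 0.0)
        else:
            scaled = np.clip((grid - lo) / (hi - lo), 0.0, 1.0)
    if isinstance(image, IonImage):
        return IonImage(scaled, image.target_mz, image.tolerance, image.normalization)
    return scaled


def rgb_composite(
    r: IonImage | np.ndarray,
    g: IonImage | np.ndarray,
    b: IonImage | np.ndarray,
    missing_color: tuple[float, float, float] = MISSING_COLOR,
) -> np.ndarray:
    """Stack three [0, 1]-scaled ion images into an (rows, cols, 3) raster.

    Missing pixels (NaN in any channel) are rendered in
    ``missing_color``. Channels must share the grid shape.
    """
    chans = [c.grid if isinstance(c, IonImage) else np.asarray(c, float) for c in (r, g, b)]
    if not (chans[0].shape == chans[1].shape == chans[2].shape):
        raise ValueError(f"channel shapes differ: {[c.shape for c in chans]}")
    rgb = np.stack(chans, axis=-1)
    missing = np.isnan(rgb).any(axis=-1)
    rgb = np.nan_to_num(rgb, nan=0.0)
    rgb[missing] = missing_color
    return rgb


def save_image(image, path, colormap: str = "viridis") -> None:
    """Write an ion image or RGB raster as PNG/TIFF.

    Single-channel images are percentile-scaled and mapped through
    ``colormap`` (perceptually uniform default; pass ``"jet"`` for the
    legacy rainbow look). RGB arrays are written as-is.
    """
    from PIL import Image as PILImage

    if isinstance(image, IonImage):
        arr = scale_image(image).grid
    else:
        arr = np.asarray(image, float)
    if arr.ndim == 2:
        import matplotlib

        rgba = matplotlib.colormaps[colormap](np.nan_to_num(arr, nan=0.0))
        rgba[np.isnan(arr)] = (*MISSING_COLOR, 1.0)
        out = (rgba[..., :3] * 255).round().astype(np.uint8)
    else:
        out = (np.clip(arr, 0, 1) * 255).round().astype(np.uint8)
    PILImage.fromarray(out).save(str(path))
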