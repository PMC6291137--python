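"""Spectral preprocessing: noise, peak picking, alignment, calibration.

The processing chain mirrors standard practice for internally
calibrated TOF imaging data:

1. resample/align every pixel spectrum onto one shared mass axis,
   label-free (no prior knowledge of which peaks are which);
2. compute the dataset mean spectrum;
3. fit an internal calibration on the mean spectrum against the
   gold-cluster + salt-cluster reference list (polynomial in sqrt(m),
   the natural TOF coordinate since m is proportional to t^2);
4. propagate that single model to every pixel;
5. pick peaks per pixel at S/N > 5 and bin them across pixels into a
   pixels x peak matrix.

S/N is defined here as apex height over a local robust noise level
(median-absolute-deviation based); the definition is parameterised
because different vendors disagree on it.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import signal as _signal
from scipy.fft import next_fast_len, irfft, rfft
from scipy.ndimage import minimum_filter1d, uniform_filter1d

from .chem import ReferencePeak, ppm_error
from .io import MSIDataset

__all__ = [
    "Peak",
    "PeakMatrix",
    "CalibrationModel",
    "CalibrationError",
    "estimate_noise",
    "estimate_baseline",
    "pick_peaks",
    "pick_peaks_dataset",
    "align_dataset",
    "mean_spectrum",
    "calibrate",
    "apply_calibration",
    "build_peak_matrix",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Peak:
    """A centroided peak: m/z, apex height, integrated area, S/N."""

    mz: float
    height: float
    area: float
    snr: float


class CalibrationError(RuntimeError):
    """Raised when internal calibration cannot be fitted."""


# -- noise and baseline ------------------------------------------------


def estimate_noise(
    intensity: np.ndarray, window: int = 512, floor: float = 1e-10
) -> np.ndarray:
    """Local robust noise level per axis point.

    The first difference of the spectrum removes smooth trends
    (baseline, peak flanks contribute only locally); its
    median-absolute-deviation within tiled windows, scaled by
    1.4826/sqrt(2), estimates the additive noise SD, which is then
    interpolated back to every axis point. Always >= ``floor``.
    """
    y = np.asarray(intensity, float)
    if window < 5:
        raise ValueError("noise window must be >= 5 points")
    if y.size < window:
        raise ValueError(f"spectrum ({y.size} points) shorter than noise window ({window})")
    d = np.diff(y)
    nb = max(1, d.size // window)
    blocks = d[: nb * window].reshape(nb, window)
    med = np.median(blocks, axis=1, keepdims=True)
    mad = np.median(np.abs(blocks - med), axis=1)
    sigma = mad * 1.4826 / math.sqrt(2.0)
    centers = (np.arange(nb) + 0.5) * window
    est = np.interp(np.arange(y.size), centers, sigma)
    return np.maximum(est, floor)


def estimate_baseline(intensity: np.ndarray, window: int = 2001, mode: str = "median") -> np.ndarray:
    """Smooth background level under sparse peaks.

    ``"median"`` (default) interpolates tiled-window medians — centred
    on the noise mean, robust as long as peaks cover well under half of
    each window. ``"minimum"`` is the classic rolling-minimum variant
    (sits at the lower noise envelope; useful for dense spectra).
    ``window`` should be much wider than a peak.
    """
    y = np.asarray(intensity, float)
    w = min(window, max(3, y.size // 2))
    if mode == "minimum":
        base = minimum_filter1d(y, size=w, mode="nearest")
        return uniform_filter1d(base, size=w, mode="nearest")
    if mode != "median":
        raise ValueError(f"unknown baseline mode {mode!r}")
    nb = max(1, y.size // w)
    blocks = y[: nb * w].reshape(nb, w)
    med = np.median(blocks, axis=1)
    centers = (np.arange(nb) + 0.5) * w
    return np.interp(np.arange(y.size), centers, med)


# -- peak picking ------------------------------------------------------


def _gaussian_centroid(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Apex position and height from a 3-point fit around the apex.

    Fits a parabola to log-intensity (exact for a noiseless Gaussian at
    any sampling) and falls back to a plain parabola when intensities
    are not all positive.
    """
    x1, x2, x3 = x
    y1, y2, y3 = y
    if min(y1, y2, y3) > 0:
        l1, l2, l3 = math.log(y1), math.log(y2), math.log(y3)
    else:
        l1, l2, l3 = y1, y2, y3
    d21, d32 = x2 - x1, x3 - x2
    denom = (l1 - l2) * d32 + (l3 - l2) * d21
    if denom == 0:
        return float(x2), float(y2)
    xv = x2 + 0.5 * ((l1 - l2) * d32 * d32 - (l3 - l2) * d21 * d21) / denom
    # clamp to the apex triplet; a degenerate fit must not jump away
    xv = min(max(xv, x1), x3)
    # parabola coefficients in (log-)space to evaluate the vertex value
    a = (l1 - l2) / (d21 * (d21 + d32)) + (l3 - l2) / (d32 * (d21 + d32))
    b = (l3 - l2) / d32 - a * d32
    lv = l2 + b * (xv - x2) + a * (xv - x2) ** 2
    hv = math.exp(lv) if min(y1, y2, y3) > 0 else lv
    return float(xv), float(hv)


def pick_peaks(
    mz: np.ndarray,
    intensity: np.ndarray,
    snr_min: float = 5.0,
    noise: np.ndarray | None = None,
    noise_window: int = 512,
    baseline_window: int = 2001,
    subtract_baseline: bool = True,
    smooth_window: int = 5,
    max_halfwidth_pts: int = 60,
) -> list[Peak]:
    """S/N-thresholded peak picking with Gaussian-apex centroiding.

    The (optionally baseline-subtracted) profile is lightly
    Savitzky-Golay smoothed (``smooth_window`` points, quadratic;
    0 disables) so isolated one-sample noise spikes cannot masquerade
    as peaks; S/N is the smoothed apex height over the *raw-signal*
    local robust noise, so the threshold semantics are unchanged.
    Local maxima above ``snr_min`` x noise are centroided by a 3-point
    log-parabolic fit; the area is a trapezoidal integral between the
    flanking minima (searched within ``max_halfwidth_pts`` samples).
    Returns peaks sorted by m/z.
    """
    mz = np.asarray(mz, float)
    y = np.asarray(intensity, float)
    if subtract_baseline:
        y = y - estimate_baseline(y, baseline_window)
    if noise is None:
        noise = estimate_noise(y, noise_window)
    if not np.isfinite(snr_min):
        return []
    if smooth_window >= 3 and y.size > smooth_window:
        y = _signal.savgol_filter(y, smooth_window, 2)
    idx, _ = _signal.find_peaks(y, height=snr_min * noise)
    idx = idx[(idx > 0) & (idx < y.size - 1)]
    peaks: list[Peak] = []
    for k in idx:
        c_mz, c_h = _gaussian_centroid(mz[k - 1 : k + 2], y[k - 1 : k + 2])
        if c_h <= 0:
            continue
        lo = k - 1
        stop = max(0, k - max_halfwidth_pts)
        lo = stop + int(np.argmin(y[stop : k + 1]))
        stop = min(y.size, k + max_halfwidth_pts + 1)
        hi = k + int(np.argmin(y[k:stop]))
        if hi <= lo + 1:
            area = 0.0
        else:
            area = float(np.trapezoid(y[lo : hi + 1], mz[lo : hi + 1]))
        peaks.append(Peak(c_mz, c_h, area, float(y[k] / noise[k])))
    peaks.sort(key=lambda p: p.mz)
    return peaks


def apex_mz(mz: np.ndarray, intensity: np.ndarray, target: float, window: float = 0.3) -> float:
    """Centroided apex position of the strongest peak near ``target``.

    Searches ``target ± window`` Da and refines the sample maximum with
    the 3-point Gaussian fit. Returns NaN when the window is empty or
    the apex sits on its edge.
    """
    mz = np.asarray(mz, float)
    y = np.asarray(intensity, float)
    lo, hi = np.searchsorted(mz, (target - window, target + window))
    if hi - lo < 3:
        return float("nan")
    k = lo + int(np.argmax(y[lo:hi]))
    if k <= lo or k >= hi - 1:
        return float("nan")
    c, _h = _gaussian_centroid(mz[k - 1 : k + 2], y[k - 1 : k + 2])
    return c


def pick_peaks_dataset(dataset: MSIDataset, snr_min: float = 5.0, **kw) -> list[list[Peak]]:
    """Per-pixel peak picking over a whole dataset."""
    return [
        pick_peaks(mzv, inten, snr_min=snr_min, **kw)
        for mzv, inten in zip(dataset.mzs, dataset.intensities)
    ]


# -- alignment ---------------------------------------------------------


def _window_lag(x: np.ndarray, ref: np.ndarray, max_lag: int) -> tuple[float, float]:
    """Sub-sample lag of ``x`` relative to ``ref`` by cross-correlation.

    Positive lag means the content of ``x`` sits at higher index than
    in ``ref``. Returns (lag, normalized correlation at the optimum).
    """
    x = x - x.mean()
    ref = ref - ref.mean()
    n = x.size
    nfft = next_fast_len(n + 2 * max_lag + 1)
    c = irfft(rfft(x, nfft) * np.conj(rfft(ref, nfft)), nfft)
    lags = np.concatenate([np.arange(0, max_lag + 1), np.arange(-max_lag, 0)])
    cvals = np.concatenate([c[: max_lag + 1], c[-max_lag:]])
    order = np.argsort(lags)
    lags, cvals = lags[order], cvals[order]
    k = int(np.argmax(cvals))
    lag = float(lags[k])
    if 0 < k < cvals.size - 1:
        y1, y2, y3 = cvals[k - 1 : k + 2]
        denom = y1 - 2 * y2 + y3
        if denom < 0:
            lag += 0.5 * (y1 - y3) / denom
    norm = math.sqrt(float(np.dot(x, x)) * float(np.dot(ref, ref)))
    ncc = float(cvals[k] / norm) if norm > 0 else 0.0
    return lag, ncc


def _fit_affine_shift(
    positions: np.ndarray, shifts: np.ndarray, weights: np.ndarray
) -> tuple[float, float]:
    """Weighted LS fit ``shift(m) = alpha*m + beta`` (constant if 1 point)."""
    if positions.size == 0:
        return 0.0, 0.0
    if positions.size == 1:
        return 0.0, float(shifts[0])
    w = weights / weights.sum()
    A = np.stack([positions, np.ones_like(positions)], axis=1)
    Aw = A * w[:, None]
    coef, *_ = np.linalg.lstsq(Aw.T @ A, Aw.T @ shifts, rcond=None)
    return float(coef[0]), float(coef[1])


def align_dataset(
    dataset: MSIDataset,
    n_segments: int = 8,
    n_anchors: int = 12,
    max_shift: float = 0.5,
    anchor_halfwidth: float = 0.4,
    min_ncc: float = 0.3,
    passes: int = 2,
) -> MSIDataset:
    """Align all spectra onto one shared mass axis, label-free.

    Each spectrum is compared with the running mean spectrum, first in
    ``n_segments`` broad mass segments (coarse pass), then in narrow
    windows around the ``n_anchors`` strongest mean-spectrum peaks
    (refinement passes). The per-window cross-correlation lags are
    converted to mass shifts and fitted by an affine model
    ``shift(m) = alpha*m + beta`` per spectrum — the exact form of an
    affine axis miscalibration — and the correction is applied by
    monotone interpolation. No peak identities are used at any point.
    """
    if dataset.n_pixels < 2:
        raise ValueError("alignment needs at least 2 pixels")
    # common target axis
    if dataset.shared_axis:
        axis = np.asarray(dataset.mz_axis, float)
        X = np.vstack([np.asarray(v, float) for v in dataset.intensities])
    else:
        lens = {len(a) for a in dataset.mzs}
        if len(lens) == 1:
            axis = np.mean(np.vstack(dataset.mzs), axis=0)
        else:
            lo = float(np.median([a[0] for a in dataset.mzs]))
            hi = float(np.median([a[-1] for a in dataset.mzs]))
            n = int(np.median([len(a) for a in dataset.mzs]))
            s = np.linspace(math.sqrt(lo), math.sqrt(hi), n)
            axis = s * s
        X = np.vstack(
            [np.interp(axis, mzv, inten) for mzv, inten in zip(dataset.mzs, dataset.intensities)]
        )
    n_px, n_pts = X.shape
    step = np.gradient(axis)

    for p in range(max(1, passes)):
        mean = X.mean(axis=0)
        windows: list[tuple[int, int, float]] = []  # (lo, hi, weight)
        if p == 0:
            bounds = np.linspace(0, n_pts, n_segments + 1).astype(int)
            for lo, hi in zip(bounds[:-1], bounds[1:]):
                if hi - lo > 16:
                    windows.append((int(lo), int(hi), 1.0))
        else:
            noise = estimate_noise(mean, min(512, max(8, n_pts // 4)))
            cand, props = _signal.find_peaks(mean, height=10.0 * noise)
            if cand.size:
                top = cand[np.argsort(props["peak_heights"])[::-1][: n_anchors * 2]]
                top = np.sort(top)
                kept: list[int] = []
                for k in top:
                    if all(abs(axis[k] - axis[j]) > 3 * anchor_halfwidth for j in kept):
                        kept.append(int(k))
                kept = sorted(kept, key=lambda k: -mean[k])[:n_anchors]
                for k in sorted(kept):
                    half = max(4, int(round(anchor_halfwidth / step[k])))
                    lo, hi = max(0, k - half), min(n_pts, k + half + 1)
                    windows.append((lo, hi, float(mean[k])))
            if not windows:
                break
        for i in range(n_px):
            pos, shifts, wts = [], [], []
            for lo, hi, w in windows:
                c = (lo + hi) // 2
                if p == 0:
                    seg = mean[lo:hi]
                    energy = seg - seg.min()
                    tot = energy.sum()
                    if tot > 0:
                        c = int(round(float(np.dot(np.arange(lo, hi), energy)) / tot))
                max_lag = int(min((hi - lo) // 3, math.ceil(max_shift / step[c])))
                if max_lag < 1:
                    continue
                lag, ncc = _window_lag(X[i, lo:hi], mean[lo:hi], max_lag)
                if ncc < min_ncc:
                    continue
                pos.append(axis[c])
                shifts.append(lag * step[c])
                wts.append(w * ncc)
            a, b = _fit_affine_shift(np.array(pos), np.array(shifts), np.array(wts))
            if a != 0.0 or b != 0.0:
                X[i] = np.interp(axis * (1.0 + a) + b, axis, X[i])

    return MSIDataset(
        dataset.coordinates.copy(),
        [axis] * n_px,
        [row for row in X],
        shared_axis=True,
        pixel_pitch=dataset.pixel_pitch,
        metadata={**dataset.metadata, "aligned": True},
    )


def mean_spectrum(dataset: MSIDataset) -> tuple[np.ndarray, np.ndarray]:
    """Arithmetic mean spectrum of a shared-axis dataset."""
    if not dataset.shared_axis:
        raise ValueError("mean spectrum requires a shared mass axis; align first")
    return dataset.mz_axis, dataset.intensity_matrix().mean(axis=0)


# -- calibration -------------------------------------------------------


@dataclass
class CalibrationModel:
    """Monotone observed -> calibrated m/z map, polynomial in sqrt(m).

    ``calibrated = P(sqrt(observed))`` where P has ``degree``
    coefficients + 1 (numpy polyval order). Degree 2 in sqrt(m)
    contains every affine miscalibration of the mass axis exactly.
    """

    coefficients: np.ndarray
    degree: int
    matched: list[tuple[str, float, float, float]]  # label, observed, reference, residual ppm
    unmatched: list[str] = field(default_factory=list)
    fit_range: tuple[float, float] = (0.0, float("inf"))

    def __call__(self, mz):
        scalar = np.isscalar(mz)
        out = np.polyval(self.coefficients, np.sqrt(np.asarray(mz, float)))
        return float(out) if scalar else out

    @property
    def residuals_ppm(self) -> dict[str, float]:
        return {label: res for label, _obs, _ref, res in self.matched}

    def check_monotone(self, lo: float, hi: float, n: int = 10_000) -> bool:
        grid = np.linspace(lo, hi, n)
        return bool(np.all(np.diff(self(grid)) > 0))


def calibrate(
    mz: np.ndarray,
    intensity: np.ndarray,
    references: Sequence[ReferencePeak],
    search_window: float = 0.3,
    degree: int = 2,
    snr_min: float = 5.0,
) -> CalibrationModel:
    """Fit an internal calibration on one (mean) spectrum.

    Peaks are picked at S/N > ``snr_min``; each reference is matched to
    the most intense picked peak within ``search_window`` Da of its
    nominal m/z. A least-squares polynomial of the requested degree in
    sqrt(observed m/z) maps observed to reference masses. Falls back to
    degree 1 when fewer than 4 references match (a quadratic on 3
    points would have no redundancy). Raises :class:`CalibrationError`
    naming the missing references when the fit is underdetermined, or
    when the fitted map is not strictly increasing over the axis range.
    """
    mz = np.asarray(mz, float)
    peaks = pick_peaks(mz, intensity, snr_min=snr_min)
    pk_mz = np.array([p.mz for p in peaks])
    pk_h = np.array([p.height for p in peaks])
    matched: list[tuple[str, float, float]] = []
    unmatched: list[str] = []
    for ref in references:
        if pk_mz.size:
            inside = np.abs(pk_mz - ref.mz) <= search_window
        else:
            inside = np.zeros(0, bool)
        if not inside.any():
            unmatched.append(ref.label)
            continue
        cand = np.flatnonzero(inside)
        best = cand[np.argmax(pk_h[cand])]
        matched.append((ref.label, float(pk_mz[best]), ref.mz))
    eff_degree = degree if len(matched) >= 4 else min(degree, 1)
    if len(matched) < eff_degree + 1:
        raise CalibrationError(
            f"only {len(matched)} references matched (need >= {eff_degree + 1}); "
            f"missing: {unmatched}"
        )
    obs = np.array([m[1] for m in matched])
    ref_mz = np.array([m[2] for m in matched])
    coeffs = np.polyfit(np.sqrt(obs), ref_mz, eff_degree)
    model = CalibrationModel(
        coeffs,
        eff_degree,
        [],
        unmatched,
        (float(obs.min()), float(obs.max())),
    )
    if not model.check_monotone(float(mz[0]), float(mz[-1])):
        raise CalibrationError(
            f"degree-{eff_degree} calibration is not monotone over the axis range; "
            "try a lower degree"
        )
    model.matched = [
        (label, o, r, ppm_error(model(o), r)) for (label, o, r) in matched
    ]
    for label, _o, _r, res in model.matched:
        log.info("calibration reference %s: residual %.2f ppm", label, res)
    if unmatched:
        log.warning("unmatched calibration references: %s", unmatched)
    return model


def apply_calibration(data, model: CalibrationModel):
    """Map every m/z value through the calibration model.

    Accepts an :class:`MSIDataset` (axes are transformed; one model for
    all pixels), a list of :class:`Peak`, or a :class:`PeakMatrix`.
    Ordering is preserved because the model is monotone.
    """
    if isinstance(data, MSIDataset):
        lo, hi = model.fit_range
        if data.shared_axis:
            ax = model(data.mz_axis)
            new_mzs = [ax] * data.n_pixels
            out_lo, out_hi = float(data.mz_axis[0]), float(data.mz_axis[-1])
        else:
            new_mzs = [model(a) for a in data.mzs]
            out_lo = min(float(a[0]) for a in data.mzs)
            out_hi = max(float(a[-1]) for a in data.mzs)
        if out_lo < lo or out_hi > hi:
            log.info(
                "calibration extrapolated beyond matched references "
                "(%.4f-%.4f applied to %.4f-%.4f)", lo, hi, out_lo, out_hi,
            )
        return MSIDataset(
            data.coordinates.copy(), new_mzs, list(data.intensities),
            data.shared_axis, data.pixel_pitch, dict(data.metadata),
        )
    if isinstance(data, PeakMatrix):
        return PeakMatrix(data.coordinates.copy(), model(data.bin_mz), data.heights.copy())
    return [Peak(model(p.mz), p.height, p.area, p.snr) for p in data]


# -- peak matrix -------------------------------------------------------


@dataclass
class PeakMatrix:
    """Pixels x peak-bins intensity matrix after cross-pixel binning."""

    coordinates: np.ndarray  # (N, 2)
    bin_mz: np.ndarray       # (B,) intensity-weighted bin centres
    heights: np.ndarray      # (N, B), 0 where a pixel lacks the peak

    @property
    def n_bins(self) -> int:
        return len(self.bin_mz)

    def pixel_peaks(self, i: int) -> list[Peak]:
        """The i-th pixel's binned peaks as a PeakList (height == area proxy)."""
        mask = self.heights[i] > 0
        return [
            Peak(float(m), float(h), float(h), float("nan"))
            for m, h in zip(self.bin_mz[mask], self.heights[i, mask])
        ]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.heights, columns=[f"{m:.4f}" for m in self.bin_mz])
        df.insert(0, "y", self.coordinates[:, 1])
        df.insert(0, "x", self.coordinates[:, 0])
        return df


def build_peak_matrix(
    peak_lists: Sequence[Sequence[Peak]],
    coordinates: np.ndarray,
    bin_tolerance_ppm: float = 20.0,
) -> PeakMatrix:
    """Bin per-pixel peak lists into a pixels x bins matrix.

    Peaks from all pixels are pooled and sorted by m/z; a gap larger
    than ``bin_tolerance_ppm`` between consecutive peaks starts a new
    bin. Bin m/z is the intensity-weighted mean of its members; a pixel
    contributing several peaks to one bin has their heights summed.
    """
    coordinates = np.asarray(coordinates, int)
    entries = [
        (p.mz, p.height, i) for i, plist in enumerate(peak_lists) for p in plist
    ]
    if not entries:
        return PeakMatrix(coordinates, np.empty(0), np.zeros((len(peak_lists), 0)))
    entries.sort()
    mzv = np.array([e[0] for e in entries])
    gaps_ppm = np.diff(mzv) / mzv[1:] * 1e6
    bin_id = np.concatenate([[0], np.cumsum(gaps_ppm > bin_tolerance_ppm)])
    n_bins = int(bin_id[-1]) + 1
    heights = np.zeros((len(peak_lists), n_bins))
    wsum = np.zeros(n_bins)
    mzsum = np.zeros(n_bins)
    for (mz_i, h, px), b in zip(entries, bin_id):
        heights[px, b] += h
        wsum[b] += h
        mzsum[b] += h * mz_i
    return PeakMatrix(coordinates, mzsum / wsum, heights)
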