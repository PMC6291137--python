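"""Synthetic gold-nanolayer LDI-MSI datasets with known ground truth.

Emulates the acquisition this pipeline targets: a reflectron-TOF
instrument covering m/z 70–1200 with resolving power ~12,000 at
m/z 1000, gold cluster ions [Au]+..[Au5]+ plus the [KNaCl]+ and
[K2Cl]+ salt clusters in every pixel, region-structured metabolite
adduct ions, per-pixel affine mass miscalibration
(``m_obs = m_true*(1+alpha) + beta``), shot-like Gaussian noise, a
smooth low-amplitude baseline, and log-normal pixel-to-pixel intensity
variation.

Every dataset comes with a :class:`GroundTruth` (true m/z, true
per-pixel peak heights, injected drift per pixel) so calibration, peak
picking, metrics and imaging can all be tested against known answers.

Randomness is counter-based: one master seed, one independent
``numpy`` generator per pixel keyed ``[seed, pixel_index]``, so pixel
streams do not depend on evaluation order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .chem import ReferencePeak, default_reference_set, ion_mz
from .io import MSIDataset

__all__ = [
    "InstrumentModel",
    "SpeciesSpec",
    "BackgroundPeak",
    "PhantomScene",
    "GroundTruth",
    "default_instrument",
    "default_scene",
    "render_dataset",
]

#: m/z of the phosphocholine head-group fragment [C5H15NO4P]+, the
#: marker whose relative intensity quantifies in-source fragmentation.
PC_HEADGROUP_MZ = 184.0733


@dataclass(frozen=True)
class InstrumentModel:
    """Simulated TOF envelope and noise model.

    ``resolving_power`` is m/FWHM at m/z 1000. With
    ``fwhm_mode="constant_R"`` (default) FWHM(m) = m/R everywhere; the
    optional ``"sqrt_R"`` mode lets R grow as sqrt(m), i.e.
    FWHM(m) = sqrt(1000*m)/R. Axis sampling is uniform in sqrt(m)
    (TOF-like digitization) by default, uniform in m optionally.
    ``axis_points=None`` auto-sizes the axis to >= ~3.2 samples per
    FWHM at the narrowest peak. Drift standard deviations: ``drift_ppm_sd``
    for the multiplicative term (ppm), ``drift_da_sd`` for the additive
    term (Da).
    """

    mz_min: float = 70.0
    mz_max: float = 1200.0
    resolving_power: float = 12000.0
    axis_points: int | None = None
    axis_spacing: str = "sqrt"
    fwhm_mode: str = "constant_R"
    noise_sd: float = 1.0
    baseline_amplitude: float = 2.0
    baseline_decay: float = 300.0
    detector_offset: float | None = None
    drift_ppm_sd: float = 0.0
    drift_da_sd: float = 0.0

    def __post_init__(self) -> None:
        if not (self.mz_min < self.mz_max):
            raise ValueError("require mz_min < mz_max")
        if self.resolving_power <= 0:
            raise ValueError("resolving power must be positive")
        if self.axis_spacing not in ("sqrt", "linear"):
            raise ValueError(f"unknown axis spacing {self.axis_spacing!r}")
        if self.fwhm_mode not in ("constant_R", "sqrt_R"):
            raise ValueError(f"unknown fwhm mode {self.fwhm_mode!r}")

    def fwhm(self, mz):
        """Peak full width at half maximum at the given m/z, in Da."""
        mz = np.asarray(mz, float)
        if self.fwhm_mode == "constant_R":
            return mz / self.resolving_power
        return np.sqrt(1000.0 * mz) / self.resolving_power

    def _auto_points(self) -> int:
        samples_per_fwhm = 3.2
        if self.axis_spacing == "sqrt":
            s0, s1 = math.sqrt(self.mz_min), math.sqrt(self.mz_max)
            # FWHM expressed in sqrt(m) units: fwhm(m) / (2 sqrt(m))
            if self.fwhm_mode == "constant_R":
                w = s0 / (2.0 * self.resolving_power)  # narrowest at mz_min
            else:
                w = math.sqrt(1000.0) / (2.0 * self.resolving_power)
            return int(math.ceil((s1 - s0) / (w / samples_per_fwhm))) + 1
        w = float(self.fwhm(self.mz_min))
        return int(math.ceil((self.mz_max - self.mz_min) / (w / samples_per_fwhm))) + 1

    def axis(self) -> np.ndarray:
        """The shared (undrifted) m/z axis."""
        n = self.axis_points or self._auto_points()
        if self.axis_spacing == "sqrt":
            s = np.linspace(math.sqrt(self.mz_min), math.sqrt(self.mz_max), n)
            return s * s
        return np.linspace(self.mz_min, self.mz_max, n)

    def baseline(self, mz: np.ndarray) -> np.ndarray:
        """Smooth baseline: exponential chemical background + detector offset."""
        offset = 6.0 * self.noise_sd if self.detector_offset is None else self.detector_offset
        return self.baseline_amplitude * np.exp(-(mz - self.mz_min) / self.baseline_decay) + offset


def default_instrument(**overrides) -> InstrumentModel:
    """The standard simulated instrument (m/z 70–1200, R=12k at 1000)."""
    return InstrumentModel(**overrides)


@dataclass(frozen=True)
class SpeciesSpec:
    """One injected analyte ion: chemistry, location and abundance.

    Either give ``formula`` + ``adduct`` (the theoretical m/z is
    computed with the electron correction) or an explicit ``mz`` (for
    fragment ions or unidentified markers). ``region`` names a mask of
    the scene; ``mean_intensity`` is the mean rendered peak height in
    noise-sd units and ``cv`` the log-normal pixel-to-pixel coefficient
    of variation.
    """

    name: str
    region: str
    mean_intensity: float
    cv: float = 0.25
    formula: str | None = None
    adduct: str | None = None
    mz: float | None = None

    def theoretical_mz(self) -> float:
        if self.mz is not None:
            return float(self.mz)
        if self.formula is None or self.adduct is None:
            raise ValueError(f"species {self.name!r}: give formula+adduct or explicit mz")
        return ion_mz(self.formula, self.adduct, electron_correction=True)


@dataclass(frozen=True)
class BackgroundPeak:
    """A matrix/background ion present in every pixel (gold or salt cluster)."""

    reference: ReferencePeak
    mean_intensity: float
    cv: float = 0.15


@dataclass
class PhantomScene:
    """Spatial layout + chemistry of a synthetic section."""

    grid_shape: tuple[int, int]
    pixel_pitch: float
    regions: dict[str, np.ndarray]
    species: list[SpeciesSpec]
    background: list[BackgroundPeak]
    seed: int = 0

    def __post_init__(self) -> None:
        for label, mask in self.regions.items():
            mask = np.asarray(mask, bool)
            if mask.shape != tuple(self.grid_shape):
                raise ValueError(f"region {label!r} mask shape {mask.shape} != grid {self.grid_shape}")
            self.regions[label] = mask
        for sp in self.species:
            if sp.region not in self.regions:
                raise ValueError(f"species {sp.name!r} references unknown region {sp.region!r}")


def _default_background() -> list[BackgroundPeak]:
    refs = default_reference_set()  # KNaCl, K2Cl, Au1..Au5
    heights = {"KNaCl": 70.0, "K2Cl": 60.0, "Au1": 120.0, "Au2": 95.0,
               "Au3": 70.0, "Au4": 50.0, "Au5": 40.0}
    return [BackgroundPeak(r, heights[r.label]) for r in refs]


def default_scene(kind: str, seed: int = 0, grid_shape: tuple[int, int] | None = None) -> PhantomScene:
    """Canonical phantom scenes.

    ``"uniform"`` — homogeneous tissue (liver-like), every species in
    every pixel; ``"two_region"`` — two disjoint halves with disjoint
    species; ``"brain_like"`` — three morphological structures carrying
    the three ions used for RGB composites (845.4577, 849.6369 and
    213.04 Da) plus a region with cholesterol as both Na and K adducts.
    """
    frag = SpeciesSpec("PC head-group fragment", "all", 55.0, mz=PC_HEADGROUP_MZ)
    if kind == "uniform":
        shape = grid_shape or (8, 8)
        all_mask = np.ones(shape, bool)
        species = [
            frag,
            SpeciesSpec("Citrulline +Na", "all", 40.0, formula="C6H13N3O3", adduct="+Na"),
            SpeciesSpec("Cholesterol +Na", "all", 60.0, formula="C27H46O", adduct="+Na"),
            SpeciesSpec("PC(38:3) +Na", "all", 70.0, formula="C46H88NO7P", adduct="+Na"),
            SpeciesSpec("PS(38:7) +Na", "all", 45.0, formula="C44H72NO10P", adduct="+Na"),
            SpeciesSpec("TG(49:5) +K", "all", 50.0, formula="C52H90O6", adduct="+K"),
        ]
        return PhantomScene(shape, 100.0, {"all": all_mask}, species, _default_background(), seed)
    if kind == "two_region":
        shape = grid_shape or (12, 12)
        rows, cols = shape
        all_mask = np.ones(shape, bool)
        left = np.zeros(shape, bool)
        left[:, : cols // 2] = True
        right = ~left
        species = [
            frag,
            SpeciesSpec("Citrulline +Na", "left", 45.0, formula="C6H13N3O3", adduct="+Na"),
            SpeciesSpec("PC(38:3) +Na", "left", 65.0, formula="C46H88NO7P", adduct="+Na"),
            SpeciesSpec("Cholesterol +Na", "right", 55.0, formula="C27H46O", adduct="+Na"),
            SpeciesSpec("TG(49:5) +K", "right", 50.0, formula="C52H90O6", adduct="+K"),
        ]
        return PhantomScene(
            shape, 100.0, {"all": all_mask, "left": left, "right": right},
            species, _default_background(), seed,
        )
    if kind == "brain_like":
        shape = grid_shape or (20, 20)
        rows, cols = shape
        all_mask = np.ones(shape, bool)
        yy, xx = np.mgrid[0:rows, 0:cols]
        # cortex-like outer band / striatum-like disc / cerebellum-like wedge
        band = xx < cols // 3
        disc = (yy - rows / 2) ** 2 + (xx - cols / 2) ** 2 <= (min(rows, cols) / 4.5) ** 2
        disc &= ~band
        wedge = (xx >= 2 * cols // 3) & (yy >= rows // 4)
        wedge &= ~disc
        species = [
            frag,
            SpeciesSpec("PI(32:2) +K", "band", 70.0, formula="C41H75O13P", adduct="+K"),
            SpeciesSpec("TG(49:5) +K", "disc", 65.0, formula="C52H90O6", adduct="+K"),
            SpeciesSpec("m/z 213.04 marker", "wedge", 60.0, mz=213.04),
            SpeciesSpec("Cholesterol +Na", "band", 50.0, formula="C27H46O", adduct="+Na"),
            SpeciesSpec("Cholesterol +K", "band", 40.0, formula="C27H46O", adduct="+K"),
        ]
        return PhantomScene(
            shape, 80.0,
            {"all": all_mask, "band": band, "disc": disc, "wedge": wedge},
            species, _default_background(), seed,
        )
    raise ValueError(f"unknown scene kind {kind!r}")


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    coordinates: np.ndarray          # (N, 2) 0-based (x, y)
    species_names: list[str]
    species_mz: np.ndarray           # (S,) true m/z, species then background
    species_is_background: np.ndarray  # (S,) bool
    true_heights: np.ndarray         # (N, S) drawn peak heights (0 where absent)
    alpha: np.ndarray                # (N,) multiplicative drift (fractional)
    beta: np.ndarray                 # (N,) additive drift (Da)

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.true_heights, columns=self.species_names)
        df.insert(0, "y", self.coordinates[:, 1])
        df.insert(0, "x", self.coordinates[:, 0])
        df["alpha"] = self.alpha
        df["beta"] = self.beta
        return df


def _lognormal(rng: np.random.Generator, mean: float, cv: float) -> float:
    """Log-normal draw with the requested arithmetic mean and CV."""
    if cv <= 0:
        return mean
    s2 = math.log1p(cv * cv)
    mu = math.log(mean) - s2 / 2.0
    return float(rng.lognormal(mu, math.sqrt(s2)))


def render_dataset(
    scene: PhantomScene,
    instrument: InstrumentModel | None = None,
    seed: int | None = None,
) -> tuple[MSIDataset, GroundTruth]:
    """Render a phantom scene into profile spectra + ground truth.

    Each species/background peak contributes a Gaussian of the
    instrument FWHM at its true m/z; per-pixel drift perturbs only the
    *reported* axis (``axis_obs = axis_true*(1+alpha) + beta``), which
    is exactly how a miscalibrated TOF mislabels its samples. The
    dataset is shared-axis iff both drift SDs are zero.
    """
    instrument = instrument or default_instrument()
    if seed is None:
        seed = scene.seed
    axis = instrument.axis()
    rows, cols = scene.grid_shape
    coords = np.array([(x, y) for y in range(rows) for x in range(cols)])
    n_px = len(coords)

    all_specs: list[tuple[str, float, float, float, np.ndarray | None]] = []
    for sp in scene.species:
        all_specs.append((sp.name, sp.theoretical_mz(), sp.mean_intensity, sp.cv,
                          scene.regions[sp.region]))
    bg_start = len(all_specs)
    for bp in scene.background:
        all_specs.append((bp.reference.label, bp.reference.mz, bp.mean_intensity, bp.cv, None))

    out_of_range = [name for name, mz, *_ in all_specs
                    if not (instrument.mz_min <= mz <= instrument.mz_max)]
    if out_of_range:
        raise ValueError(f"species outside instrument m/z range: {out_of_range}")

    mz_true = np.array([mz for _, mz, *_ in all_specs])
    sigmas = np.asarray(instrument.fwhm(mz_true)) / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    baseline = instrument.baseline(axis)

    drifted = instrument.drift_ppm_sd > 0 or instrument.drift_da_sd > 0
    alphas = np.zeros(n_px)
    betas = np.zeros(n_px)
    heights = np.zeros((n_px, len(all_specs)))
    intensities: list[np.ndarray] = []
    mzs: list[np.ndarray] = []

    for i, (x, y) in enumerate(coords):
        rng = np.random.default_rng([seed, i])
        a = rng.normal(0.0, instrument.drift_ppm_sd * 1e-6) if instrument.drift_ppm_sd > 0 else 0.0
        b = rng.normal(0.0, instrument.drift_da_sd) if instrument.drift_da_sd > 0 else 0.0
        alphas[i], betas[i] = a, b
        spec = baseline.copy()
        for j, (name, mz, mean, cv, mask) in enumerate(all_specs):
            if mask is not None and not mask[y, x]:
                continue
            h = _lognormal(rng, mean, cv)
            heights[i, j] = h
            sig = sigmas[j]
            lo = np.searchsorted(axis, mz - 5.0 * sig)
            hi = np.searchsorted(axis, mz + 5.0 * sig)
            seg = axis[lo:hi]
            spec[lo:hi] += h * np.exp(-0.5 * ((seg - mz) / sig) ** 2)
        if instrument.noise_sd > 0:
            spec += rng.normal(0.0, instrument.noise_sd, axis.size)
            np.maximum(spec, 0.0, out=spec)
        intensities.append(spec.astype(np.float32))
        mzs.append(axis * (1.0 + a) + b if drifted else axis)

    names = [name for name, *_ in all_specs]
    is_bg = np.array([j >= bg_start for j in range(len(all_specs))])
    truth = GroundTruth(coords, names, mz_true, is_bg, heights, alphas, betas)
    ds = MSIDataset(
        coords, mzs, intensities,
        shared_axis=not drifted,
        pixel_pitch=scene.pixel_pitch,
        metadata={"seed": seed, "kind": "synthetic"},
    )
    return ds, truth
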