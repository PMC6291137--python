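# Methods

This note documents the models, conventions and numerical choices
behind `aurimsi`, in the order data flows through the pipeline.

## Mass arithmetic and conventions

Monoisotopic masses are embedded (AME2020/NIST values, 8 decimals per
element) so results are hermetic; the electron mass is
0.000548579909 Da. Two conventions coexist on purpose:

- **Calibration references** ([Auₙ]⁺, [KNaCl]⁺, [K₂Cl]⁺) use *neutral
  atomic sums* with no electron subtraction, which is how lock-mass
  tables for sputtered metal clusters are conventionally printed.
- **Annotation masses** for [M+X]⁺ adducts subtract one electron per
  charge: m/z = (M + A − z·mₑ)/z.

Both are exposed (`electron_correction` flag, `mass_convention` field);
the difference (≈0.5 mDa at z=1) matters at the 1–2 ppm level and
the defaults reproduce both printed number sets simultaneously.
Adduct charge is inferred from the label ("+H+NH4" → z=2) and can be
overridden. The formula parser accepts Hill-style tokens with optional
multipliers and parenthesised groups; unknown symbols are rejected at
parse time naming the offending token.

The default ppm sign convention is `(theoretical − observed)/
theoretical × 10⁶`. Published tables are not fully consistent in sign,
so the convention is flippable; tests pin only rows whose printed
arithmetic is self-consistent.

## Synthetic data generator

The generator emulates a reflectron-TOF acquisition over m/z 70–1200
with resolving power R = 12,000 at m/z 1000:

- **Axis**: uniform in √m by default (TOF digitization is uniform in
  time and m ∝ t²); uniform-in-m optional. When `axis_points` is not
  given, the axis is auto-sized to ≥ ~3.2 samples per FWHM at the
  narrowest peak (≈240k points for the full range), enough for 3-point
  apex fits everywhere.
- **Peak shape**: Gaussian with FWHM(m) = m/R (constant R, the single
  published anchor point); an optional √m-scaling mode
  (FWHM = √(1000·m)/R) is provided.
- **Chemistry**: gold clusters Au₁…Au₅ plus the two salt clusters in
  every pixel (heights 120…40 and 70/60 noise-SD units, CV 0.15);
  region-structured metabolite adduct ions defined by formula+adduct or
  explicit m/z. Canonical scenes: `uniform` (liver-like homogeneous),
  `two_region`, and `brain_like` (three masks carrying the ions at
  845.4577, 849.6369 and 213.04 Da used for RGB composites, plus
  cholesterol as both +Na and +K in one mask for cross-adduct tests).
- **Intensity variation**: per-pixel log-normal with configurable CV
  (default 0.25 for analytes) mimicking tissue-morphology variation;
  the log-normal choice is ours.
- **Noise and baseline**: additive Gaussian noise (SD 1 intensity
  unit), plus a smooth exponential chemical background (amplitude 2,
  decay 300 Da) on a detector offset of 6 noise-SD so clipping at zero
  is negligible. A species with mean height 50 therefore yields
  S/N ≈ 50 under the pipeline's S/N definition — this calibration of
  "mean intensity" to S/N is a documented design choice, not a claim
  about any instrument.
- **Mass drift**: per-pixel affine miscalibration
  m_obs = m_true(1+α) + β with α ~ N(0, σ_α) (ppm) and β ~ N(0, σ_β)
  (Da). Physically the samples are fixed in time; a wrong calibration
  mislabels them, so the *reported axis* is transformed while the
  intensity samples are unchanged. Datasets are shared-axis
  (imzML continuous) iff both SDs are zero.
- **Determinism**: one master seed; each pixel gets an independent
  generator keyed `[seed, pixel_index]`, so pixel streams are
  order-independent and renders are bit-reproducible.

What the phantom does *not* model: isotope envelopes, peak overlap
from isobaric species, detector saturation, ionization physics, and
chemical noise structure. Passing the recovery tests therefore shows
the algorithms are correct under the stated noise/drift model, not
that real tissue data will reach the same accuracy (real TOF data is
dominated by peak overlap at these resolving powers).

## Noise, baseline, peak picking

- **Noise**: robust SD from the first difference of the spectrum
  (removes smooth trends), MAD × 1.4826/√2 in tiled windows (default
  512 points) interpolated to every sample, floored at 1e-10.
- **Baseline**: tiled-window median (default 2001 points) interpolated
  — centred on the noise mean; a rolling-minimum variant exists for
  dense spectra.
- **Picking**: the baseline-subtracted profile is lightly smoothed
  (Savitzky–Golay, 5 points, quadratic) so single-sample noise spikes
  cannot pass as peaks; S/N is the smoothed apex over the *raw* local
  noise, preserving threshold semantics (default gate S/N > 5 — the
  S/N definition itself is not standardized, so it is parameterized).
  Centroids come from a 3-point parabola in log-intensity, exact for a
  noiseless Gaussian at any sampling; areas are trapezoidal integrals
  between flanking minima. Smoothing costs <1% height on peaks ≥5
  samples/FWHM (up to ~3% on the narrowest low-mass salt peaks, which
  are used for position only).

## Alignment

Label-free, two phases against the running mean spectrum: a coarse
pass over 8 broad segments, then refinement passes over ±0.4 Da
windows around the ~12 strongest mean-spectrum peaks (label-free: no
identities are used). Each window yields a sub-sample cross-correlation
lag (parabolic apex refinement); windows with normalized correlation
< 0.3 are dropped. Per spectrum the shifts are fitted by
**shift(m) = α·m + β — affine in m**, which is the exact form of an
affine axis miscalibration, and applied by monotone interpolation.
An affine-in-√m shift model was considered and rejected: it cannot
represent the additive β term at low mass (a β of 0.05 Da leaves tens
of ppm at m/z 97 under a √m-affine correction), while the affine-in-m
model recovers all seven lock masses to ~1 ppm. Total intensity per
spectrum is conserved to well under 0.5% by the interpolation.

## Calibration

Fitted on the mean spectrum only (the dataset shares one axis after
alignment, so one model serves every pixel — alignment handles
per-pixel residuals first, calibration fixes the common axis).
References are matched to picked peaks within ±0.3 Da (wide enough for
worst-case expected drift at m/z 985; ties broken by intensity);
least-squares polynomial `m_cal = P(√m_obs)`, degree 2 by default with
a degree-1 fallback when fewer than four references match (a quadratic
through three points would have no redundancy). The fitted map must be
strictly increasing over the axis range (checked on 10⁴ samples;
violation raises with a suggestion to lower the degree). Matched
references and their residuals are logged on every run; extrapolation
beyond the matched span is permitted but logged. Peaks are re-picked
per pixel *after* calibration (order is exposed via the API if the
other order is wanted).

## Peak matrix, metrics, imaging, annotation

- **Binning**: pooled peaks sorted by m/z, greedy split where the gap
  between neighbours exceeds 20 ppm; bin m/z is the intensity-weighted
  mean; a pixel's multiple peaks in one bin are summed.
- **Metrics**: "intensity" means peak height (area by flag). Gold
  exclusion removes peaks within ±0.2 Da of the five Au cluster masses
  from the peak list before *both* metrics (the clusters come from the
  layer, not the tissue). The fragmentation ratio takes the most
  intense peak within 184.07 ± 0.1 Da over the summed 500–1000 Da
  intensity; 0 when no fragment, +∞ (logged) when the denominator is
  empty. Top-K selection (default 250) ranks by gold-excluded TIC
  (flag to rank raw), ties broken by grid order for determinism.
- **Imaging**: windows default ±0.1 Da (the FWHM at m/z 800 with
  R≈12k is ≈0.07 Da); no normalization by default, per-pixel TIC
  normalization optional. Missing pixels are NaN, never zero, and
  render mid-gray (0.5, 0.5, 0.5) in composites. Percentile scaling
  maps [P0, P99] → [0, 1] by default; a constant image maps to zero.
  The default colormap is perceptually uniform; the legacy rainbow
  look is available by name.
- **Annotation**: default adducts +H/+Na/+K/+NH₄ (z=1) at 20 ppm;
  multiply-charged double adducts (e.g. +H+NH₄, z=2) are supported but
  not in the default set. Every in-tolerance (peak, metabolite,
  adduct) pair is emitted, canonically sorted; no scoring beyond |ppm|
  — all IDs are formula-level and putative. Isomer selection is left
  to the user: all candidates are emitted with a tissue-occurrence
  flag instead of guessing a biological filter. Cross-adduct
  consistency scores a formula detected under ≥2 adducts by the
  Pearson correlation of the adducts' ion images.

## Problem sizes and tolerances used in the test suite

Unit fixtures use 2×2–6×6 grids on the full instrument axis (or a
coarsened 40k-point axis for pure plumbing tests). The end-to-end
drift-recovery check uses a 20×20 grid with σ_α = 150 ppm and
σ_β = 0.05 Da and requires all seven references within 5 ppm on the
mean spectrum and in ≥95% of pixels; truth-recovery for peak picking
runs 10 seeds of a 2×2 scene with analytes at S/N≈50 and decoys at
S/N≈2; region recovery binarizes scaled ion images with Otsu's
threshold and requires Jaccard > 0.9 per region. imzML round-trips are
bit-exact in 64-bit mode (32-bit storage is the default on disk, as is
common for imzML).

## Known limitations

- No deisotoping or overlap deconvolution: overlapping peaks are
  reported as picked, so mass errors grow where species collide —
  annotation tolerances must absorb that.
- The alignment needs a handful of strong common peaks per spectrum
  (here guaranteed by the gold clusters); sparse or dead pixels fall
  back to the coarse segment estimates or stay uncorrected.
- Negative-mode adducts, isotope patterns, average masses and formula
  generation from mass are out of scope.
- The metabolite table bundled under `aurimsi/data/` is a small
  curated fixture, not a database; real annotation runs should point
  `--db` at a full HMDB-style export.
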