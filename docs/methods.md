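# Methods

This note documents the models implemented in `rcpscope`, the defaults and
why they were chosen, what the synthetic generator does and does not
emulate, and the numerical conventions that matter for reproducing results.

## Imaging model and acquisition geometry

The target instrument class is a phone camera behind a short-focal external
lens: a 6.86 mm camera objective re-imaging the focal plane of a 2.6 mm
lens gives ~2.6× magnification (`synthscope.effective_magnification`), so a
~1.1 µm sensor pixel samples the object plane at ~0.42 µm/px
(`object_pixel_pitch_um`). A diffraction-limited ~1 µm RCP therefore covers
roughly 2–8 px — the size window the detector gates on. Each channel is
acquired as N repeated exposures (default 5) of the same field; frames are
averaged before analysis for the √N noise reduction, and a warning is
raised below N=5.

## Synthetic scene generator (`synthscope`)

Each scene draws Poisson-distributed numbers of two object classes and
renders per-channel expected-intensity fields on a flat background of
0.02·65535 DN:

- **True RCPs** — isotropic 2-D Gaussians with
  σ = spot_diameter / (2.355 · pixel_size) ≈ 1.01 px (FWHM equals the
  physical spot size, the standard diffraction-limited approximation).
  Each emits in exactly one base-coding channel (A→Cy5, G→Cy3; a
  configurable `mutant_fraction` selects A) plus, optionally, the common
  anchor channel at 0.7× its signal amplitude. Peak amplitudes are
  lognormal around 0.45·65535 DN (σ_log = 0.1). That level was set from
  the generator's own geometry constraint: after the default 1-px Gaussian
  denoise roughly halves the peak of a ~1 px-σ spot, even the dim tail of
  the amplitude distribution must still place ≥2 px of area above the 0.1
  intensity threshold, i.e. the whole population must render into the
  2–8 px equivalent-diameter window (it lands at ≈2.9–4.1 px).
- **Auto-fluorescent artifacts** — larger elliptical Gaussians
  (σ_major 2–4 px, eccentricity 0.6–0.95, random orientation) that emit in
  *all* configured base channels with secondary/primary amplitude ratios
  drawn in (0.35, 1.0) — i.e. above the 0.3 double-stain rejection ratio —
  and carry no anchor stain. They differ from RCPs exactly on the axes the
  pipeline uses to reject them (size, shape, multi-channel staining,
  anchor absence).

Per frame, the recorded image is `Poisson(expected) + N(0, σ_read)`,
clipped to the 16-bit range. `peak_snr` (default 8) is defined as the mean
RCP peak amplitude over the single-frame background noise s.d., and σ_read
is derived from it after subtracting the background shot-noise variance.
At these settings read noise dominates shot noise and is broad relative to
the background level, so truncation at the sensor floor is significant;
`expected_background_mean/variance` therefore return clipped-normal
moments, and the blank-frame variance test validates the render against
them. The default peak SNR of 8 emulates a reaction optimised for bright
RCPs; the classifier benchmark uses SNR 5 as a deliberately harder floor
condition. Non-reference channels can be rigidly shifted by a configurable
(dy, dx) to emulate stage drift between sequential channel acquisitions.
Identical configuration (including seed) reproduces scenes bit-identically.

**What the generator does not emulate:** tissue morphology and structured
background, optical aberrations and field-dependent PSF, raw Bayer/DNG
sensor output (the input contract starts at converted single-channel
rasters), bleed-through between dyes, and bright-field content. Passing
tests on synthetic scenes therefore demonstrate the correctness and the
statistical behaviour of the algorithms under the stated noise model — not
performance on real tissue, where threshold choice within 0.1–0.4 and
artifact abundance dominate.

## Detection (`detect`)

Spot enhancement is a white top-hat with a disk of radius 5 px — just above
the largest spot radius of interest, so 2–8 px objects pass through while
flat background and broad structures are removed. Objects are 8-connected
components above an absolute threshold on the [0, 1] normalized scale
(8-connectivity keeps 2-px diagonal objects whole). The useful threshold
range on these images is 0.1–0.4 depending on sample auto-fluorescence; the
optional adaptive rule (median + 6·MAD of the enhanced image, clipped into
[0.1, 0.4]) is this package's reproducible stand-in for that per-sample
manual choice, not a published rule. Components are kept when the
equivalent circular diameter √(4·area/π) lies in [2, 8] px — a diameter
(not area) convention. Touching spots are not declumped: the densities of
interest are sparse, and no splitting rule is part of the design. Two
consequences are documented rather than hidden: at merging densities the
count under-reports (visible as a slightly shallow dilution slope at the
densest point), and the count-vs-threshold monotonicity property is
guaranteed only in the sparse regime, since raising the threshold can split
an oversize merged component into gate-passing pieces.

Per-object statistics (mean/max/min/integrated) are measured on every
registered channel over the object's pixel set; the local background is the
mean of a 2-px-wide annulus starting 2 px outside the object, falling back
to the global image median (flagged) when the annulus is clipped away at a
border.

## Registration (`preprocess.register_channels`)

Translation-only, estimated by cross-correlation (plain, not
phase-normalized — more robust on sparse spot fields) with 1/20-px subpixel
refinement, applied by bilinear interpolation. The estimate needs structure
common to both channels; in two-colour assays single-stained spots are
disjoint between channels, and the common features are in practice the
double-stained artifacts and any shared tissue structure (or the anchor
channel). Shifts beyond `max_shift_px` (default 10) are treated as
registration failures: flagged, and the channel passed through unshifted
rather than corrupted by a wild estimate.

## Classification (`classify`)

The 14-feature panel: mean, max, min, integrated intensity, intensity s.d.
and median; area, equivalent diameter, perimeter, eccentricity, solidity,
compactness (perimeter²/4π·area); local background contrast (object mean −
annulus mean) and peak SNR (object max / annulus s.d.). Three intensity
features are the classical core of such panels; the remaining eleven were
chosen to separate artifacts on the axes they actually differ on (size,
elongation, context). The classifier is a 100-tree random forest with
⌈√14⌉ = 4 features per split, bootstrap size N, unlimited depth — canonical
forest settings. Training rows are sorted by (label, features) before
fitting so the bootstrap, and hence the model, is invariant to the order
examples were collected in. A tied vote classifies as `not_rcp`: spurious
counts are the costly error in this application. Models persist with a
feature-order hash and refuse vectors assembled in a different order.
"Accuracy" throughout means per-object classification accuracy under
stratified k-fold cross-validation (the alternative reading — detection
sensitivity against a benchtop gold standard — is not what this module
measures).

## Base calling (`basecall`)

Single-cycle calls only; cycles are independent (no multi-cycle consensus
or colour-change filtering). Coding: A=Cy5, T=FITC, G=Cy3, C=Texas red —
or, in chemistries where one base is coded by darkness, `blank_base` can
declare it (off by default in two-channel mode, where a dark object is more
safely a `no_call`). Channel comparisons use background-subtracted object
means (annulus background, floored at 0), making calls invariant to overall
intensity scale. Rules, in order: all base channels below `min_signal` →
blank base or no-call; second/first channel ratio strictly above 0.3 →
rejected as double-stained auto-fluorescence (exactly 0.3 is kept);
otherwise the dominant channel's base. `min_signal` and the anchor-gate
level are not published constants; the pipeline sets both to 3 robust
(MAD-based) standard deviations of the corresponding channel's background —
a level blank pixels cross only exceptionally. The default device profile
is two-laser Cy3/Cy5; the anchor gate engages automatically when an anchor
channel is present and skips, with a warning, when not.

## Genotype scoring and dilution fits (`genotype`)

Per-sample scoring pools raw counts over ROIs (≥6 recommended; fewer sets a
warning flag) and computes ratio = 100·MT/WT on the pooled counts — pooling
then scoring is by construction identical to scoring summed counts, and the
pooled ratio (not the mean of per-ROI ratios) is the headline number.
Ratios are reported to one decimal, rounded half-up; the Mutant/Wild-type
decision uses the unrounded value against the threshold (default 8%), with
Mutant strictly above. An exact 8.0% therefore scores Wild type. WT = 0
raises an error naming the sample rather than reporting an infinite ratio.

Dilution series are fit by ordinary least squares on
(log10 concentration, log10 mean count) after averaging replicates per
concentration and dropping zero-mean points. The reported fit covers the
widest contiguous concentration span whose restricted regression reaches
R² ≥ 0.98 (ties broken toward more points); the span width in decades is
the dynamic range. This makes a saturated or merge-depressed end point
shrink the reported linear span instead of silently degrading the fit.

## Benchmark problem sizes (`experiments`)

The canned experiments use 1024×1024 px tiles (~0.18 mm² at 0.42 µm/px —
a quarter-FOV working tile chosen as a desk-scale unit): the dilution
benchmark renders five concentrations at densities 2→20,000 expected spots
per tile (1 fM–10 pM equivalents), three replicates per point, with four
tiles per replicate at the two sparsest points so low-count means rest on a
workable number of spots; the classifier benchmark labels 500 RCPs and 500
artifacts rendered at peak SNR 5 and cross-validates 5-fold; the mixture
benchmarks use 50:50 scenes with ≥2,000 RCPs, 1:1,000 spike-ins with ~6,000
RCPs, and pure wild-type scenes for the false-call floor, all with ~20
artifacts per tile and double-stain rejection active. Every experiment
derives all randomness from a single integer seed via seed sequences.

## Known limitations

- No declumping: counts saturate sub-linearly above ~10⁴ spots per tile.
- Absolute intensity thresholds assume the fixed 16-bit normalization;
  images scaled differently need rescaling before the 0.1–0.4 gate applies.
- Registration is translation-only (no rotation/scale) and per-acquisition.
- Single-cycle base calls; no quality scores or cross-cycle consensus.
- Synthetic validation does not certify performance on real tissue (see
  the generator's non-goals above).
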