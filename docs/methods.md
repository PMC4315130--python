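# Methods

## Measurement model

A brightfield multispectral acquisition yields one grayscale plane per
wavelength band; per pixel, transmitted counts follow Beer–Lambert:

    I(λ) = I0(λ) · 10^(−Σ_j c_j A_j(λ)),   OD(λ) = −log10(I/I0) = Σ_j c_j A_j(λ)

with dye amounts c_j ≥ 0 and reference absorbances A_j(λ). Assumptions:
the chromogens absorb without scattering or fluorescence, absorbances add
linearly (valid for the dilute precipitate/counterstain regime), and the
illumination I0 is known per plane. OD is clamped at 0 (pixels brighter
than the blank field carry no usable concentration information) and counts
are floored at `floor_counts = 1` before the log to guard dead pixels.

Reference spectra are stored peak-normalized (max A_j = 1), so an unmixed
amount c_j is "the OD dye j alone would produce at its absorbance peak" —
a unit that survives swapping reference files. The bundled
`builtin_reference_spectra()` are *synthetic* Gaussian-mixture models of
the NBT/BCIP formazan (broad band near 585 nm) and methyl green (narrow
band at 632 nm plus a weak blue shoulder); real acquisitions should supply
measured references via the CSV convention.

## Unmixing

Per pixel we solve min‖Ac − od‖², c ≥ 0 exactly: an unconstrained
pseudoinverse solve for all pixels at once, then an active-set fix-up for
the (usually few) pixels whose unconstrained optimum is negative. With two
dyes every active set has a closed form, so the fix-up is vectorized; with
more dyes it falls back to `scipy.optimize.nnls` per flagged pixel.
Pixels whose summed OD over all planes is below 1e−4 are assigned c = 0
without solving — at that level the spectrum is indistinguishable from
empty background and solving would only amplify noise. Collinear
reference pairs are rejected up front (normalized inner product above
1 − 1e−10) with an error naming the pair. The per-pixel RMS of Ac − od is
retained as a QC map.

## Compartment metrics

Masks come from thresholding the unmixed maps inside the ROI — absolute OD
threshold (default 0.10 for both dyes, comfortably above the shot-noise
floor at the default illumination, see below) or Otsu computed over ROI
pixels only. The nuclear compartment of the hybridization signal is the
exact pixelwise AND of the NBT/BCIP and methyl green masks; no morphology
is applied. All quantities are ROI aggregates, not per-cell values: the
workflow being modeled selects one ROI per field and never segments
individual cells. Conservation (cytoplasmic + nuclear = total signal)
holds by construction since the cytoplasmic signal is defined as the
difference. Zero-pixel compartments yield NaN averages with a `degenerate`
flag, propagated as missing values so one empty field cannot abort a
cohort run. Pixels are 0-based (row, column) with no subpixel geometry.

## Grading

The four-tier scale (negative / weak / moderate / strong positive) uses
cutoffs 0.377, 0.5105, 0.68025 by default — the published quartile
boundaries for the observed per-sample mean OD range [0.20825, 0.9455].
The printed tier bounds leave rounding gaps (0.377 → 0.378); they are
implemented as a total partition of [0, ∞) with upper bounds inclusive at
each cutoff, which keeps grading monotone and assigns every OD exactly one
tier. Alternatively the scale can be derived from data as the empirical
quartiles (linear interpolation between order statistics, quantile p at
sorted position p·(n−1)) of the cohort's mean ODs; this needs ≥ 4 values
and a non-degenerate spread. Derivation from the data's min–max *range*
was rejected: range-quartiles of [0.20825, 0.9455] would be
0.3925/0.5769/0.7611, which are not the published boundaries, so the
printed values are kept as literal defaults.

## Statistics

Group contrasts use Welch's unequal-variance t-test with
Welch–Satterthwaite degrees of freedom, two-tailed, at α = 0.05.
Technical triplicates are averaged to one value per sample before testing
— replicates measure the same section and would otherwise triple the
apparent n. All 15 unordered pairs of the six groups are tested per
metric; raw p-values are reported (matching the convention of the study
design this reproduces) alongside a Holm-adjusted column. If both groups
are exactly constant with equal means the test is vacuous and p = 1 by
convention. Grade/OD concordance is reported both as Spearman's r_s
(mid-rank ties) and as the OLS slope of OD on grade code 1–4 with its
two-tailed slope test, since both summaries are quoted in this
literature; constant grades leave the correlation undefined (NaN).

## Synthetic-data generator

The generator defines the study conditions under which the package is
validated:

- **Cohort**: six groups (CA 13, CA-N 12, HGIN 11, HGIN-N 10, LGIN 10,
  LGIN-N 9), three replicates per sample — 195 measurements.
- **Effects**: group-level mean cytoplasmic OD {LGIN-N 0.30, HGIN-N 0.33,
  CA-N 0.36, LGIN 0.45, HGIN 0.60, CA 0.75} — monotone from control to
  carcinoma, all inside the observed OD range. Sample means are drawn from
  a normal with SD 0.08 truncated at 0 (biological variance); replicate
  values apply multiplicative log-normal jitter with σ = 0.05 (technical
  variance). No magnitudes of group differences are published for this
  design, so the defaults were calibrated once to give high (> 80%) power
  for the primary CA vs CA-N contrast at n = 13 vs 12 and never revisited.
- **Scenes**: elliptical methyl-green nuclei inside larger NBT/BCIP
  cytoplasmic discs (40 cells on a 128×128 field by default; geometry is
  configurable and intentionally schematic — only the statistical
  structure matters for validation). A configurable fraction (default
  0.30) of nuclear pixels also carries NBT/BCIP, creating the overlap
  compartment. Per-pixel amounts are the configured means times a
  mean-one log-normal texture (σ = 0.10; set 0 for exact-recovery tests).
  A per-sample visual grade is simulated as the true OD's tier blurred by
  ±1 with probability 0.5, emulating the poor discrimination of grading
  by eye.
- **Optics**: wavelengths 420–720 nm in 10 nm steps (31 planes; the
  instrument class being modeled quotes both 700 and 720 nm as the upper
  visible limit — any declared range is accepted), blank field
  i0 = 4096 counts/plane, Poisson shot noise on transmitted counts
  (standard model for a cooled scientific CCD; no published noise figures
  exist for this workflow). At i0 = 4096 the OD noise floor is ≈ 0.01,
  which motivates the 0.10 default mask threshold and yields per-pixel
  concentration RMSE < 0.02 OD after unmixing.
- **Reproducibility**: one user seed feeds a `numpy` `SeedSequence`; each
  sample-replicate gets an independent derived stream recorded in the
  manifest, so any cube can be re-rendered alone, lazily, in any order.

What the generator does **not** emulate: histological texture, sectioning
and fixation artifacts, uneven illumination, stain spatial gradients,
chromatic aberration, or manual ROI placement. Passing tests therefore
demonstrate correctness of the computational pipeline under the stated
optical model, not robustness to real-slide artifacts.

## Statistical calibration

Calibration of the testing harness runs on the generator's sample-level
effect draws rather than rendered images: the type-I error rate and power
are properties of the cohort's statistical structure, which the draws
define; rendering adds only pixel noise already covered by the recovery
tests. Null cohorts (all group means equal) hold the empirical rejection
rate at α = 0.05 within [0.03, 0.07] over 1500 pairwise tests with
uniform p-values (KS check), and the default CA vs CA-N effect is
detected in > 80% of cohorts.

## Numerical choices and limitations

- Problem sizes: validation uses 128×128 scenes with 31 planes — large
  enough that mask areas and group statistics are stable, small enough
  that the full 195-cube cohort re-renders in seconds.
- Cubes on disk are 16-bit TIFF pages (rounded counts) with exact float
  metadata in the JSON sidecar; in-memory round-trip tests are performed
  on float cubes, disk round-trips are exact to ±0.5 count.
- Whole-slide pyramidal formats, fluorescence mode, near-infrared ranges,
  reference-free (blind) unmixing, spatial regularization, per-cell
  segmentation and visual-grade prediction are out of scope.
- The published per-comparison p-values of the motivating study were
  computed on images that were never deposited; they are not reproducible
  and are not targeted by any test here.
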