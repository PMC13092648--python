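# Methods

## ihMTR computation

The package computes the inhomogeneous magnetization transfer ratio per
voxel as `ihMTR = 100 · (MT_sing − MT_dual) / MT0` with
`MT_sing = ⟨MT+⟩ + ⟨MT−⟩` and `MT_dual = ⟨MT±⟩ + ⟨MT∓⟩`, where ⟨·⟩ averages
the repeated magnitude acquisitions of each preparation. Repetitions are
averaged **before** forming the ratio. This matches how averaged images are
produced at acquisition and keeps the denominator's noise small, minimising
ratio bias; the alternative order (one ratio per repetition, then averaging)
is exposed as `per_repetition_ratio=True` for sensitivity analyses and pairs
repetitions by index against the averaged reference.

Background exclusion: no ROI rule exists at the map level (regions are
supplied as label masks), so the validity mask simply drops voxels whose
averaged M0 is at or below a configurable fraction of the in-slice maximum
(default 0.1). The embedding fluid is proton-free, so its magnitude signal is
pure Rayleigh noise, far below that threshold at any realistic SNR. An
all-invalid map warns rather than errors, since empty masks are legitimate on
degenerate inputs.

Saturation-protocol metadata (pulse width PW, pulse repetition delay Δt,
pulses per burst, bursts, burst TR, offset ΔF, B1RMS, tabulated duty cycle
and flip angle) is carried verbatim and never used in computation: the
package prescribes or measures ihMTR, it does not model the saturation
physics (no Bloch/dipolar-order simulation). Duty cycle in particular is
stored as tabulated because published values do not equal
`pulses·PW/BTR`, so re-deriving it would misrepresent the source protocol
tables.

## ROI statistics, screening, inference

ROI means and SDs use the sample convention (n−1) everywhere — within ROIs,
across protocols and across samples — since no published convention exists
to match; a single-element SD is reported as 0 within ROIs and flagged
undefined in summary rows. Contrasts are absolute differences of ROI means,
hence shift-invariant and symmetric.

Protocol screening mirrors a two-step manual practice: first exclude
acquisitions with low baseline fiber ihMTR (threshold configurable; default
is the median free-running mean across the acquisition grid, making the
qualitative "low baseline" rule explicit and scale-free), then rank the
survivors. Because the original selection was done by inspection, the
ranking rule here is the package's own and deliberately transparent: the
score is a weighted sum of z-scores (computed over survivors) of the fiber
mean and the two contrasts, with equal default weights; every component is
reported alongside the score. Ties break on the fiber-vs-PMJ contrast — the
junction contrast being the novel observable — then on input order, which
also keeps duplicated acquisitions adjacent.

Temperature sensitivity is an ordinary least-squares line of ROI-mean ihMTR
against temperature (°C), reported as %/°C with its standard error; at two
points the fit is exact and the standard error undefined. The paired t-test
uses the textbook statistic `t = mean(d)/(sd(d)/√n)` with `df = n−1` and a
two-sided p from Student's t; zero-variance differences with nonzero mean
return an infinite t and p = 0 with a `degenerate` flag instead of raising.

## Hue-band collagen typing

RGB images are converted to HLS with the standard hexcone formulas
(vectorised; hue in degrees, validated against a scalar reference
implementation to 1e-9). Band limits follow the published integer ranges,
read as half-open intervals so they partition the hue axis: red
[330,360)∪[0,20), orange [20,39), yellow [39,62), green [62,129). A shared
printed endpoint (e.g. hue 20) goes to the higher band; the ambiguity
affects only the measure-zero boundary hues. Type I = red+orange+yellow,
Type III = green, both normalised to total collagen pixels; gated pixels
outside every band are tracked as "other" so the three aggregates always sum
to 100 %. Type aggregates are computed from pixel counts, not from the
already-divided per-band fractions, so they are exact whenever the counts
are.

Which pixels count as collagen under polarized light is not defined by any
published rule, so the package uses an explicit gate: saturation ≥ 0.10,
lightness within [0.08, 0.97], achromatic pixels never collagen.
Birefringent collagen is bright and colorful on a near-black background, so
the gate separates cleanly; the thresholds are configuration, echoed in
every output's provenance block.

Brightfield segmentation uses closed HSL boxes for collagen and adipocytes.
Defaults follow the stain's appearance under normal light — collagen
saturated red (hue 330–360∪0–20, S ≥ 0.3, L 0.10–0.80), adipocytes bright
and unsaturated (S ≤ 0.15, L ≥ 0.85) — because the alternative reading
(collagen isolated as blue, adipocytes dark) contradicts how the stain
presents; that reading remains expressible via
`BrightfieldBandConfig.inverted_thresholds()`. Overlapping configured boxes
are a configuration error, guaranteeing disjoint masks.

When a sample contributes several images per region, per-sample values
average the per-image measures with equal weight per image by default;
pixel-count weighting is available (`weighting="pixel"`), since no standard
field-selection protocol dictates the choice.

## Synthetic data: what it emulates, what it does not

The MR phantom is a 2D slice (default 96×96 voxels at 0.25×0.25 mm) with
three compartments chosen to mimic the real topology: a filled myocardium
disc, a free-running fiber as a 1 mm tube (≈4 voxels) following a circular
arc through the signal-free bath, and a junction zone of ±1.5 mm around the
disc boundary where the tube meets the disc. Each compartment prescribes an
unsaturated amplitude `m0` (default 1; background 0, as for a proton-free
embedding fluid), a single-sided residual `s_single = MT+/M0` (default 0.5 —
only the single/dual *difference* is anchored by published values, so the
common level is a free choice), and a target ihMTR. Noiseless intensities
invert the ratio definition (`MT± = MT∓ = m0·(s_single − ihMTR/200)`), so
the pipeline must return the prescription exactly without noise; a
prescription implying a negative dual residual is rejected as unphysical.
Default region ihMTRs are 11.5/9.0/8.0 % (fiber/PMJ/myocardium), the
across-sample study means.

Noise is Rician — the magnitude of the signal plus complex Gaussian noise —
applied independently per repetition *before* averaging, as in magnitude
MRI; this deliberately exposes averaging-order effects such as the Rician
floor in low-signal regions. No acquisition SNR was published, so the noise
scale is free; the default study simulation uses σ = 0.02 with m0 = 1, i.e.
SNR(M0) = 50, at the protocol-application repetition structure (50 MT
repetitions, 10 reference averages; the protocol-selection structure of 200
repetitions is a parameter away). At these conditions the residual Rician
bias on ROI-mean ihMTR is ~0.01 % absolute and averaging noise dominates;
the recovery tolerance of ±0.3 % absolute reflects both.

The phantom does **not** simulate the saturation preparation (ihMTR is
prescribed, not derived from PW/Δt/ΔF), nor readout effects (no k-space,
partial Fourier, B0/B1 inhomogeneity), nor partial-volume mixing at
compartment edges — label masks match the geometry exactly. Passing recovery
tests therefore validates the estimator chain, not the MR physics of real
acquisitions, where partial volume and coil profiles add bias the package
does not model.

Synthetic polarized-light images draw per-pixel classes i.i.d. from the
prescribed composition and hues uniformly within the class bands, keeping a
2° margin from every band edge so 8-bit PNG quantisation (worst-case hue
error ≈0.3° at the generated saturations) cannot move a pixel across a
boundary — this makes "classifier output equals generated labels" an exact,
not approximate, expectation. Collagen pixels get lightness 0.45–0.55 and
saturation 0.85–1.0; the background is unsaturated with lightness < 0.05,
cleanly below the gate. Real slides differ in every inconvenient way:
spatially correlated fibers rather than i.i.d. pixels, continuous hue
mixtures straddling band edges, glare and out-of-focus regions. The
generators validate the counting and normalisation logic and the gate's
behaviour, not robustness to stain variability. Brightfield images use the
same i.i.d. construction with the default class colors placed safely inside
the segmentation boxes.

Default per-sample compositions in the study simulator reproduce the
published per-sample histology block, so a simulated five-sample study
yields summary rows and a paired-test outcome directly comparable to the
published table.

## Aggregation and reporting

Two-stage aggregation: per-sample mean over protocols (MRI) or images
(histology), then across-sample mean ± SD — interprotocol SDs are across
protocol-level means, the reading most consistent with per-protocol summary
tables existing at all (flagged here because the published convention is
ambiguous). Machine outputs keep full precision (CSV floats written with 17
significant digits and re-read with a correctly-rounding parser, so
round-trips are bit-exact); printed-style values round half-away-from-zero
to one decimal, matching table conventions. Every report embeds provenance:
package version, configuration snapshot and SHA-256 digests of all inputs,
because the original analysis depends on manual ROIs and auditability is the
reproducible substitute.

## Problem sizes and numerical choices

Tests and the acceptance script run the default 96×96 phantom (20 noise
realisations at 50+10 repetitions), 512×512 histology fields (~1e5 collagen
pixels) and 12-point temperature fits; these sizes give sampling errors an
order of magnitude below every tolerance asserted. Noiseless recovery is
asserted at 1e-10 (double-precision arithmetic on constant compartments),
classifier recovery exactly, noisy ROI recovery at ±0.3 % absolute, and the
temperature slope within its own 95 % OLS confidence interval.

## Known limitations

- The published per-sample tables are 1-decimal rounded; aggregates
  recomputed from them can differ from unrounded originals in the last
  printed digit (e.g. an across-sample SD of 16.0 vs a published 15.9), and
  exact published p-values are not recoverable from rounded means.
- ihMTR values are prescribed, not predicted from saturation parameters; the
  package cannot rank protocols from physics, only from measured ROI
  statistics.
- No image registration between MRI and histology; correspondence is the
  caller's responsibility, as it was anatomical/visual in the source study.
- Single-slice 2D analysis; 3D volumes pass through unchanged but the
  phantom generator is 2D.
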