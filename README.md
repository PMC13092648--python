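# ihmtquant

Quantitative analysis of cardiac Purkinje-fiber microstructure from
inhomogeneous magnetization transfer (ihMT) MRI and Picrosirius-red
histology.

The cardiac His–Purkinje network conducts the activation wave to the working
myocardium. In large mammals its free-running segments ("false tendons") are
wrapped in a dense collagen sheath, while the Purkinje–myocardial junction
(PMJ) mixes transitional cells, less collagen and more adipocytes.
Conventional relaxation-based MRI contrast barely separates these tissues;
ihMT — a magnetization-transfer variant sensitive to dipolar-order relaxation
in highly organised macromolecules such as collagen — does. This package
implements the full quantitative chain for such studies: ihMT ratio (ihMTR)
map computation, ROI contrast statistics and saturation-protocol screening,
collagen Type I/III quantification under polarized light, brightfield
collagen/adipocyte area fractions, and the cross-sample aggregation that
produces study-level summary tables. A synthetic-data module (MR phantom
with Rician noise, ground-truthed histology images) makes every stage
testable without access to raw scanner or slide data.

## The quantities computed

An ihMT acquisition collects four MT-weighted magnitude images — positive
and negative single-sided (MT+, MT−) and the two frequency-alternated
dual-sided preparations (MT±, MT∓) — plus an unsaturated reference M0, each
repeated many times. With ⟨·⟩ the repetition average, the per-voxel ihMT
ratio in percent is

    ihMTR = 100 · [ (⟨MT+⟩ + ⟨MT−⟩) − (⟨MT±⟩ + ⟨MT∓⟩) ] / ⟨M0⟩

ROI contrasts are absolute differences of ROI means,
`|ihMTR_fiber − ihMTR_myocardium|` and `|ihMTR_fiber − ihMTR_PMJ|`.

For histology, RGB images are converted to HLS (hue 0–360°). Under polarized
light a pixel is collagen if it passes a lightness/saturation gate; collagen
hues in 330–360°∪0–20° are red, 20–39° orange, 39–62° yellow and 62–129°
green. Red+orange+yellow percentages (of total collagen) give Type I
collagen, green gives Type III. Brightfield images are segmented into
collagen and adipocyte masks by HSL box thresholds; areas are reported
relative to the analysed region.

Aggregation follows the two-stage study design: per-sample means over
protocols (or slide images), then across-sample mean ± sample SD, with a
paired t-test comparing free-running vs PMJ values across samples.

## Worked example

```python
import ihmtquant as iq

# synthesise one acquisition at the study's repetition structure
spec = iq.default_phantom_spec(region_ihmtr=(11.5, 9.0, 8.0),
                               noise_sigma=0.02,  # SNR(M0) = 50
                               n_mt_reps=50, n_m0_reps=10, seed=1)
mtset, mask, truth = iq.generate_phantom(spec)

ihmtr = iq.compute_ihmtr(mtset, m0_threshold_frac=0.1)
for label in (iq.FREE_RUNNING, iq.PMJ, iq.MYOCARDIUM):
    st = iq.region_stats(ihmtr, mask, label)
    print(f"label {label}: mean ihMTR = {st.mean_ihmtr:.2f} %  "
          f"(SD {st.sd_ihmtr:.2f}, n = {st.n_voxels})")

pair = iq.contrasts(iq.region_stats(ihmtr, mask, 1),
                    iq.region_stats(ihmtr, mask, 2),
                    iq.region_stats(ihmtr, mask, 3))
print(f"contrast fiber vs myocardium: {pair.contrast_fr_myo:.2f} %")
print(f"contrast fiber vs PMJ:        {pair.contrast_fr_pmj:.2f} %")

row = iq.across_sample_summary([84.3, 77.7, 87.7, 49.4, 62.9])
print("across-sample total collagen:", row.printed(), "%")
```

prints

```
label 1: mean ihMTR = 11.49 %  (SD 0.55, n = 392)
label 2: mean ihMTR = 9.05 %  (SD 0.62, n = 102)
label 3: mean ihMTR = 7.98 %  (SD 0.55, n = 1754)
contrast fiber vs myocardium: 3.51 %
contrast fiber vs PMJ:        2.44 %
across-sample total collagen: 72.4 ± 16.0 %
```

The phantom prescribed 11.5 / 9.0 / 8.0 % ihMTR for the fiber, PMJ and
myocardium compartments; at 50 repetitions and SNR 50 the ROI means recover
those values to a few hundredths of a percent (the per-voxel SD ~0.55 %
reflects the remaining averaging noise). The last line re-enters five
per-sample total-collagen percentages and reproduces their across-sample
summary row.

A CLI mirrors the stages: `ihmtquant simulate phantom|histology`,
`ihmtquant ihmtr --manifest run.yaml --out map.nii.gz`,
`ihmtquant roi-stats`, `ihmtquant select-protocols`,
`ihmtquant histo classify`, `ihmtquant aggregate mri|histology`.

## Layout

- `ihmtquant.core` — ihMTR map computation, NIfTI and manifest I/O
- `ihmtquant.roi` — ROI statistics, contrasts, protocol screening,
  temperature fit, paired t-test
- `ihmtquant.histology` — HLS conversion, hue-band collagen typing,
  brightfield segmentation
- `ihmtquant.synthetic` — MR phantom and histology generators, study
  simulation on disk
- `ihmtquant.reporting` — summary tables, end-to-end pipelines, provenance
- `ihmtquant.studydata` — published per-sample summary values used as
  regression inputs and generator defaults
- `ihmtquant.cli` — command-line wrappers

See `docs/methods.md` for the modelling choices, defaults and limitations.
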