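# mriqa

Image-quality assessment for conventional and dynamic (DCE) MRI series.

Large multi-centre imaging studies aggregate MRI data of very uneven quality:
different scanners, coils, protocols, and patient behaviour. `mriqa` gives
radiologists and data curators an evidence-based quality verdict for a DICOM
series by combining three complementary views:

* **Subjective rating** — a schema-driven questionnaire (overall impression
  plus contrast / noise / artifact detail items shown unless the overall score
  is *excellent*). This is the mandatory part of an assessment.
* **Objective metrics** — no-reference (NR) scores per slice for any series,
  and full-reference (FR) similarity of every timepoint of a dynamic
  contrast-enhanced study against its pre-contrast phase.
* **ROI statistics** — medically oriented SNR / CNR / CVP / CJV indices from
  labeled regions (`pos1`, `pos2`, `FG`, `BG`), because none of the generic
  metrics is tissue-specific.

A synthetic DCE breast phantom (ellipsoidal compartments, enhancement curves,
correlated texture, Gaussian noise, scriptable blur and through-plane-shift
degradations) plus a minimal DICOM writer make every experiment reproducible
offline, with no patient data.

## Metrics

No-reference, computed per slice on min-max-normalised intensities:

* **Total Variation** — mean over pixels of
  `sqrt((Δrow I)² + (Δcol I)²)` (forward differences). Higher = more
  edge content / contrast.
* **BRISQUE** — mean-subtracted contrast-normalised (MSCN) coefficients
  `(I − μ)/(σ + C)`, asymmetric generalised Gaussian (AGGD) fits of the field
  and its four directional pairwise products at two scales (36 features),
  scored by an RBF support-vector regressor. Lower = better. The bundled
  regressor is a compact synthetic stand-in trained on phantom degradations
  (see `docs/methods.md`); any model in the same text format can be dropped
  in.

Full-reference, target vs reference on jointly normalised intensities:

* **PSNR** `= 10·log₁₀(1 / (MSE + 10⁻⁸))` on unit range — identical images
  print 80.0 dB.
* **SSIM** — 11×11 Gaussian window (σ = 1.5), `C₁ = (0.01 L)²`,
  `C₂ = (0.03 L)²`.
* **MS-SSIM** — five dyadic scales, weights
  (0.0448, 0.2856, 0.3001, 0.2363, 0.1333), luminance only at the coarsest
  scale; needs ≥ 176×176 images.
* **FSIM** — phase congruency from a 4-scale × 4-orientation log-Gabor bank
  combined with Scharr gradient similarity (`T₁ = 0.85`, `T₂ = 160` on a
  0–255 scale).

ROI indices from per-region mean/sd: `SNR = μ_tissue/σ_BG`,
`CNR = |μ₁ − μ₂|/σ_BG`, `CVP = σ_FG/μ_FG`, `CJV = (σ₁ + σ₂)/|μ₁ − μ₂|`,
relative SNR `= SNR₁/SNR₂ = μ₁/μ₂`.

## Worked example

Synthesise a 7-phase DCE phantom with 7×7 Gaussian blur injected at phases 3
and 5 (simulated in-plane patient motion), write it as DICOM, read it back,
and assess it:

```python
from mriqa import phantom, pipeline, volume_io

spec = phantom.default_breast_spec(degradations={3: ("blur", 7), 5: ("blur", 7)}, seed=0)
phantom.write_dicom_series(phantom.make_dce_study(spec), "study")

study = volume_io.read_series(volume_io.discover_inputs("study", "DCE")[0])
nr_profile, fr_profile = pipeline.assess_dynamic(study)
print(pipeline.fr_summary(fr_profile).round(3).to_string(index=False))
for flag in pipeline.flag_profiles(nr_profile, fr_profile):
    if flag.axis == "timepoint":
        print(f"flag: {flag.metric} timepoint {flag.coordinate} "
              f"(severity {flag.severity:.1f})")
```

which prints:

```
 timepoint  psnr_mean  psnr_std  ssim_mean  ssim_std  ms_ssim_mean  ms_ssim_std  fsim_mean  fsim_std
         0     80.000     0.000      1.000     0.000         1.000        0.000      1.000     0.000
         1     32.079     2.928      0.834     0.047         0.965        0.019      0.968     0.005
         2     29.763     3.990      0.845     0.054         0.945        0.050      0.965     0.007
         3     26.465     2.765      0.783     0.035         0.931        0.051      0.851     0.013
         4     31.155     3.854      0.838     0.059         0.943        0.048      0.964     0.007
         5     26.637     2.551      0.779     0.031         0.928        0.050      0.848     0.013
         6     31.152     3.363      0.834     0.058         0.942        0.047      0.963     0.007
flag: psnr timepoint 3 (severity 2.3)
flag: psnr timepoint 5 (severity 2.2)
flag: ssim timepoint 3 (severity 3.1)
flag: ssim timepoint 5 (severity 3.3)
flag: fsim timepoint 3 (severity 22.5)
flag: fsim timepoint 5 (severity 23.2)
```

Timepoint 0 is the reference (pre-contrast) phase, so its rows sit at the
identity ceiling (80 dB / 1.0). Every FR metric dips at the two degraded
phases, and the minima flags point exactly there — the reader's attention
goes straight to the suspicious timepoints.

The same pipeline is available from the shell:

```sh
mriqa phantom --out study --seed 0
mriqa questionnaire --out response.txt   # fill in at least the overall score
mriqa assess --mode DCE --input study --response response.txt
```

`assess` writes everything into `study/IQA/`: the questionnaire response as
text, header metadata as CSV + XLSX, NR/FR profile tables and flags as CSV,
and per-metric line plots. `mriqa roi --input <dir> --mask <mask>` prints the
ROI report for a label mask (integer grid: 1 pos1, 2 pos2, 3 FG, 4 BG).

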