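# mwbreast

Radar-based (confocal) microwave breast imaging at desk scale: synthetic
multistatic scan simulation, Delay-and-Sum (DAS) and Delay-Multiply-and-Sum
(DMAS) beamforming, image-quality metrics, patient-specific permittivity
estimation, and a reproducible comparative phantom study.

Radar-based breast imaging reconstructs a qualitative energy map of
backscattered microwave energy inside the breast: tumour tissue has higher
relative permittivity than adipose tissue, so reflections cohere at tumour
boundaries when the recorded signals are synthetically focused there.  The
package is aimed at researchers comparing imaging algorithms who need
realistic *and fully controlled* test cases — including healthy (no-tumour)
scenes and per-case estimation of the unknown breast permittivity — rather
than a single idealised tumour scenario.

## The methods in brief

A multistatic scan records one complex sample `E_{a,a'}(f)` per transmit
antenna `a`, receive antenna `a'` and frequency `f` (24 antennas on a
hemispherical radome, 2–4 GHz).  For a voxel `r` and an assumed effective
permittivity ε′, the two-way straight-line delay is

    τ_{a,a'}(r) = √ε′ (|a − r| + |a' − r|) / c₀ .

**DAS** phase-aligns and sums all channels and frequencies:

    I_DAS(r, ε′) = | Σ_{a,a'} Σ_f E_{a,a'}(f) · exp(+j 2π f τ_{a,a'}(r)) |²

**DMAS** multiplies the focused signals pairwise before summation, rewarding
mutual coherence; per frequency,

    I_DMAS(r, ε′) = | Σ_f [ (Σ_i s_i(f))² − Σ_i s_i(f)² ] | ,
    s_i(f) = E_i(f) · exp(+j 2π f τ_i(r))

(the self-pair rule and the frequency/multiplication order are configurable;
including self-pairs after a joint frequency sum makes DMAS identical to DAS,
which serves as a regression oracle).

Because the true breast permittivity is unknown, images are reconstructed at
25 candidate ε′ on [8, 14] and scored with an absolute-gradient focal-quality
cost; the cost-maximising image is selected.  Preprocessing mirrors the
experimental practice: per-antenna calibration factors from a homogeneous
reference scan, then rotational subtraction (subtracting the scan from a copy
of itself rotated by one array-symmetry step) to cancel the rotationally
symmetric skin reflection.

Image quality is quantified by SCR (peak vs. strongest background clutter,
dB), SMR (mean tumour-area vs. mean image intensity, dB), FWHM of the
dominant response, and localization error; images with SCR > 1.5 dB are
annotated as detections and classified TP/FP/FN/TN against ground truth.

## Worked example

```python
import mwbreast as mw
from mwbreast.scans import apply_calibration, compute_calibration, rotational_subtract

array = mw.ARRAY_PRESETS["rings24"]()          # 24 antennas, 3 rings of 8
freqs = mw.FrequencyGrid.default()             # 51 points on 2-4 GHz
phantom = mw.build_phantom(10, tumor_diameter_mm=16.0, seed=2)
config = mw.SimulationConfig(noise_sigma=0.5, attenuation_model="conductive",
                             antenna_gains=mw.draw_gains(24, __import__("numpy").random.default_rng(0)),
                             seed=3)
scan = mw.simulate_scan(phantom, array, freqs, config)
reference = mw.simulate_reference_scan(array, freqs, config)

scan = apply_calibration(scan, compute_calibration(reference))
scan = rotational_subtract(scan, array.azimuthal_step)

grid = mw.ImagingGrid.build(spacing=0.0025)    # 2.5 mm voxels, ~47k in-mask
result = mw.sweep(scan, "das", grid,
                  config=mw.BeamformerConfig(engine="interp", dtype="complex64"),
                  truth=phantom)
eps, image, report = mw.select_image(result)
print(f"selected eps' = {eps:.2f}")
print(f"SCR {report.scr_db:.2f} dB, FWHM {report.fwhm*1e3:.1f} mm, "
      f"localization error {report.localization_error*1e3:.1f} mm")
print(mw.annotate(report, phantom))
```

Output (seed-exact):

```
selected eps' = 8.00
SCR 2.13 dB, FWHM 12.1 mm, localization error 32.8 mm
Detection(label='positive', truth_class='FP', scr_db=2.128238605386646, threshold_db=1.5)
```

The search correctly lands on the adipose background permittivity (8.0),
and the image clears the 1.5 dB detection threshold — but the dominant
response sits 33 mm from the 16 mm tumour, on a glandular inclusion: a
false positive, exactly the clutter-driven failure mode the comparative
study is designed to expose.  The same pipeline on a 0 % VGF phantom yields
SCR above 10 dB at the tumour site and a true positive.

The full 24-case study (4 VGF classes × {5 tumour sizes + healthy}, 50
reconstructions per case, both beamformers, all three selection strategies):

```bash
mwbreast study-run --out runs/demo --seed 1
```

which prints per-strategy sensitivity/specificity and writes `report.csv`,
`matched.csv`, `selected.csv` and `report.json` into the run directory.

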