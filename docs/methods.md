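# Methods

This note documents the models, parameter choices and numerical conventions
behind `mwbreast`, and what the synthetic phantom set does and does not
emulate.

## Forward model

The simulator produces frequency-domain multistatic scattering data under a
single-scattering (Born-like) approximation.  Each phantom is a collection
of homogeneous dielectric spheres in an adipose background inside a
hemisphere (chest wall at `z = 0`, nipple at `z = R`, default breast radius
`R = 0.07 m`).  For channel `(a, a')` and frequency `f`, the sample is

    E_{a,a'}(f) = g_a g_{a'} Σ_k R_k exp(-j 2π f √ε_bg (d_ak + d_a'k)/c0)
                              exp(-α (d_ak + d_a'k)) / (d_ak d_a'k) + n

with straight-line propagation at the homogeneous background permittivity
ε_bg, spherical spreading `1/(d1 d2)`, and per-sample circular complex
Gaussian noise `n`.  The reflectivity of sphere `k` follows the quasi-static
(Rayleigh) contrast of a small dielectric sphere,

    R_k = κ V_k (ε_k − ε_bg) / (ε_k + 2 ε_bg),

with `V_k` the sphere volume and `κ = 1e6 m⁻³` an arbitrary overall scale
(every reported metric is a ratio, so κ only fixes the units the noise level
is quoted in).  Conductive attenuation uses the low-loss plane-wave
approximation `α = σ_bg η / 2` with `η = η₀/√ε_bg` the background wave
impedance; it is frequency-independent in this band and enabled by default
in the study (`attenuation_model="conductive"`, σ_bg = 0.1 S/m, adipose).

Assumptions worth keeping in mind: no multiple scattering, no skin
refraction (a single effective propagation speed, matching the confocal
delay model), no antenna patterns, and a flat incident spectrum.  The
forward model shares the beamformers' straight-line delay geometry, so
localization tests are not confounded by model mismatch; attenuation,
spreading, gain mismatch and noise — all of which the beamformers do *not*
compensate — keep the inversion from being a trivial inverse crime.

## The synthetic phantom set

The study set emulates a modular experimental phantom family: four breast
phantoms with volume glandular fractions (VGF) of 0, 10, 15 and 20 %, each
combinable with five spherical tumour plugs of diameter 5, 8.5, 12, 16 and
20 mm at one fixed location, plus a healthy configuration — 24 cases (20
with tumour, 4 without).

* **Tissue dielectrics** (at ~3 GHz): adipose ε=8/σ=0.1, skin 30/2,
  glandular 45/2.5, tumour 70/6.
* **Glandular inclusions**: VGF class maps to {0: 0, 10: 4, 15: 7, 20: 10}
  spheres of radius 8–12 mm placed along seeded cone directions radiating
  from below the nipple towards the chest wall — a sphere-cluster stand-in
  for conical glandular lobes.  Their per-inclusion reflectivity
  (volume × contrast) is comparable to or larger than the tumours', so the
  dense phantoms are genuinely hard: the clutter limits detection the way
  breast density does in practice.
* **Skin residual**: artefact removal never cancels the skin reflection
  perfectly; the leftovers are modelled directly as a weak ring of sixteen
  1.5 mm "skin residual" spheres just under the surface with seeded azimuth
  and strength jitter.  The homogeneous *reference* phantom carries the same
  ring without jitter, exactly symmetric under the array's rotation step.
* **Tumour location**: fixed at cylindrical radius 8 mm, azimuth 15°,
  height 30 mm.  Two constraints pin this choice: it must sit off the
  array's azimuthal mirror planes (a generic position), and it must sit
  close enough to the axis that the ghost produced by rotational
  subtraction (next section) merges into the tumour area.  At radius 8 mm
  the ghost chord is ~6 mm.
* **Acquisition nuisances**: per-antenna complex gains (log-normal
  amplitude, σ = 0.75 dB; Gaussian phase, σ = 10°) shared between each
  measurement and its paired reference scan, and additive noise with
  σ = 0.5 per sample — roughly 18 dB below a single-channel response of the
  smallest tumour, and far below the glandular clutter, so clutter rather
  than noise limits detection, as in the emulated experiments.
* **Array**: the published system used 24 antennas with a 36° rotation
  step, a combination that no single rotationally symmetric layout
  reproduces (24 is not divisible by 10).  The default array is therefore
  24 antennas in three rings of eight (polar angles 30°, 55°, 80°, radome
  radius 7 cm) with an exact 45° step, and a 20-antenna preset (two rings
  of ten) provides the 36° step.  The rotation angle is always read from
  the array, never hard-coded.
* **Frequencies**: 51 evenly spaced points on 2–4 GHz.  51 points keep the
  delay spectrum unambiguous over the aperture (maximum two-way delay
  ~3.5 ns against a 25 ns alias period) at desk-scale cost.

## Preprocessing

**Calibration.**  Per-antenna real factors are computed from the reference
scan by iterating the magnitude equalisation
`f_a ← f_a √(mean|all| / mean|channels involving a|)` to its fixed point
(a symmetric Sinkhorn scaling).  At the fixed point every antenna has the
same mean calibrated channel magnitude; on a noise-free symmetric reference
this recovers `1/|g_a|` exactly up to the array's intrinsic per-ring
response and one global scale.  A one-shot application of the same update
does not: each antenna's observed mean is contaminated by the other
antennas' gains, so only the fixed point cancels gains exactly.  Phases are
left untouched — phase equalisation is ill-posed without a known reference
target.  Degenerate references (a zero-magnitude channel) raise an error.

**Rotational subtraction.**  Output channel `(a, a')` is
`input(a, a') − input(π(a), π(a'))` with `π` the antenna permutation induced
by rotating the array about +z by the requested angle (positive =
counterclockwise seen from the nipple); the angle must be a multiple of the
array's azimuthal step or the operation refuses to run.  Rotationally
symmetric scene content (the skin ring) cancels identically; any compact
scatterer leaves its response *minus a rotated copy* — an equal-amplitude
ghost.  For a sub-resolution rotation the residual approaches a spatial
derivative of the point response: twin lobes of equal height about one
beamwidth apart.  This is intrinsic to the method, not an implementation
artefact, and it drives two design choices documented below (tumour
location, tumour-area radius).

## Beamformers

Both beamformers focus with `τ = √ε′ (|a−r| + |a'−r|)/c0` and the phase
convention `exp(+jωτ)` (the simulator writes `exp(−jωτ)`; this pairing is
fixed in one place).  DAS takes the squared magnitude of the coherent sum.
DMAS multiplies focused channels pairwise before summation; two discrete
orderings of the frequency integral are implemented:

* `focus_first` (default): per-channel frequency-coherent sums `s_i`, then
  the ordered-pair sum `Σ_{i≠j} s_i s_j = (Σ s_i)² − Σ s_i²`.  With
  hundreds of channels the `(Σ s_i)²` term dominates, so this variant is
  numerically close to DAS squared — it serves as the algebraically
  transparent form (its closed form, the self-pair identity, and
  DMAS(include_self) ≡ DAS are the regression oracles).
* `per_frequency`: pairwise products within each frequency, then the
  frequency sum, `Σ_ω [(Σ_i s_iω)² − Σ_i s_iω²]` — the discretisation in
  which the energy integral runs outside the channel products.  Its clutter
  statistics genuinely differ from DAS (the per-frequency coherence is
  rewarded before frequencies are combined), and it is the variant under
  which DAS-vs-DMAS comparisons are scientifically interesting.

The self-pair rule (`exclude_self` default / `include_self`) and per-voxel
/ per-channel weight hooks are configuration; no published weighting scheme
is built in.

### Numerical engines

`engine="exact"` evaluates the frequency sums as per-frequency quadratic
forms `u_ω^T M_ω u_ω` (the steering phase factorises per antenna on a
uniform frequency grid) with batched matrix products over voxel chunks;
pair sums reduce to the same quadratic forms on the sum-frequency grid via
an elementwise self-convolution of the channel matrices.  Non-uniform grids
fall back to the explicit focused-channel matrix.  This path is used by all
oracle tests (complex128).

`engine="interp"` exploits that each channel's focused value is a sample of
its periodic delay response `y_i(τ) = Σ_ω E_i(ω) e^{jωτ}`: the response is
tabulated once per scan by zero-padded inverse FFT (default 16384 samples,
~320× oversampled) and linearly interpolated at the focusing delays by a
fused numba kernel.  Relative accuracy is ~1e-4 against the exact path —
far below every decision threshold in the pipeline — at roughly a
tenth of the cost, and the table is permittivity-independent so sweeps
reuse it.  For the per-frequency DMAS order the self-pair correction
`Σ_ω Σ_i s_iω²` is likewise a delay response of the squared spectra at
doubled frequencies and is gathered from a second table; the
`Σ_ω (Σ_i s_iω)²` term still requires the quadratic-form batch.

Default dtype is complex128; the study runs complex64 (phase errors ~1e-5
radians, image errors ~1e-6 relative — immaterial at 2.5 mm voxels).

## Image metrics

Intensities are energies, so ratios use `10·log10`.  The peak is the global
argmax over in-mask voxels (ties to the lowest C-order index; an optional
near-skin exclusion margin for the peak search is off by default and
recorded in every report).  FWHM is measured by linear interpolation of the
half-maximum crossings along the three grid axes through the peak and
averaged; runs that hit the mask boundary mirror the available side and
flag the report.  The tumour area is the sphere around the peak of radius
**twice** the FWHM: with the tighter radius-one-FWHM sphere the rotational
subtraction ghost (twin lobe ~1.1 beamwidths away) always falls just
outside the area, capping SCR near 0 dB for every compact target — a
reading under which the emulated pipeline could never annotate a detection.
The scale is a parameter (`radius_scale`), so the tighter convention
remains available.  SCR compares the peak against the maximum background
intensity (everything outside the tumour area), SMR the mean tumour-area
intensity against the whole-image mean (background-only denominator by
flag).  Detections: SCR > 1.5 dB annotates a positive; a positive is a true
positive iff the peak lies within the physical tumour sphere.

## Permittivity search

Images are reconstructed at 25 evenly spaced ε′ on [8, 14] (0.25 steps) and
scored by an absolute-gradient focal-quality cost; the maximiser is
selected, ties towards the lower ε′.  Two cost variants:

* `max_gradient` (default): the maximum absolute intensity difference
  between adjacent in-mask voxels — the steepest edge.  It scales with peak
  amplitude and is insensitive to the spatial dilation of a defocused
  response, so its argmax tracks the true background permittivity on this
  forward model.
* `total_gradient`: the total absolute first difference over all adjacent
  in-mask pairs (3-D total variation), optionally unit-max normalised.
  Under defocus the response dilates spatially and a 3-D total variation
  grows roughly quadratically with the dilation factor, outpacing the
  amplitude loss; on this forward model the variant is therefore biased
  low in ε′.  It is retained as the literal total-variation reading and
  for comparison.

This choice is a resolution of a genuinely open convention (gradient-based
focal metrics appear in several normalisations in the autofocus
literature); the parameter-recovery acceptance test pins the behaviour the
selected default must have.

## The comparative study

`run_study` generates the 24-case set, calibrates against each paired
reference, applies rotational subtraction at one azimuthal step, runs both
beamformer sweeps (50 images per case), and annotates detections for three
strategies: DAS at its own selected ε′, DMAS at its own selected ε′, and
DMAS at the DAS-selected ε′.  Matched DAS/DMAS pairs are classified
sharper / similar / deteriorated with the conventional cutoffs (SCR ≥ 1 dB
higher and FWHM ≥ 2 mm smaller; SCR within 1 dB and peaks within 1 cm;
otherwise, or a DMAS peak more than 5 cm from the tumour), and the
independent selections are compared with a 0.5 agreement threshold on ε′.
Everything is reproducible from config + seed (byte-identical report CSV).

Problem sizes: 2.5 mm isotropic voxels over the 7 cm hemisphere (~47 000
in-mask voxels), 51 frequencies, 552 ordered bistatic channels, 25
candidate permittivities — a full study is a few minutes on one CPU with
the interpolation engine.  The parameter-recovery experiment runs at the
same 2.5 mm resolution: the max-gradient cost reads the steepest edge of
the response, and halving the voxel size measurably sharpens its argmax
(median recovery error ~0.3 at 2.5 mm versus ~0.5 at 5 mm on the same
cases), so coarser shortcut grids are not used for selection experiments.

## Known limitations

* Born-model spheres cannot represent distributed boundaries: a large
  homogeneous glandular blob is compressed into a single strong point-like
  reflector, which overstates clutter compactness and makes the densest
  synthetic phantoms harder than their physical counterparts; synthetic
  sensitivity figures are therefore not comparable to measured ones and
  are reported only as outputs of this synthetic world.
* The focus-first DMAS default is numerically close to DAS at this channel
  count; beamformer contrast appears under the `per_frequency` order.
* Because tumour and glandular clutter are both compact reflectors in the
  Born model, their peak ranking is stable under small (±10 %)
  reconstruction-permittivity errors: low-density cases stay localized
  across the error range and dense cases fail already at the true value.
  Scenarios where one beamformer rescues a slightly defocused detection
  while the other loses it require distributed boundary-like clutter that
  decoheres under defocus faster than the compact tumour, and do not occur
  in this synthetic set.
* Rotational subtraction's ghost is faithfully produced; any workflow that
  treats the background max as clutter must decide how the tumour area
  handles the ghost (see the radius discussion above).
* No skin layer refraction, antenna patterns, cable/switch dispersion, or
  mechanical positioning error; calibration recovers gain magnitudes only.
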