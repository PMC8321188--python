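"""Single-scattering frequency-domain forward model and study-set generation.

The simulator emulates a 24-port switched VNA acquisition between 2 and 4 GHz:
for each ordered bistatic channel (a, a') and frequency f the sample is

    g_a * g_a' * sum_k  R_k * exp(-j 2 pi f sqrt(eps_bg) (d_ak + d_a'k) / c0)
                      * exp(-alpha (d_ak + d_a'k)) / (d_ak * d_a'k)
    + noise

with straight-line propagation at the homogeneous background permittivity,
reflectivity ``R_k`` proportional to scatterer volume times the Rayleigh
dielectric contrast ``(eps_k - eps_bg) / (eps_k + 2 eps_bg)``, optional
low-loss conductive attenuation, 1/(d1 d2) spherical spreading, per-antenna
complex gain mismatch and i.i.d. circular complex Gaussian receiver noise.

The model is Born-like: no multiple scattering and no skin refraction,
matching the straight-line delay assumption of the confocal beamformers.  The
incident spectrum is flat (unit amplitude); any common spectral factor
cancels in the relative image metrics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .constants import C0, ETA0
from .errors import GeometryError
from .phantoms import (
    ARRAY_PRESETS,
    TUMOR_DIAMETERS_MM,
    VGF_CLASSES,
    AntennaArray,
    BreastPhantom,
    build_phantom,
    build_reference_phantom,
)
from .scans import MultistaticScan, bistatic_channels

__all__ = [
    "FrequencyGrid",
    "SimulationConfig",
    "StudyCase",
    "simulate_scan",
    "simulate_reference_scan",
    "generate_study_set",
    "draw_gains",
    "scatterer_reflectivity",
]


@dataclass(frozen=True)
class FrequencyGrid:
    """Strictly increasing frequency axis in Hz (default band 2-4 GHz)."""

    frequencies: np.ndarray

    def __post_init__(self):
        f = np.asarray(self.frequencies, dtype=float)
        object.__setattr__(self, "frequencies", f)
        if f.size < 2:
            raise GeometryError("frequency grid needs at least 2 points")
        if np.any(np.diff(f) <= 0):
            raise GeometryError("frequencies must be strictly increasing")

    @classmethod
    def default(cls, n_points: int = 51, fmin: float = 2e9, fmax: float = 4e9):
        """Evenly spaced grid; 51 points keep the delay spectrum unaliased
        over a 14 cm aperture at desk-scale runtime."""
        return cls(np.linspace(fmin, fmax, n_points))

    @property
    def n_points(self) -> int:
        return self.frequencies.size


@dataclass(frozen=True)
class SimulationConfig:
    """Acquisition nuisance parameters.

    ``noise_sigma`` is the standard deviation of the complex noise per
    channel-frequency sample (E|n|^2 = sigma^2) in the same arbitrary units
    as the scattered samples; ``reflectivity_scale`` (m^-3) sets those units
    so that a 10 mm tumour yields O(0.1) reflectivity.
    """

    antenna_gains: Optional[np.ndarray] = None  # None = unit gains
    noise_sigma: float = 0.0
    seed: int = 0
    include_monostatic: bool = False
    attenuation_model: str = "none"  # "none" | "conductive"
    spreading: bool = True
    reflectivity_scale: float = 1e6

    def __post_init__(self):
        if self.noise_sigma < 0:
            raise GeometryError("noise_sigma must be nonnegative")
        if self.attenuation_model not in ("none", "conductive"):
            raise GeometryError(f"unknown attenuation model {self.attenuation_model!r}")
        if self.antenna_gains is not None:
            g = np.asarray(self.antenna_gains, dtype=complex)
            if not np.all(np.isfinite(g)) or np.any(g == 0):
                raise GeometryError("antenna gains must be finite and nonzero")
            object.__setattr__(self, "antenna_gains", g)


def scatterer_reflectivity(eps_s: float, eps_bg: float, radius: float, scale: float = 1e6) -> float:
    """Volume-times-contrast reflectivity of one spherical scatterer."""
    volume = 4.0 / 3.0 * math.pi * radius**3
    return scale * volume * (eps_s - eps_bg) / (eps_s + 2.0 * eps_bg)


def draw_gains(
    n_antennas: int,
    rng: np.random.Generator,
    amplitude_sigma_db: float = 0.75,
    phase_sigma_deg: float = 10.0,
) -> np.ndarray:
    """Per-antenna complex gain mismatch: log-normal amplitude (sigma in dB)
    and Gaussian phase (sigma in degrees)."""
    amp = 10.0 ** (rng.normal(0.0, amplitude_sigma_db, n_antennas) / 20.0)
    phase = np.deg2rad(rng.normal(0.0, phase_sigma_deg, n_antennas))
    return amp * np.exp(1j * phase)


def simulate_scan(
    phantom: BreastPhantom,
    array: AntennaArray,
    freqs: FrequencyGrid,
    config: SimulationConfig = SimulationConfig(),
) -> MultistaticScan:
    """Simulate one multistatic scan of a phantom.

    Reproducible given ``config.seed``; the scan of an empty phantom with
    ``noise_sigma = 0`` is identically zero.
    """
    channels = bistatic_channels(array.n_antennas, config.include_monostatic)
    f = freqs.frequencies
    nch, nf = channels.shape[0], f.size
    data = np.zeros((nch, nf), dtype=np.complex128)

    scatterers = phantom.all_scatterers
    if scatterers:
        centers = np.stack([s.center for s in scatterers])  # (k, 3)
        refl = np.array(
            [
                scatterer_reflectivity(
                    s.relative_permittivity,
                    phantom.background_permittivity,
                    s.radius,
                    config.reflectivity_scale,
                )
                for s in scatterers
            ]
        )
        # (n_antennas, k) antenna-to-scatterer distances
        d = np.linalg.norm(array.positions[:, None, :] - centers[None, :, :], axis=2)
        if np.any(d <= 0):
            raise GeometryError("scatterer coincides with an antenna position")
        d1 = d[channels[:, 0]]  # (nch, k)
        d2 = d[channels[:, 1]]
        path = d1 + d2
        amp = refl[None, :].astype(float).copy()
        amp = np.broadcast_to(amp, path.shape).copy()
        if config.spreading:
            amp = amp / (d1 * d2)
        if config.attenuation_model == "conductive":
            # Low-loss plane-wave attenuation alpha = sigma * eta / 2 (Np/m)
            # with eta the background wave impedance.
            eta = ETA0 / math.sqrt(phantom.background_permittivity)
            alpha = phantom.background_conductivity * eta / 2.0
            amp = amp * np.exp(-alpha * path)
        slowness = 2.0 * math.pi * math.sqrt(phantom.background_permittivity) / C0
        # sum over scatterers of amp * exp(-j w tau); (nch, k) x (nf,)
        phase = np.exp(-1j * slowness * path[:, :, None] * f[None, None, :])
        data = np.einsum("ck,ckf->cf", amp, phase)

    if config.antenna_gains is not None:
        g = config.antenna_gains
        if g.shape[0] != array.n_antennas:
            raise GeometryError("one gain per antenna required")
        data = data * (g[channels[:, 0]] * g[channels[:, 1]])[:, None]

    if config.noise_sigma > 0:
        rng = np.random.default_rng(config.seed)
        scale = config.noise_sigma / math.sqrt(2.0)
        data = data + scale * (
            rng.standard_normal(data.shape) + 1j * rng.standard_normal(data.shape)
        )

    return MultistaticScan(
        data=data,
        channels=channels,
        frequencies=f.copy(),
        array=array,
        meta={
            "kind": "simulated",
            "background_permittivity": phantom.background_permittivity,
            "history": [],
        },
    )


def simulate_reference_scan(
    array: AntennaArray,
    freqs: FrequencyGrid,
    config: SimulationConfig = SimulationConfig(),
    background_permittivity: float = 8.0,
    skin_residual_scale: float = 1.0,
) -> MultistaticScan:
    """Scan of the homogeneous calibration phantom with the SAME antenna
    gains as the paired measurement (pass the same config)."""
    phantom = build_reference_phantom(
        array.rotational_symmetry_order,
        background_permittivity=background_permittivity,
        skin_residual_scale=skin_residual_scale,
    )
    scan = simulate_scan(phantom, array, freqs, config)
    scan.meta["kind"] = "reference"
    return scan


@dataclass(frozen=True)
class StudyCase:
    """One study case: ground truth plus measurement and reference scans."""

    case_id: str
    phantom: BreastPhantom
    scan: MultistaticScan
    reference: MultistaticScan


def generate_study_set(
    seed: int,
    array: Optional[AntennaArray] = None,
    freqs: Optional[FrequencyGrid] = None,
    noise_sigma: float = 0.02,
    gains_mode: str = "random",
    attenuation_model: str = "conductive",
    background_permittivity: float = 8.0,
    skin_residual_scale: float = 1.0,
) -> list[StudyCase]:
    """Generate the full 24-case synthetic phantom set.

    The cross product of the four VGF classes with the five tumour diameters
    plus one healthy case per class: 20 tumour cases and 4 healthy cases.
    Each case carries a paired reference scan acquired with the same antenna
    gains.  Deterministic given ``seed``.
    """
    if array is None:
        array = ARRAY_PRESETS["rings24"]()
    if freqs is None:
        freqs = FrequencyGrid.default()
    if gains_mode not in ("unit", "random"):
        raise GeometryError(f"unknown gains mode {gains_mode!r}")

    cases = []
    root = np.random.SeedSequence(seed)
    for vgf in VGF_CLASSES:
        for diam in (None,) + TUMOR_DIAMETERS_MM:
            label = "healthy" if diam is None else f"d{diam:04.1f}mm"
            case_id = f"vgf{vgf:02d}_{label}"
            ss = np.random.SeedSequence((seed, vgf, 0 if diam is None else int(diam * 10)))
            child = np.random.default_rng(ss)
            phantom_seed = int(child.integers(0, 2**31 - 1))
            scan_seed = int(child.integers(0, 2**31 - 1))
            ref_seed = int(child.integers(0, 2**31 - 1))
            gains = None
            if gains_mode == "random":
                gains = draw_gains(array.n_antennas, child)
            phantom = build_phantom(
                vgf,
                tumor_diameter_mm=diam,
                seed=phantom_seed,
                background_permittivity=background_permittivity,
                skin_residual_scale=skin_residual_scale,
            )
            cfg = SimulationConfig(
                antenna_gains=gains,
                noise_sigma=noise_sigma,
                seed=scan_seed,
                attenuation_model=attenuation_model,
            )
            scan = simulate_scan(phantom, array, freqs, cfg)
            scan.meta["case_id"] = case_id
            reference = simulate_reference_scan(
                array,
                freqs,
                replace(cfg, seed=ref_seed),
                background_permittivity=background_permittivity,
                skin_residual_scale=skin_residual_scale,
            )
            reference.meta["case_id"] = case_id
            cases.append(StudyCase(case_id, phantom, scan, reference))
    return cases
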