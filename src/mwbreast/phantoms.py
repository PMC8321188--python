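"""Antenna arrays and synthetic breast phantoms.

The experimental setting emulated here is a hemispherical radome of radius
``R`` housing a ring array of antennas, with the breast resting against the
radome: the chest wall lies in the ``z = 0`` plane and the nipple points
towards ``z = R``.  Phantoms are collections of spherical scatterers — a
tumour, fibroglandular inclusions whose number grows with the volume
glandular fraction (VGF), and a weak ring of "skin residual" scatterers that
stands in for the part of the skin reflection that artefact removal does not
cancel.

Dielectric constants follow the standard polyurethane/graphite phantom
recipes: adipose background eps_r ~ 8, skin ~ 30, glandular ~ 45, tumour ~ 70.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .errors import GeometryError

__all__ = [
    "AntennaArray",
    "Scatterer",
    "BreastPhantom",
    "build_array",
    "build_phantom",
    "build_reference_phantom",
    "ARRAY_PRESETS",
    "TISSUES",
    "TUMOR_DIAMETERS_MM",
    "TUMOR_LOCATION",
    "VGF_CLASSES",
    "GLANDULAR_COUNTS",
]

#: (relative permittivity, conductivity S/m) at ~3 GHz for each phantom tissue.
TISSUES = {
    "adipose": (8.0, 0.1),
    "skin": (30.0, 2.0),
    "glandular": (45.0, 2.5),
    "tumor": (70.0, 6.0),
}

#: Tumour plug diameters (mm) of the five spherical tumour phantoms.
TUMOR_DIAMETERS_MM = (5.0, 8.5, 12.0, 16.0, 20.0)

#: Volume-glandular-fraction classes (%) of the four breast phantoms.
VGF_CLASSES = (0, 10, 15, 20)

#: Number of glandular inclusions used to emulate each VGF class.
GLANDULAR_COUNTS = {0: 0, 10: 4, 15: 7, 20: 10}

#: Fixed tumour-plug location shared by every tumour case (metres).  Chosen
#: mid-depth and off the azimuthal mirror planes of the default array, close
#: enough to the axis that the rotational-subtraction ghost of the tumour
#: (the equal-amplitude copy at one azimuthal step that this artefact-removal
#: method necessarily produces) merges into the tumour area of the
#: reconstructed response rather than standing as separate clutter.
TUMOR_LOCATION = np.array(
    [0.008 * math.cos(math.radians(15.0)), 0.008 * math.sin(math.radians(15.0)), 0.030]
)

_POSITION_TOL = 1e-9


@dataclass(frozen=True)
class AntennaArray:
    """Hemispherical antenna array with exact discrete rotational symmetry.

    Parameters
    ----------
    positions
        ``(n, 3)`` antenna phase centres in metres, all on the radome sphere
        with ``z >= 0``.
    radome_radius
        Radius of the radome sphere in metres.
    rotational_symmetry_order
        Number of equal azimuthal steps that map the antenna set onto itself.
    """

    positions: np.ndarray
    radome_radius: float
    rotational_symmetry_order: int

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "positions", pos)
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise GeometryError("antenna positions must be an (n, 3) array")
        radii = np.linalg.norm(pos, axis=1)
        if np.any(np.abs(radii - self.radome_radius) > _POSITION_TOL):
            raise GeometryError("antenna positions must lie on the radome sphere")
        if np.any(pos[:, 2] < -_POSITION_TOL):
            raise GeometryError("antenna positions must satisfy z >= 0 (hemisphere)")
        if self.rotational_symmetry_order < 1:
            raise GeometryError("rotational symmetry order must be positive")
        # Rotation by one azimuthal step must permute the antennas bijectively.
        self.rotation_permutation(self.azimuthal_step)

    @property
    def n_antennas(self) -> int:
        return self.positions.shape[0]

    @property
    def azimuthal_step(self) -> float:
        """Azimuthal symmetry step in degrees (360 / symmetry order)."""
        return 360.0 / self.rotational_symmetry_order

    def rotation_permutation(self, angle_degrees: float) -> np.ndarray:
        """Antenna permutation induced by rotating the array about +z.

        Positive angles are counterclockwise about +z viewed from the nipple.
        ``perm[i]`` is the index of the antenna whose position coincides with
        antenna ``i`` rotated by ``angle_degrees``.

        Raises
        ------
        IncompatibleRotationError
            If the angle is not an integer multiple of the azimuthal step, or
            the rotated positions do not map onto the antenna set.
        """
        from .errors import IncompatibleRotationError

        step = self.azimuthal_step
        ratio = angle_degrees / step
        if abs(ratio - round(ratio)) > 1e-9:
            raise IncompatibleRotationError(
                f"rotation angle {angle_degrees} deg is not a multiple of the "
                f"array's azimuthal step {step} deg"
            )
        theta = math.radians(angle_degrees)
        c, s = math.cos(theta), math.sin(theta)
        rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
        rotated = self.positions @ rot.T
        diff = np.linalg.norm(rotated[:, None, :] - self.positions[None, :, :], axis=2)
        perm = np.argmin(diff, axis=1)
        if np.any(diff[np.arange(len(perm)), perm] > _POSITION_TOL) or len(
            set(perm.tolist())
        ) != len(perm):
            raise IncompatibleRotationError(
                f"rotation by {angle_degrees} deg does not map the antenna set "
                "onto itself"
            )
        return perm


def build_array(
    n_antennas: int = 24,
    radome_radius: float = 0.07,
    rings: Sequence[tuple[float, int]] = ((30.0, 8), (55.0, 8), (80.0, 8)),
) -> AntennaArray:
    """Build a ring array on the radome hemisphere.

    Parameters
    ----------
    n_antennas
        Total antenna count; must equal the sum of the per-ring counts.
    radome_radius
        Radome sphere radius in metres.
    rings
        Sequence of ``(polar_angle_degrees, count)``: each ring places
        ``count`` equally spaced antennas at the given polar angle measured
        from the +z (nipple) axis.

    The rotational symmetry order is the gcd of the ring counts, so the
    azimuthal step is ``360 / gcd``; the default 24-antenna array (three rings
    of eight) has a 45 degree step, and the 20-antenna preset (two rings of
    ten) reproduces the 36 degree step used with rotational subtraction.
    """
    counts = [int(c) for _, c in rings]
    if sum(counts) != n_antennas:
        raise GeometryError(
            f"ring counts {counts} sum to {sum(counts)}, expected {n_antennas}"
        )
    if any(c < 1 for c in counts):
        raise GeometryError("every ring must contain at least one antenna")
    order = counts[0]
    for c in counts[1:]:
        order = math.gcd(order, c)
    positions = []
    for polar_deg, count in rings:
        theta = math.radians(polar_deg)
        if not (0.0 <= polar_deg <= 90.0 + 1e-12):
            raise GeometryError("ring polar angles must lie in [0, 90] degrees")
        for k in range(int(count)):
            phi = 2.0 * math.pi * k / count
            positions.append(
                [
                    radome_radius * math.sin(theta) * math.cos(phi),
                    radome_radius * math.sin(theta) * math.sin(phi),
                    radome_radius * math.cos(theta),
                ]
            )
    return AntennaArray(
        positions=np.array(positions),
        radome_radius=radome_radius,
        rotational_symmetry_order=order,
    )


def _preset_rings24() -> AntennaArray:
    return build_array(24, 0.07, ((30.0, 8), (55.0, 8), (80.0, 8)))


def _preset_rings20() -> AntennaArray:
    # 10-fold symmetric preset: exercises the 36 degree rotational
    # subtraction reported for the experimental system.
    return build_array(20, 0.07, ((45.0, 10), (75.0, 10)))


ARRAY_PRESETS = {"rings24": _preset_rings24, "rings20": _preset_rings20}


@dataclass(frozen=True)
class Scatterer:
    """Spherical scatterer inside the breast hemisphere."""

    center: np.ndarray
    radius: float
    relative_permittivity: float
    conductivity: float
    kind: str  # "tumor" | "glandular" | "skin_residual"

    def __post_init__(self):
        center = np.asarray(self.center, dtype=float)
        object.__setattr__(self, "center", center)
        if self.radius <= 0:
            raise GeometryError("scatterer radius must be positive")
        if self.relative_permittivity < 1:
            raise GeometryError("relative permittivity must be >= 1")

    @property
    def volume(self) -> float:
        return 4.0 / 3.0 * math.pi * self.radius**3

    def to_dict(self) -> dict:
        return {
            "center": self.center.tolist(),
            "radius": self.radius,
            "relative_permittivity": self.relative_permittivity,
            "conductivity": self.conductivity,
            "kind": self.kind,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Scatterer":
        return cls(
            center=np.asarray(d["center"], dtype=float),
            radius=float(d["radius"]),
            relative_permittivity=float(d["relative_permittivity"]),
            conductivity=float(d["conductivity"]),
            kind=str(d["kind"]),
        )


@dataclass(frozen=True)
class BreastPhantom:
    """Ground-truth scatterer description of one synthetic breast phantom.

    ``scatterers`` holds the glandular and skin-residual inclusions;
    ``tumor`` is present only for tumour cases.  All coordinates live in the
    radome frame (chest wall at ``z = 0``).
    """

    vgf_class: int
    scatterers: tuple[Scatterer, ...]
    tumor: Optional[Scatterer]
    background_permittivity: float = 8.0
    background_conductivity: float = 0.1
    breast_radius: float = 0.07
    tumor_location: np.ndarray = field(default_factory=lambda: TUMOR_LOCATION.copy())

    def __post_init__(self):
        object.__setattr__(self, "scatterers", tuple(self.scatterers))
        object.__setattr__(
            self, "tumor_location", np.asarray(self.tumor_location, dtype=float)
        )
        if self.vgf_class not in VGF_CLASSES:
            raise GeometryError(f"unknown VGF class {self.vgf_class}")
        for s in self.all_scatterers:
            r = np.linalg.norm(s.center)
            if r > self.breast_radius or s.center[2] < 0:
                raise GeometryError(
                    f"{s.kind} scatterer at {s.center} lies outside the breast"
                )

    @property
    def all_scatterers(self) -> tuple[Scatterer, ...]:
        """Scatterers including the tumour, in simulation order."""
        if self.tumor is not None:
            return self.scatterers + (self.tumor,)
        return self.scatterers

    @property
    def has_tumor(self) -> bool:
        return self.tumor is not None

    def to_dict(self) -> dict:
        return {
            "vgf_class": self.vgf_class,
            "scatterers": [s.to_dict() for s in self.scatterers],
            "tumor": self.tumor.to_dict() if self.tumor is not None else None,
            "background_permittivity": self.background_permittivity,
            "background_conductivity": self.background_conductivity,
            "breast_radius": self.breast_radius,
            "tumor_location": self.tumor_location.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BreastPhantom":
        return cls(
            vgf_class=int(d["vgf_class"]),
            scatterers=tuple(Scatterer.from_dict(s) for s in d["scatterers"]),
            tumor=Scatterer.from_dict(d["tumor"]) if d.get("tumor") else None,
            background_permittivity=float(d["background_permittivity"]),
            background_conductivity=float(d.get("background_conductivity", 0.1)),
            breast_radius=float(d["breast_radius"]),
            tumor_location=np.asarray(d["tumor_location"], dtype=float),
        )

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path) -> "BreastPhantom":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _skin_residual_ring(
    rng: Optional[np.random.Generator],
    breast_radius: float,
    count: int,
    base_radius: float,
    symmetric: bool,
) -> list[Scatterer]:
    """Weak near-surface scatterers standing in for imperfect skin removal.

    With ``symmetric=True`` the ring is exactly invariant under the array's
    azimuthal step (counts are chosen as a multiple of the symmetry order), as
    appropriate for a homogeneous reference phantom; otherwise seeded jitter
    in azimuth and strength leaves a residual that rotational subtraction does
    not fully cancel.
    """
    eps, sigma = TISSUES["skin"]
    polar = math.radians(65.0)
    shell = breast_radius - 2.0 * base_radius
    out = []
    for k in range(count):
        phi = 2.0 * math.pi * k / count
        radius = base_radius
        if not symmetric:
            phi += rng.uniform(-0.035, 0.035)
            radius = base_radius * rng.uniform(0.75, 1.25)
        out.append(
            Scatterer(
                center=np.array(
                    [
                        shell * math.sin(polar) * math.cos(phi),
                        shell * math.sin(polar) * math.sin(phi),
                        shell * math.cos(polar),
                    ]
                ),
                radius=radius,
                relative_permittivity=eps,
                conductivity=sigma,
                kind="skin_residual",
            )
        )
    return out


def build_phantom(
    vgf_class: int,
    tumor_diameter_mm: Optional[float] = None,
    seed: int = 0,
    background_permittivity: float = 8.0,
    breast_radius: float = 0.07,
    skin_residual_scale: float = 1.0,
    skin_residual_count: int = 16,
) -> BreastPhantom:
    """Build a seeded breast phantom for one study case.

    Parameters
    ----------
    vgf_class
        Volume glandular fraction class, one of ``{0, 10, 15, 20}`` percent.
        The number of glandular inclusions grows with the class
        (``{0: 0, 10: 4, 15: 7, 20: 10}``).
    tumor_diameter_mm
        Spherical tumour diameter in mm within [5, 20], or ``None`` for a
        healthy case.  The tumour always sits at :data:`TUMOR_LOCATION`.
    seed
        Seeds the glandular placement and the skin-residual jitter; the
        tumour itself is deterministic.
    skin_residual_scale
        Multiplies the base 1.5 mm radius of the skin-residual scatterers;
        0 disables them (idealised artefact removal).
    """
    if vgf_class not in VGF_CLASSES:
        raise GeometryError(f"unknown VGF class {vgf_class}; expected {VGF_CLASSES}")
    if tumor_diameter_mm is not None and not (5.0 <= tumor_diameter_mm <= 20.0):
        raise GeometryError("tumor diameter must lie in [5, 20] mm")
    rng = np.random.default_rng(seed)

    scatterers: list[Scatterer] = []
    eps_g, sigma_g = TISSUES["glandular"]
    n_gland = GLANDULAR_COUNTS[vgf_class]
    # Glandular lobes radiate from the areola axis towards the chest wall:
    # sphere centres sampled along cones from a point below the nipple.
    apex = np.array([0.0, 0.0, 0.75 * breast_radius])
    for _ in range(n_gland):
        for _attempt in range(100):
            phi = rng.uniform(0.0, 2.0 * math.pi)
            polar = rng.uniform(math.radians(35.0), math.radians(80.0))
            direction = np.array(
                [
                    math.sin(polar) * math.cos(phi),
                    math.sin(polar) * math.sin(phi),
                    -math.cos(polar),
                ]
            )
            t = rng.uniform(0.25, 0.55) * breast_radius
            radius = rng.uniform(0.008, 0.012)
            center = apex + t * direction
            if (
                np.linalg.norm(center) + radius < breast_radius - 0.002
                and center[2] - radius > 0.0
            ):
                break
        else:  # pragma: no cover - rejection sampling practically always succeeds
            raise GeometryError("could not place glandular scatterer inside breast")
        scatterers.append(
            Scatterer(center, radius, eps_g, sigma_g, kind="glandular")
        )

    if skin_residual_scale > 0:
        scatterers.extend(
            _skin_residual_ring(
                rng,
                breast_radius,
                count=skin_residual_count,
                base_radius=0.0015 * skin_residual_scale,
                symmetric=False,
            )
        )

    tumor = None
    if tumor_diameter_mm is not None:
        eps_t, sigma_t = TISSUES["tumor"]
        tumor = Scatterer(
            center=TUMOR_LOCATION.copy(),
            radius=tumor_diameter_mm * 1e-3 / 2.0,
            relative_permittivity=eps_t,
            conductivity=sigma_t,
            kind="tumor",
        )

    return BreastPhantom(
        vgf_class=vgf_class,
        scatterers=tuple(scatterers),
        tumor=tumor,
        background_permittivity=background_permittivity,
        breast_radius=breast_radius,
    )


def build_reference_phantom(
    array_symmetry_order: int,
    background_permittivity: float = 8.0,
    breast_radius: float = 0.07,
    skin_residual_scale: float = 1.0,
) -> BreastPhantom:
    """Homogeneous calibration phantom: adipose background plus a skin ring
    that is exactly symmetric under the array's azimuthal step.

    With ``skin_residual_scale = 0`` the phantom is empty and its scan is
    identically zero (noise aside).
    """
    scatterers: list[Scatterer] = []
    if skin_residual_scale > 0:
        scatterers = _skin_residual_ring(
            None,
            breast_radius,
            count=2 * array_symmetry_order,
            base_radius=0.0015 * skin_residual_scale,
            symmetric=True,
        )
    return BreastPhantom(
        vgf_class=0,
        scatterers=tuple(scatterers),
        tumor=None,
        background_permittivity=background_permittivity,
        breast_radius=breast_radius,
    )
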