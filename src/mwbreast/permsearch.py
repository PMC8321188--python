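"""Patient-specific permittivity estimation by image-quality parameter search.

The reconstruction (effective) permittivity is unknown in practice; images
are therefore reconstructed over a grid of candidate values (default 25
points on [8, 14]) and scored with an absolute-gradient focal-quality cost:
a sharply focused response produces a compact, intense peak with steep
flanks, so the cost is maximised over the grid and the maximising image is
selected for detection.

Two members of the absolute-gradient family are provided:

* ``"max_gradient"`` (the sweep default) — the maximum absolute intensity
  difference between adjacent in-mask voxels, i.e. the steepest edge in the
  image.  It scales with the peak amplitude and is insensitive to the
  spatial dilation that defocusing produces, which makes its argmax track
  the true background permittivity on single-scattering synthetic scenes.
* ``"total_gradient"`` — the total absolute first difference over all
  adjacent in-mask voxel pairs (3-D total variation), optionally on the
  unit-maximum-normalised image (``normalize="max"``).  Under defocus the
  image dilates spatially and a 3-D total variation grows roughly with the
  dilation squared, which biases this variant towards low permittivities;
  it is kept for comparison and as the literal total-variation reading.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .beamform import (
    BeamformerConfig,
    ImagingGrid,
    MicrowaveImage,
    das_and_dmas_images,
    das_image,
    dmas_image,
)
from .errors import GeometryError
from .metrics import QualityReport, quality_report
from .phantoms import BreastPhantom
from .scans import MultistaticScan

__all__ = [
    "PermittivityGrid",
    "SweepResult",
    "absolute_gradient",
    "max_absolute_gradient",
    "sweep",
    "sweep_pair",
    "select_image",
]


@dataclass(frozen=True)
class PermittivityGrid:
    """Strictly increasing candidate effective permittivities (all >= 1)."""

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.size == 0:
            raise GeometryError("permittivity grid is empty")
        if np.any(v < 1.0):
            raise GeometryError("permittivities must be >= 1")
        if v.size > 1 and np.any(np.diff(v) <= 0):
            raise GeometryError("permittivities must be strictly increasing")

    @classmethod
    def default(cls, n: int = 25, lo: float = 8.0, hi: float = 14.0):
        """25 evenly spaced values on [8, 14] (0.25 steps)."""
        return cls(np.linspace(lo, hi, n))

    @property
    def n_points(self) -> int:
        return self.values.size


def _axis_differences(image: MicrowaveImage, normalize: Optional[str]):
    """Yield |adjacent in-mask intensity differences| along each grid axis."""
    if normalize not in (None, "max"):
        raise GeometryError(f"unknown normalization {normalize!r}")
    vol = image.volume()
    mask = image.grid.mask
    if normalize == "max":
        peak = vol.max()
        if peak > 0.0:
            vol = vol / peak
    for axis in range(3):
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[axis] = slice(None, -1)
        sl_hi[axis] = slice(1, None)
        both = mask[tuple(sl_lo)] & mask[tuple(sl_hi)]
        diff = vol[tuple(sl_hi)] - vol[tuple(sl_lo)]
        yield np.abs(diff[both])


def absolute_gradient(image: MicrowaveImage, normalize: Optional[str] = None) -> float:
    """Total absolute-gradient focal quality of an image.

    Sum over in-mask voxel pairs adjacent along each grid axis of the
    absolute intensity difference.  ``normalize="max"`` first scales the
    image to unit maximum; an all-zero image scores 0.
    """
    return float(sum(d.sum() for d in _axis_differences(image, normalize)))


def max_absolute_gradient(image: MicrowaveImage) -> float:
    """Maximum absolute intensity difference between adjacent in-mask voxels.

    The steepest edge in the image; the sweep's default focal-quality cost.
    """
    return float(
        max((d.max() if d.size else 0.0) for d in _axis_differences(image, None))
    )


def _cost_value(image: MicrowaveImage, cost: str, normalize: Optional[str]) -> float:
    if cost == "max_gradient":
        return max_absolute_gradient(image)
    if cost == "total_gradient":
        return absolute_gradient(image, normalize=normalize)
    raise GeometryError(f"unknown focal-quality cost {cost!r}")


@dataclass
class SweepResult:
    """Outcome of one scan x beamformer permittivity sweep."""

    beamformer: str
    permittivities: np.ndarray
    costs: np.ndarray
    images: list[MicrowaveImage]
    reports: list[QualityReport]
    selected_index: int
    scan_id: Optional[str] = None
    meta: dict = field(default_factory=dict)

    @property
    def selected_permittivity(self) -> float:
        return float(self.permittivities[self.selected_index])

    @property
    def selected_image(self) -> MicrowaveImage:
        return self.images[self.selected_index]

    @property
    def selected_report(self) -> QualityReport:
        return self.reports[self.selected_index]


def sweep(
    scan: MultistaticScan,
    beamformer: str,
    grid: ImagingGrid,
    perms: PermittivityGrid = None,
    config: BeamformerConfig = BeamformerConfig(),
    truth: Optional[BreastPhantom] = None,
    cost: str = "max_gradient",
    normalize: Optional[str] = None,
    peak_margin: float = 0.0,
) -> SweepResult:
    """Reconstruct one image per candidate permittivity and score each.

    The selected index maximises the focal-quality cost; ties are broken
    towards the lower permittivity.  Deterministic.
    """
    if beamformer not in ("das", "dmas"):
        raise GeometryError(f"unknown beamformer {beamformer!r}")
    if perms is None:
        perms = PermittivityGrid.default()
    form = das_image if beamformer == "das" else dmas_image
    images, costs, reports = [], [], []
    for eps in perms.values:
        img = form(scan, grid, float(eps), config)
        images.append(img)
        costs.append(_cost_value(img, cost, normalize))
        reports.append(quality_report(img, truth=truth, peak_margin=peak_margin))
    costs = np.asarray(costs)
    selected = int(np.argmax(costs))  # argmax takes the first (lowest) maximiser
    return SweepResult(
        beamformer=beamformer,
        permittivities=perms.values.copy(),
        costs=costs,
        images=images,
        reports=reports,
        selected_index=selected,
        scan_id=scan.meta.get("case_id"),
        meta={
            "cost": cost,
            "normalize": normalize,
            "history": list(scan.meta.get("history", [])),
        },
    )


def sweep_pair(
    scan: MultistaticScan,
    grid: ImagingGrid,
    perms: PermittivityGrid = None,
    config: BeamformerConfig = BeamformerConfig(),
    truth: Optional[BreastPhantom] = None,
    cost: str = "max_gradient",
    normalize: Optional[str] = None,
    peak_margin: float = 0.0,
) -> tuple[SweepResult, SweepResult]:
    """DAS and DMAS sweeps of the same scan from shared focusing passes.

    Produces exactly the results of ``sweep(scan, "das", ...)`` and
    ``sweep(scan, "dmas", ...)``; the two selections remain independent
    (each beamformer's cost is maximised over its own images).
    """
    if perms is None:
        perms = PermittivityGrid.default()
    results = {"das": ([], [], []), "dmas": ([], [], [])}
    for eps in perms.values:
        pair = das_and_dmas_images(scan, grid, float(eps), config)
        for img, (images, costs, reports) in zip(pair, results.values()):
            images.append(img)
            costs.append(_cost_value(img, cost, normalize))
            reports.append(quality_report(img, truth=truth, peak_margin=peak_margin))
    out = []
    for name, (images, costs, reports) in results.items():
        costs = np.asarray(costs)
        out.append(
            SweepResult(
                beamformer=name,
                permittivities=perms.values.copy(),
                costs=costs,
                images=images,
                reports=reports,
                selected_index=int(np.argmax(costs)),
                scan_id=scan.meta.get("case_id"),
                meta={
                    "cost": cost,
                    "normalize": normalize,
                    "history": list(scan.meta.get("history", [])),
                },
            )
        )
    return tuple(out)


def select_image(result: SweepResult) -> tuple[float, MicrowaveImage, QualityReport]:
    """The cost-maximising entry of a sweep: (permittivity, image, report)."""
    return (
        result.selected_permittivity,
        result.selected_image,
        result.selected_report,
    )
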