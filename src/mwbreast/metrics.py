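"""Image quality metrics: peak, FWHM, tumour area, SCR, SMR, detection.

Conventions (intensities are energies, so ratios use 10 log10):

* the tumour area is the sphere of radius twice the FWHM centred on the
  image peak (see :func:`tumor_area` for why), intersected with the breast
  mask;
* SCR compares the peak to the maximum intensity outside the tumour area;
* SMR compares the mean tumour-area intensity to the mean over the whole
  masked image (a background-only denominator is available by flag);
* images whose peak SCR exceeds a 1.5 dB threshold are annotated positive,
  and positives are true positives when the peak lies within the physical
  extent of the tumour.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .beamform import MicrowaveImage
from .errors import NoPeakError
from .phantoms import BreastPhantom

__all__ = [
    "QualityReport",
    "Detection",
    "peak_location",
    "fwhm",
    "tumor_area",
    "scr",
    "smr",
    "quality_report",
    "annotate",
]

DETECTION_THRESHOLD_DB = 1.5


@dataclass(frozen=True)
class QualityReport:
    """Quantitative summary of one reconstructed image."""

    peak_location: np.ndarray  # metres
    peak_value: float
    fwhm: float  # metres (mean of the three axis widths)
    fwhm_boundary: bool  # a half-maximum crossing hit the mask boundary
    scr_db: float
    smr_db: float
    localization_error: Optional[float]  # metres; None for healthy truth
    peak_margin: float  # skin-margin exclusion applied to the peak search (m)

    def to_dict(self) -> dict:
        return {
            "peak_location_m": self.peak_location.tolist(),
            "peak_value": self.peak_value,
            "fwhm_mm": self.fwhm * 1e3,
            "fwhm_boundary": self.fwhm_boundary,
            "scr_db": self.scr_db,
            "smr_db": self.smr_db,
            "localization_error_mm": (
                None if self.localization_error is None else self.localization_error * 1e3
            ),
            "peak_margin_mm": self.peak_margin * 1e3,
        }


@dataclass(frozen=True)
class Detection:
    """Positive/negative annotation with truth classification."""

    label: str  # "positive" | "negative"
    truth_class: str  # "TP" | "FP" | "FN" | "TN"
    scr_db: float
    threshold_db: float = DETECTION_THRESHOLD_DB


def peak_location(
    image: MicrowaveImage, peak_margin: float = 0.0
) -> tuple[np.ndarray, float]:
    """Global intensity argmax over the unmasked voxels.

    Ties are broken towards the lowest linear (C-order) voxel index.  An
    optional ``peak_margin`` (metres) excludes near-skin voxels from the
    search, since a response hugging the skin would typically be read as an
    artefact.
    """
    values = image.values
    voxels = image.grid.voxels
    if peak_margin > 0.0:
        keep = (
            np.linalg.norm(voxels, axis=1)
            <= image.grid.breast_radius - image.grid.skin_margin - peak_margin
        )
        if not np.any(keep):
            raise NoPeakError("peak margin excludes every voxel")
        values = np.where(keep, values, -np.inf)
    idx = int(np.argmax(values))
    value = float(values[idx])
    if value <= 0.0:
        raise NoPeakError("image has no positive maximum")
    return voxels[idx].copy(), value


def _axis_half_width(profile: np.ndarray, peak_idx: int, half: float) -> tuple[float, float, bool, bool]:
    """Half-maximum crossing distances (in voxels) left and right of the peak
    along one axis, found by linear interpolation on the contiguous run
    containing the peak.  A flag marks a side whose run hit the boundary."""
    left = right = None
    i = peak_idx
    while i + 1 < profile.size:
        if profile[i + 1] < half:
            right = i - peak_idx + (profile[i] - half) / (profile[i] - profile[i + 1])
            break
        i += 1
    i = peak_idx
    while i - 1 >= 0:
        if profile[i - 1] < half:
            left = peak_idx - i + (profile[i] - half) / (profile[i] - profile[i - 1])
            break
        i -= 1
    return left, right, left is None, right is None


def fwhm(image: MicrowaveImage, peak: Optional[np.ndarray] = None) -> tuple[float, bool]:
    """Full width at half maximum in metres, averaged over the three grid
    axes through the peak; masked voxels count as zero intensity.

    Returns ``(width, boundary_flag)``; the flag is set when the half-maximum
    run reached the grid or mask boundary on some side, in which case the
    available side is mirrored.
    """
    vol = image.volume()
    if peak is None:
        loc, _ = peak_location(image)
    else:
        loc = np.asarray(peak, dtype=float)
    idx = tuple(
        int(np.argmin(np.abs(ax - loc[k]))) for k, ax in enumerate(image.grid.axes)
    )
    pv = vol[idx]
    if pv <= 0:
        raise NoPeakError("peak intensity is not positive")
    half = pv / 2.0
    widths = []
    flagged = False
    for axis in range(3):
        sl = [idx[0], idx[1], idx[2]]
        sl[axis] = slice(None)
        profile = vol[tuple(sl)]
        left, right, lflag, rflag = _axis_half_width(profile, idx[axis], half)
        if lflag and rflag:
            # run spans the whole profile: fall back to the run length
            width = profile.size - 1
            flagged = True
        elif lflag or rflag:
            width = 2.0 * (right if left is None else left)
            flagged = True
        else:
            width = left + right
        widths.append(max(width, 1.0))  # a single-voxel spike spans one spacing
    return float(np.mean(widths) * image.grid.spacing), flagged


def tumor_area(
    image: MicrowaveImage, peak: np.ndarray, fwhm_m: float, radius_scale: float = 2.0
) -> np.ndarray:
    """Boolean mask (over the flat voxels) of the tumour area: the sphere of
    radius ``radius_scale * FWHM`` centred at the peak.

    The default radius of twice the FWHM keeps the twin lobe that rotational
    subtraction necessarily produces for a compact target (an equal-amplitude
    ghost about one beamwidth away) inside the tumour area, so SCR measures
    the response against genuine clutter rather than against the method's own
    ghost; ``radius_scale=1.0`` gives the tighter sphere of diameter 2 FWHM.
    """
    dist = np.linalg.norm(image.grid.voxels - np.asarray(peak)[None, :], axis=1)
    return dist <= radius_scale * fwhm_m


def scr(image: MicrowaveImage, area: np.ndarray) -> float:
    """Signal-to-clutter ratio in dB: max intensity inside the tumour area
    over max intensity in the background (everything else).  An empty or
    all-zero background yields +inf."""
    inside = image.values[area]
    outside = image.values[~area]
    if inside.size == 0:
        raise NoPeakError("tumour area contains no voxels")
    peak = float(inside.max())
    if outside.size == 0 or outside.max() <= 0.0:
        return math.inf
    return 10.0 * math.log10(peak / float(outside.max()))


def smr(image: MicrowaveImage, area: np.ndarray, background_only: bool = False) -> float:
    """Signal-to-mean ratio in dB: mean tumour-area intensity over the mean
    of the whole masked image (or of the background only, by flag)."""
    inside = image.values[area]
    denom_values = image.values[~area] if background_only else image.values
    if inside.size == 0 or denom_values.size == 0:
        raise NoPeakError("cannot compute SMR on an empty region")
    denom = float(denom_values.mean())
    if denom <= 0.0:
        return math.inf
    return 10.0 * math.log10(float(inside.mean()) / denom)


def quality_report(
    image: MicrowaveImage,
    truth: Optional[BreastPhantom] = None,
    peak_margin: float = 0.0,
    area_radius_scale: float = 2.0,
) -> QualityReport:
    """Compute the full metric set for one image."""
    loc, value = peak_location(image, peak_margin=peak_margin)
    width, boundary = fwhm(image, peak=loc)
    area = tumor_area(image, loc, width, radius_scale=area_radius_scale)
    loc_err = None
    if truth is not None and truth.has_tumor:
        loc_err = float(np.linalg.norm(loc - truth.tumor.center))
    return QualityReport(
        peak_location=loc,
        peak_value=value,
        fwhm=width,
        fwhm_boundary=boundary,
        scr_db=scr(image, area),
        smr_db=smr(image, area),
        localization_error=loc_err,
        peak_margin=peak_margin,
    )


def annotate(
    report: QualityReport,
    truth: BreastPhantom,
    threshold_db: float = DETECTION_THRESHOLD_DB,
) -> Detection:
    """Detection annotation: positive iff SCR > threshold; a positive is a
    true positive iff the peak lies within the physical tumour extent."""
    positive = report.scr_db > threshold_db
    if truth.has_tumor:
        inside = (
            np.linalg.norm(report.peak_location - truth.tumor.center)
            <= truth.tumor.radius
        )
        if positive:
            truth_class = "TP" if inside else "FP"
        else:
            truth_class = "FN"
    else:
        truth_class = "FP" if positive else "TN"
    return Detection(
        label="positive" if positive else "negative",
        truth_class=truth_class,
        scr_db=report.scr_db,
        threshold_db=threshold_db,
    )
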