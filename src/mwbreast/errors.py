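"""Exception types shared across the package."""


class MwBreastError(Exception):
    """Base class for package errors."""


class GeometryError(MwBreastError):
    """Invalid antenna-array or phantom geometry."""


class FormatError(MwBreastError):
    """Malformed scan or image file; the message names the missing field."""


class DegenerateReferenceError(MwBreastError):
    """Reference scan unusable for calibration (zero-magnitude channel)."""


class IncompatibleRotationError(MwBreastError):
    """Requested rotation angle is not a symmetry of the antenna array."""


class NoPeakError(MwBreastError):
    """Image has no positive maximum; peak-based metrics are undefined."""
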