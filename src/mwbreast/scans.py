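"""Multistatic scan container, HDF5 I/O, calibration and rotational subtraction.

A multistatic scan holds one complex sample per (transmit antenna, receive
antenna, frequency).  Channels are ordered (tx, rx) pairs; by default the
monostatic pairs (tx == rx) are excluded since they are dominated by the skin
reflection in the emulated acquisition.

Two preprocessing steps are provided:

* reference-scan calibration — per-antenna factors computed from a scan of a
  homogeneous phantom, equalising each antenna's mean channel magnitude;
* rotational subtraction — subtracting the scan from a copy of itself rotated
  by one array-symmetry step, cancelling rotationally symmetric reflections.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import h5py
import numpy as np

from .errors import DegenerateReferenceError, FormatError, GeometryError
from .phantoms import AntennaArray

__all__ = [
    "MultistaticScan",
    "CalibrationFactors",
    "bistatic_channels",
    "write_scan",
    "read_scan",
    "compute_calibration",
    "apply_calibration",
    "rotational_subtract",
]


def bistatic_channels(n_antennas: int, include_monostatic: bool = False) -> np.ndarray:
    """Ordered (tx, rx) channel index pairs in lexicographic order."""
    tx, rx = np.meshgrid(np.arange(n_antennas), np.arange(n_antennas), indexing="ij")
    pairs = np.stack([tx.ravel(), rx.ravel()], axis=1)
    if not include_monostatic:
        pairs = pairs[pairs[:, 0] != pairs[:, 1]]
    return pairs


@dataclass
class MultistaticScan:
    """Frequency-domain multistatic scattering data.

    Attributes
    ----------
    data
        Complex ``(n_channels, n_frequencies)`` matrix.
    channels
        ``(n_channels, 2)`` integer (tx, rx) antenna indices.
    frequencies
        Strictly increasing frequency axis in Hz.
    array
        The antenna array the channel indices refer to.
    meta
        Provenance: case id and an append-only ``history`` list of
        preprocessing steps.
    """

    data: np.ndarray
    channels: np.ndarray
    frequencies: np.ndarray
    array: AntennaArray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.channels = np.asarray(self.channels, dtype=int)
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if self.data.ndim != 2:
            raise FormatError("scan data must be a 2-D (channels x frequencies) matrix")
        if self.data.shape != (self.channels.shape[0], self.frequencies.shape[0]):
            raise FormatError(
                f"scan data shape {self.data.shape} inconsistent with "
                f"{self.channels.shape[0]} channels x {self.frequencies.shape[0]} "
                "frequencies"
            )
        if self.channels.size and self.channels.max() >= self.array.n_antennas:
            raise GeometryError("channel index exceeds antenna count")
        if not np.all(np.isfinite(self.data)):
            raise FormatError("scan data contains non-finite samples")
        self.meta.setdefault("history", [])

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_frequencies(self) -> int:
        return self.data.shape[1]

    def with_data(self, data: np.ndarray, step: Optional[dict] = None) -> "MultistaticScan":
        """Copy of the scan with new data and an optional history entry."""
        meta = {k: v for k, v in self.meta.items() if k != "history"}
        meta["history"] = list(self.meta.get("history", []))
        if step is not None:
            meta["history"].append(step)
        return MultistaticScan(
            data=data,
            channels=self.channels.copy(),
            frequencies=self.frequencies.copy(),
            array=self.array,
            meta=meta,
        )

    def channel_row(self, tx: int, rx: int) -> int:
        """Row index of channel (tx, rx); raises KeyError if absent."""
        return self._channel_lookup()[(tx, rx)]

    def _channel_lookup(self) -> dict:
        lut = getattr(self, "_lut", None)
        if lut is None:
            lut = {(int(t), int(r)): i for i, (t, r) in enumerate(self.channels)}
            self._lut = lut
        return lut

    def channel_matrices(self, dtype=np.complex128) -> np.ndarray:
        """Dense ``(n_frequencies, n_antennas, n_antennas)`` per-frequency
        channel matrices, zero where a channel is absent."""
        na = self.array.n_antennas
        out = np.zeros((self.n_frequencies, na, na), dtype=dtype)
        out[:, self.channels[:, 0], self.channels[:, 1]] = self.data.T.astype(dtype)
        return out


# ---------------------------------------------------------------------------
# HDF5 serialization
#
# Layout: /data_re, /data_im float64 (channels x freqs); /channels int (n x 2);
# /freqs Hz float64; /array/positions (n x 3) with radome radius and symmetry
# order as attributes; /meta a JSON string (includes the history list).
# ---------------------------------------------------------------------------

def write_scan(scan: MultistaticScan, path) -> None:
    """Write a scan to an HDF5 file (lossless round trip)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("data_re", data=scan.data.real.astype(np.float64))
        f.create_dataset("data_im", data=scan.data.imag.astype(np.float64))
        f.create_dataset("channels", data=scan.channels)
        f.create_dataset("freqs", data=scan.frequencies)
        grp = f.create_group("array")
        grp.create_dataset("positions", data=scan.array.positions)
        grp.attrs["radome_radius"] = scan.array.radome_radius
        grp.attrs["rotational_symmetry_order"] = scan.array.rotational_symmetry_order
        f.create_dataset("meta", data=json.dumps(scan.meta))


def read_scan(path) -> MultistaticScan:
    """Read a scan written by :func:`write_scan`.

    Raises
    ------
    FormatError
        Naming the missing dataset or attribute if the file is malformed.
    """
    path = Path(path)
    with h5py.File(path, "r") as f:
        for name in ("data_re", "data_im", "channels", "freqs", "meta"):
            if name not in f:
                raise FormatError(f"scan file {path} is missing field '{name}'")
        if "array" not in f or "positions" not in f["array"]:
            raise FormatError(f"scan file {path} is missing field 'array/positions'")
        grp = f["array"]
        for attr in ("radome_radius", "rotational_symmetry_order"):
            if attr not in grp.attrs:
                raise FormatError(f"scan file {path} is missing field 'array.{attr}'")
        array = AntennaArray(
            positions=grp["positions"][()],
            radome_radius=float(grp.attrs["radome_radius"]),
            rotational_symmetry_order=int(grp.attrs["rotational_symmetry_order"]),
        )
        data = f["data_re"][()] + 1j * f["data_im"][()]
        return MultistaticScan(
            data=data,
            channels=f["channels"][()],
            frequencies=f["freqs"][()],
            array=array,
            meta=json.loads(f["meta"][()].decode()),
        )


# ---------------------------------------------------------------------------
# Reference-scan calibration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CalibrationFactors:
    """Per-antenna real factors; channel (a, a') is scaled by f[a] * f[a']."""

    factors: np.ndarray

    def __post_init__(self):
        f = np.asarray(self.factors, dtype=float)
        object.__setattr__(self, "factors", f)
        if not np.all(np.isfinite(f)) or np.any(f == 0):
            raise DegenerateReferenceError("calibration factors must be finite and nonzero")


def compute_calibration(
    reference: MultistaticScan,
    tol: float = 1e-12,
    max_iter: int = 1000,
) -> CalibrationFactors:
    """Per-antenna magnitude-equalising factors from a homogeneous reference.

    Iterates the per-antenna magnitude equalisation
    ``f_a <- f_a * sqrt(mean|channels| / mean|channels involving a|)`` to its
    fixed point (a symmetric Sinkhorn scaling), at which every antenna's mean
    calibrated channel magnitude equals the array-wide mean.  On a noise-free
    reference with per-antenna gains ``g`` the factors recover ``1/|g|`` up to
    the array's intrinsic (gain-independent) per-ring response and one global
    scale.  Phases are left untouched: phase equalisation is ill-posed without
    a known reference target.
    """
    mags = np.abs(reference.data).mean(axis=1)  # mean |sample| per channel
    if np.any(mags == 0):
        raise DegenerateReferenceError(
            "reference scan has a zero-magnitude channel; cannot calibrate"
        )
    na = reference.array.n_antennas
    tx, rx = reference.channels[:, 0], reference.channels[:, 1]
    f = np.ones(na)
    for _ in range(max_iter):
        cur = mags * f[tx] * f[rx]
        means = np.zeros(na)
        counts = np.zeros(na)
        np.add.at(means, tx, cur)
        np.add.at(means, rx, cur)
        np.add.at(counts, tx, 1)
        np.add.at(counts, rx, 1)
        means /= counts
        target = cur.mean()
        ratio = target / means
        if np.max(np.abs(ratio - 1.0)) < tol:
            break
        f *= np.sqrt(ratio)
    return CalibrationFactors(factors=f)


def apply_calibration(scan: MultistaticScan, factors: CalibrationFactors) -> MultistaticScan:
    """Scale channel (a, a') by ``f[a] * f[a']``; appends to the history."""
    f = factors.factors
    if f.shape[0] != scan.array.n_antennas:
        raise GeometryError(
            f"{f.shape[0]} calibration factors for {scan.array.n_antennas} antennas"
        )
    scale = f[scan.channels[:, 0]] * f[scan.channels[:, 1]]
    return scan.with_data(
        scan.data * scale[:, None],
        step={"op": "calibrate"},
    )


# ---------------------------------------------------------------------------
# Rotational subtraction
# ---------------------------------------------------------------------------

def rotational_subtract(scan: MultistaticScan, angle_degrees: float) -> MultistaticScan:
    """Subtract the scan rotated by ``angle_degrees`` about +z from itself.

    Output channel (a, a') is ``input(a, a') - input(pi(a), pi(a'))`` where
    ``pi`` is the antenna permutation induced by the rotation.  Rotationally
    symmetric contributions (the skin reflection) cancel; everything else
    leaves a residual plus a rotated "ghost" copy.

    Raises
    ------
    IncompatibleRotationError
        If the angle is not a symmetry of the array.
    """
    perm = scan.array.rotation_permutation(angle_degrees)
    lut = scan._channel_lookup()
    rows = np.empty(scan.n_channels, dtype=int)
    for i, (t, r) in enumerate(scan.channels):
        rows[i] = lut[(int(perm[t]), int(perm[r]))]
    return scan.with_data(
        scan.data - scan.data[rows],
        step={"op": "rotational_subtract", "angle_degrees": float(angle_degrees)},
    )
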