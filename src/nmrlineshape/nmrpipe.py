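"""NMRPipe 2D (.ft2) reading and writing, and frequency-axis arithmetic.

An .ft2 file is a 512-float32 header (2048 bytes) followed by the real
intensity plane in row-major order (rows = indirect dimension).  Only the
header fields needed for lineshape analysis are interpreted: per-dimension
observe frequency (MHz), sweep width (Hz), frequency origin (Hz), sizes,
quadrature/FT flags and axis labels.

Axis convention (standard for processed NMRPipe data): point ``i`` of an
``N``-point frequency axis lies at

    hz(i) = ORIG + (N - 1 - i) * SW / N

so the first point is the high-frequency edge and the carrier sits at point
``N // 2``, i.e. ``ORIG = OBS * CAR - SW/2 + SW/N``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import EstimationError, UnsupportedLayoutError

__all__ = ["AxisInfo", "Spectrum2D", "read_ft2", "write_ft2", "ppm_scale"]

HEADER_SIZE = 512  # float32 words

# header word indices (NMRPipe standard)
FDMAGIC = 0
FDFLTFORMAT = 1
FDFLTORDER = 2
FDDIMCOUNT = 9
FDF2LABEL = 16  # words 16-17
FDF1LABEL = 18  # words 18-19
FDDIMORDER = 24  # words 24-27
FDF1QUADFLAG = 55
FDF2QUADFLAG = 56
FDF2CAR = 66
FDF1CAR = 67
FDF2CENTER = 79
FDF1CENTER = 80
FDF2FTSIZE = 96
FDF1FTSIZE = 98
FDSIZE = 99
FDF2SW = 100
FDF2ORIG = 101
FDQUADFLAG = 106
FDF2OBS = 119
FDPIPEFLAG = 57
FDF1OBS = 218
FDSPECNUM = 219
FDF2FTFLAG = 220
FDTRANSPOSED = 221
FDF1FTFLAG = 222
FDF1SW = 229
FDF1ORIG = 249
FD2DPHASE = 256

_FLTFORMAT = 4008636160.0
_FLTORDER = 2.345


def ppm_scale(size: int, sw: float, obs: float, orig: float) -> np.ndarray:
    """ppm of each point of a frequency axis from header fields."""
    hz = orig + (size - 1 - np.arange(size)) * sw / size
    return hz / obs


@dataclass
class AxisInfo:
    """One frequency axis: size, sweep width (Hz), observe frequency (MHz),
    origin (Hz, frequency of the last point) and a short label."""

    size: int
    sw: float
    obs: float
    orig: float
    label: str = ""

    @classmethod
    def from_carrier(cls, size: int, sw: float, obs: float, car_ppm: float,
                     label: str = "") -> "AxisInfo":
        orig = obs * car_ppm - sw / 2.0 + sw / size
        return cls(size, sw, obs, orig, label)

    @property
    def car_ppm(self) -> float:
        return (self.orig + self.sw / 2.0 - self.sw / self.size) / self.obs

    def ppm(self) -> np.ndarray:
        return ppm_scale(self.size, self.sw, self.obs, self.orig)

    def hz(self) -> np.ndarray:
        return self.ppm() * self.obs


@dataclass
class Spectrum2D:
    """Real 2D spectrum on frequency axes.

    ``data`` has shape ``(axis_indirect.size, axis_direct.size)`` (rows are
    the indirect dimension).  ``noise_sigma`` is filled by
    :func:`nmrlineshape.processing.estimate_noise` or set manually.
    """

    data: np.ndarray
    axis_direct: AxisInfo
    axis_indirect: AxisInfo
    noise_sigma: Optional[float] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise UnsupportedLayoutError("spectrum data must be 2D")
        ny, nx = self.data.shape
        if nx != self.axis_direct.size or ny != self.axis_indirect.size:
            raise UnsupportedLayoutError(
                f"data shape {self.data.shape} does not match axis sizes "
                f"({self.axis_indirect.size}, {self.axis_direct.size})"
            )
        if self.noise_sigma is not None and self.noise_sigma <= 0:
            raise EstimationError("noise_sigma must be positive")

    @property
    def ppm_direct(self) -> np.ndarray:
        return self.axis_direct.ppm()

    @property
    def ppm_indirect(self) -> np.ndarray:
        return self.axis_indirect.ppm()


def _pack_label(header: np.ndarray, word: int, label: str) -> None:
    raw = label.encode("ascii", "replace")[:8].ljust(8, b"\x00")
    header[word:word + 2] = np.frombuffer(raw, dtype="<f4")


def _unpack_label(header: np.ndarray, word: int) -> str:
    raw = header[word:word + 2].tobytes()
    return raw.split(b"\x00", 1)[0].decode("ascii", "replace")


def read_ft2(path) -> Spectrum2D:
    """Read a processed real 2D NMRPipe spectrum.

    Raises :class:`UnsupportedLayoutError` for non-2D or complex layouts and
    :class:`OSError` for truncated files or size mismatches.
    """
    with open(path, "rb") as fh:
        buf = fh.read()
    if len(buf) < HEADER_SIZE * 4:
        raise OSError(f"{path}: file shorter than an NMRPipe header")
    header = np.frombuffer(buf[: HEADER_SIZE * 4], dtype="<f4").copy()
    byte_order = "<"
    if abs(header[FDFLTORDER] - _FLTORDER) > 1e-3:
        header = np.frombuffer(buf[: HEADER_SIZE * 4], dtype=">f4").astype("<f4")
        byte_order = ">"
        if abs(header[FDFLTORDER] - _FLTORDER) > 1e-3:
            raise OSError(f"{path}: not an NMRPipe file (bad float-order mark)")
    dims = int(round(float(header[FDDIMCOUNT])))
    if dims != 2:
        raise UnsupportedLayoutError(f"{path}: {dims}D data; only 2D supported")
    if int(header[FDTRANSPOSED]):
        raise UnsupportedLayoutError(f"{path}: transposed planes not supported")
    for flag, name in ((FDQUADFLAG, "data"), (FDF2QUADFLAG, "F2"),
                       (FDF1QUADFLAG, "F1")):
        if int(round(float(header[flag]))) != 1:
            raise UnsupportedLayoutError(
                f"{path}: complex {name} plane; only real .ft2 supported"
            )
    if not (int(header[FDF2FTFLAG]) and int(header[FDF1FTFLAG])):
        raise UnsupportedLayoutError(f"{path}: time-domain data; expected .ft2")
    nx = int(round(float(header[FDSIZE])))
    ny = int(round(float(header[FDSPECNUM])))
    expected = HEADER_SIZE * 4 + 4 * nx * ny
    if len(buf) != expected:
        raise OSError(
            f"{path}: declared size {ny}x{nx} needs {expected} bytes, "
            f"file has {len(buf)}"
        )
    data = np.frombuffer(buf[HEADER_SIZE * 4:], dtype=byte_order + "f4")
    data = data.reshape(ny, nx)
    ax2 = AxisInfo(nx, float(header[FDF2SW]), float(header[FDF2OBS]),
                   float(header[FDF2ORIG]), _unpack_label(header, FDF2LABEL))
    ax1 = AxisInfo(ny, float(header[FDF1SW]), float(header[FDF1OBS]),
                   float(header[FDF1ORIG]), _unpack_label(header, FDF1LABEL))
    return Spectrum2D(np.asarray(data), ax2, ax1)


def write_ft2(spectrum: Spectrum2D, path) -> None:
    """Write a real 2D spectrum as NMRPipe .ft2 (little-endian float32)."""
    ax2, ax1 = spectrum.axis_direct, spectrum.axis_indirect
    header = np.zeros(HEADER_SIZE, dtype="<f4")
    header[FDMAGIC] = 0.0
    header[FDFLTFORMAT] = _FLTFORMAT
    header[FDFLTORDER] = _FLTORDER
    header[FDDIMCOUNT] = 2.0
    header[FDDIMORDER:FDDIMORDER + 4] = (2.0, 1.0, 3.0, 4.0)
    header[FDPIPEFLAG] = 0.0
    header[FDQUADFLAG] = 1.0
    header[FDF2QUADFLAG] = 1.0
    header[FDF1QUADFLAG] = 1.0
    header[FDTRANSPOSED] = 0.0
    header[FD2DPHASE] = 2.0  # States
    header[FDSIZE] = float(ax2.size)
    header[FDSPECNUM] = float(ax1.size)
    header[FDF2SW] = ax2.sw
    header[FDF2OBS] = ax2.obs
    header[FDF2ORIG] = ax2.orig
    header[FDF2CAR] = ax2.car_ppm
    header[FDF2FTFLAG] = 1.0
    header[FDF2FTSIZE] = float(ax2.size)
    header[FDF2CENTER] = float(ax2.size // 2 + 1)
    header[FDF1SW] = ax1.sw
    header[FDF1OBS] = ax1.obs
    header[FDF1ORIG] = ax1.orig
    header[FDF1CAR] = ax1.car_ppm
    header[FDF1FTFLAG] = 1.0
    header[FDF1FTSIZE] = float(ax1.size)
    header[FDF1CENTER] = float(ax1.size // 2 + 1)
    _pack_label(header, FDF2LABEL, ax2.label or "HN")
    _pack_label(header, FDF1LABEL, ax1.label or "15N")
    with open(path, "wb") as fh:
        fh.write(header.tobytes())
        fh.write(np.ascontiguousarray(spectrum.data, dtype="<f4").tobytes())
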