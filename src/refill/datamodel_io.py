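"""Core data types, phase-wrapping conventions and NIfTI I/O.

Conventions used throughout the package:

* array axes are ordered ``[x (readout), y (phase-encode), z (slice)]``,
  with optional trailing ``coil`` and ``echo``/``time`` axes;
* phase is stored wrapped to ``[-pi, pi)`` (lower limit inclusive);
* the canonical field-map unit is angular frequency offset in rad/s
  (helpers convert to Hz and Tesla);
* missing / out-of-mask voxels are encoded as NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np

__all__ = [
    "GAMMA_1H",
    "TWO_PI",
    "AcquisitionMeta",
    "CoilStack",
    "Volume",
    "PhaseOffsetMap",
    "ReadoutRamp",
    "wrap_phase",
    "rad_s_to_hz",
    "hz_to_rad_s",
    "rad_s_to_tesla",
    "readout_coordinate",
    "load_coil_stack",
    "save_volume",
    "load_volume",
]

#: gyromagnetic ratio of 1H in rad/s/T
GAMMA_1H = 2.675e8
TWO_PI = 2.0 * np.pi

_VOLUME_KINDS = ("phase", "magnitude", "fieldmap_rad_s", "quality", "vsm_voxels", "mask")


def wrap_phase(phi, lower_limit: float = -np.pi):
    """Wrap phase into ``[lower_limit, lower_limit + 2*pi)``.

    The output differs from the input by an integer multiple of 2*pi, so
    ``exp(1j * wrap_phase(phi)) == exp(1j * phi)`` to machine precision.
    A total function: any finite input is valid.
    """
    phi = np.asarray(phi, dtype=float)
    return (phi - lower_limit) % TWO_PI + lower_limit


def rad_s_to_hz(omega):
    """Angular frequency offset (rad/s) to frequency offset (Hz)."""
    return np.asarray(omega) / TWO_PI


def hz_to_rad_s(f):
    return np.asarray(f) * TWO_PI


def rad_s_to_tesla(omega, gamma: float = GAMMA_1H):
    """Angular frequency offset (rad/s) to field offset (T) via Larmor."""
    return np.asarray(omega) / gamma


def readout_coordinate(n_readout: int):
    """Readout coordinate in voxels, measured from the array centre.

    Ramp phase is ``slope * readout_coordinate(nx)`` throughout; centring at
    the geometric centre ``(nx - 1) / 2`` keeps the ramp sign symmetric with
    the k-space echo shift.
    """
    return np.arange(n_readout, dtype=float) - (n_readout - 1) / 2.0


@dataclass(frozen=True)
class AcquisitionMeta:
    """Acquisition metadata shared by reference and EPI scans.

    Parameters
    ----------
    echo_times:
        Echo times in seconds, strictly increasing. Three entries
        ``(dTE, 2*dTE, 3*dTE)`` for the bipolar FLASH reference scan, a
        single entry ``(TE_EPI,)`` for EPI.
    readout_polarity, pe_polarity:
        +1 or -1; orientation of the (first) readout line and of the
        phase-encode blips.
    pe_bandwidth_per_pixel:
        Bandwidth per pixel along the phase-encode axis in Hz/pixel;
        required for any distortion/VSM computation.
    voxel_size:
        mm per axis (x, y, z).
    gamma:
        Gyromagnetic ratio in rad/s/T (1H by default).
    first_lobe_negative:
        Echo-polarity bookkeeping for bipolar trains: if True (default),
        odd echoes (1-based) carry ``-ramp`` and even echoes ``+ramp``.
        Flip if the acquisition's first readout lobe is inverted.
    """

    echo_times: tuple = ()
    readout_polarity: int = 1
    pe_polarity: int = 1
    pe_bandwidth_per_pixel: float | None = None
    voxel_size: tuple = (3.3, 3.3, 3.3)
    fov: tuple | None = None
    gamma: float = GAMMA_1H
    axes: str = "readout,pe,slice"
    first_lobe_negative: bool = True

    def __post_init__(self):
        te = tuple(float(t) for t in self.echo_times)
        object.__setattr__(self, "echo_times", te)
        if any(t <= 0 for t in te):
            raise ValueError("echo times must be positive")
        if any(b <= a for a, b in zip(te, te[1:])):
            raise ValueError("echo times must be strictly increasing")
        if self.readout_polarity not in (1, -1) or self.pe_polarity not in (1, -1):
            raise ValueError("polarities must be +1 or -1")
        if self.pe_bandwidth_per_pixel is not None and self.pe_bandwidth_per_pixel <= 0:
            raise ValueError("pe_bandwidth_per_pixel must be > 0")

    @property
    def n_echoes(self) -> int:
        return len(self.echo_times)

    @property
    def delta_te(self) -> float:
        """Echo spacing; requires uniform spacing (TEj = j * dTE)."""
        te = np.asarray(self.echo_times)
        d = np.diff(te)
        if len(d) == 0:
            raise ValueError("need at least two echoes for an echo spacing")
        if not np.allclose(d, d[0], rtol=1e-6, atol=1e-12):
            raise ValueError("echo spacing is not uniform")
        return float(d[0])

    def echo_ramp_sign(self, echo_index_1based: int) -> int:
        """Sign of the readout ramp carried by a given echo of a bipolar train."""
        sign = -1 if echo_index_1based % 2 == 1 else 1
        return sign if self.first_lobe_negative else -sign

    def with_(self, **kw) -> "AcquisitionMeta":
        return replace(self, **kw)


@dataclass
class CoilStack:
    """Per-channel magnitude + phase data with acquisition metadata.

    ``magnitude`` and ``phase`` share the shape ``(nx, ny, nz, n_coils)``
    plus an optional trailing axis tagged by ``stack_axis`` ("echo" for
    multi-echo reference data, "time" for an EPI series, None for a single
    volume).
    """

    magnitude: np.ndarray
    phase: np.ndarray
    meta: AcquisitionMeta
    stack_axis: str | None = None

    def __post_init__(self):
        self.magnitude = np.asarray(self.magnitude, dtype=float)
        self.phase = np.asarray(self.phase, dtype=float)
        if self.magnitude.shape != self.phase.shape:
            raise ValueError("magnitude/phase shapes differ")
        expected = 4 if self.stack_axis is None else 5
        if self.magnitude.ndim != expected:
            raise ValueError(
                f"expected {expected}-D array for stack_axis={self.stack_axis!r}, "
                f"got {self.magnitude.ndim}-D"
            )
        if np.any(self.magnitude < 0):
            raise ValueError("magnitude must be non-negative")
        if np.any(self.phase < -np.pi) or np.any(self.phase >= np.pi):
            raise ValueError("phase must be wrapped to [-pi, pi)")

    @property
    def grid(self) -> tuple:
        return self.magnitude.shape[:3]

    @property
    def n_coils(self) -> int:
        return self.magnitude.shape[3]

    @property
    def n_stacked(self) -> int:
        if self.stack_axis is None:
            return 1
        return self.magnitude.shape[4]

    def complex(self) -> np.ndarray:
        """Reconstitute complex data (magnitude * exp(i*phase))."""
        return self.magnitude * np.exp(1j * self.phase)

    def volume(self, index: int) -> "CoilStack":
        """Extract one echo/time point as a 4-D CoilStack."""
        if self.stack_axis is None:
            raise ValueError("stack has no echo/time axis")
        return CoilStack(
            self.magnitude[..., index], self.phase[..., index], self.meta, None
        )


@dataclass
class Volume:
    """A single 3-D volume with a semantic kind tag."""

    values: np.ndarray
    kind: str = "magnitude"
    meta: AcquisitionMeta | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("Volume expects a 3-D array")
        if self.kind not in _VOLUME_KINDS:
            raise ValueError(f"unknown kind {self.kind!r}; one of {_VOLUME_KINDS}")
        if self.kind == "quality":
            finite = self.values[np.isfinite(self.values)]
            if finite.size and (finite.min() < 0 or finite.max() > 1):
                raise ValueError("quality values must lie in [0, 1]")
        if self.kind == "mask":
            u = np.unique(self.values)
            if not np.all(np.isin(u, (0.0, 1.0))):
                raise ValueError("mask values must be 0/1")

    @property
    def finite_mask(self) -> np.ndarray:
        return np.isfinite(self.values)


@dataclass
class PhaseOffsetMap:
    """Per-coil wrapped time-zero phase offsets, shape (nx, ny, nz, n_coils)."""

    offsets: np.ndarray
    meta: AcquisitionMeta | None = None
    source_grid: tuple | None = None

    def __post_init__(self):
        self.offsets = np.asarray(self.offsets, dtype=float)
        if self.offsets.ndim != 4:
            raise ValueError("offsets must be (nx, ny, nz, n_coils)")
        if np.any(self.offsets < -np.pi) or np.any(self.offsets >= np.pi):
            raise ValueError("offsets must be wrapped to [-pi, pi)")
        if self.source_grid is None:
            self.source_grid = self.offsets.shape[:3]

    @property
    def grid(self) -> tuple:
        return self.offsets.shape[:3]

    @property
    def n_coils(self) -> int:
        return self.offsets.shape[3]


@dataclass
class ReadoutRamp:
    """Linear phase gradient along the readout axis.

    ``slope`` is rad/voxel, either a scalar (global) or one value per slice.
    An optional per-voxel map (rad) is kept for diagnostics. The ramp phase
    at readout index x is ``slope * (x - x_centre)``.
    """

    slope: np.ndarray | float
    sequence: str = "FLASH"
    per_voxel_map: np.ndarray | None = None

    def __post_init__(self):
        self.slope = np.atleast_1d(np.asarray(self.slope, dtype=float))
        if self.sequence not in ("FLASH", "EPI"):
            raise ValueError("sequence must be 'FLASH' or 'EPI'")
        if np.any(np.abs(self.slope) >= np.pi / 2):
            raise ValueError("|slope| must be < pi/2 rad/voxel")

    def slope_for_slices(self, n_slices: int) -> np.ndarray:
        if self.slope.size == 1:
            return np.full(n_slices, float(self.slope[0]))
        if self.slope.size != n_slices:
            raise ValueError("per-slice slope count does not match volume")
        return self.slope

    def phase(self, shape3: Sequence[int]) -> np.ndarray:
        """Evaluate slope*x on a (nx, ny, nz) grid (broadcast over y)."""
        nx, ny, nz = shape3
        x = readout_coordinate(nx)[:, None, None]
        s = self.slope_for_slices(nz)[None, None, :]
        return np.broadcast_to(x * s, (nx, ny, nz)).copy()

    @property
    def mean_slope(self) -> float:
        return float(np.mean(self.slope))


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def _affine(meta: AcquisitionMeta | None) -> np.ndarray:
    vox = meta.voxel_size if meta is not None else (1.0, 1.0, 1.0)
    aff = np.diag(list(vox[:3]) + [1.0])
    return aff


def save_volume(v: Volume, path) -> Path:
    """Write a Volume (or the package's other arrays via ``save_array``) to NIfTI.

    The kind tag is recorded in the header description; masks and quality
    maps are stored as float so NaN sentinels survive a roundtrip.
    """
    path = Path(path)
    img = nib.Nifti1Image(v.values.astype(np.float32), _affine(v.meta))
    img.header["descrip"] = f"kind={v.kind}".encode()
    nib.save(img, str(path))
    return path


def load_volume(path, meta: AcquisitionMeta | None = None) -> Volume:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    descrip = bytes(img.header["descrip"]).decode(errors="ignore")
    kind = "magnitude"
    if "kind=" in descrip:
        kind = descrip.split("kind=")[1].split("\x00")[0].strip()
    if kind not in _VOLUME_KINDS:
        kind = "magnitude"
    return Volume(data, kind=kind, meta=meta)


def save_array(values: np.ndarray, path, meta: AcquisitionMeta | None = None) -> Path:
    """Write a raw (possibly >3-D) array to NIfTI (magnitude/phase stacks)."""
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(values, dtype=np.float32), _affine(meta))
    nib.save(img, str(path))
    return path


def _rescale_phase(data: np.ndarray, convention: str) -> np.ndarray:
    if convention == "radians":
        return wrap_phase(data)
    if convention == "range_2pi":  # stored on [0, 2*pi)
        return wrap_phase(data)
    if convention == "siemens_int":  # integers on [-4096, 4094] mapping to [-pi, pi)
        return wrap_phase(data * np.pi / 4096.0)
    raise ValueError(f"unknown phase rescale convention {convention!r}")


def load_coil_stack(
    magnitude_paths: Sequence,
    phase_paths: Sequence,
    meta: AcquisitionMeta,
    stack_axis: str | None = None,
    phase_convention: str = "radians",
) -> CoilStack:
    """Load per-coil magnitude/phase NIfTI files into a CoilStack.

    Each file holds one coil, either 3-D (single volume) or 4-D
    (echo/time along the 4th axis, matching ``stack_axis``). All files must
    share one grid; the phase is rewrapped to [-pi, pi) after applying the
    declared vendor rescale convention.
    """
    if len(magnitude_paths) != len(phase_paths):
        raise ValueError("need one phase file per magnitude file")
    mags, phases = [], []
    for mp, pp in zip(magnitude_paths, phase_paths):
        m = np.asarray(nib.load(str(mp)).dataobj, dtype=float)
        p = np.asarray(nib.load(str(pp)).dataobj, dtype=float)
        if m.shape != p.shape:
            raise ValueError(f"magnitude/phase shape mismatch for {mp}")
        mags.append(m)
        phases.append(p)
    shapes = {m.shape for m in mags}
    if len(shapes) != 1:
        raise ValueError(f"coil files disagree on grid: {sorted(shapes)}")
    # stack coils on axis 3: (nx, ny, nz, coil[, echo|time])
    if mags[0].ndim == 3:
        mag = np.stack(mags, axis=3)
        ph = np.stack(phases, axis=3)
        if stack_axis is not None:
            raise ValueError("3-D inputs cannot carry an echo/time axis")
    elif mags[0].ndim == 4:
        mag = np.stack(mags, axis=3)
        ph = np.stack(phases, axis=3)
        if stack_axis is None:
            raise ValueError("4-D inputs require stack_axis 'echo' or 'time'")
    else:
        raise ValueError("coil files must be 3-D or 4-D")
    ph = _rescale_phase(ph, phase_convention)
    return CoilStack(mag, ph, meta, stack_axis=stack_axis)


def save_coil_stack(stack: CoilStack, mag_path, phase_path) -> tuple:
    """Write a CoilStack as one multi-coil magnitude + one phase NIfTI."""
    return (
        save_array(stack.magnitude, mag_path, stack.meta),
        save_array(stack.phase, phase_path, stack.meta),
    )


def load_combined_coil_stack(
    mag_path, phase_path, meta: AcquisitionMeta, stack_axis: str | None = None,
    phase_convention: str = "radians",
) -> CoilStack:
    """Inverse of :func:`save_coil_stack` (coil axis already stacked)."""
    m = np.asarray(nib.load(str(mag_path)).dataobj, dtype=float)
    p = _rescale_phase(np.asarray(nib.load(str(phase_path)).dataobj, dtype=float),
                       phase_convention)
    return CoilStack(m, p, meta, stack_axis=stack_axis)
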