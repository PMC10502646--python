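"""Coil phase offsets and the FLASH readout ramp from the bipolar reference scan.

A triple-echo bipolar gradient-echo train with TEj = j*dTE lets both the
field term and the coil offsets be eliminated algebraically, with no
spatial unwrapping anywhere:

* ``2*theta2 - theta1 - theta3`` cancels field and offsets, leaving four
  times the alternating readout ramp — the ramp slope is then extracted in
  the complex domain from the lag-1 autocorrelation along the readout axis
  (exploiting the ramp's linearity), immune to voxelwise wrapping;
* ``2*theta1 - theta2`` cancels the field term (2*TE1 = TE2), leaving the
  wrapped offset plus three ramp units, which the estimated ramp removes.

Note the operand order: it is the first and second echoes in the 2:1
combination that cancel the field; combining them the other way round
leaves a residual ``3*dTE*field`` term and would make the offsets
shim-dependent.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .datamodel_io import (
    CoilStack,
    PhaseOffsetMap,
    ReadoutRamp,
    wrap_phase,
)

__all__ = [
    "estimate_theta_g_flash",
    "compute_phase_offsets",
    "resample_offsets_to_epi",
]

#: lag-1 validity bound: the autocorrelation angle is 4*slope per voxel step
SLOPE_LIMIT = np.pi / 4


def _check_reference(ref: CoilStack):
    if ref.stack_axis != "echo":
        raise ValueError("reference scan must carry an echo axis")
    if ref.n_stacked < 3 or ref.meta.n_echoes < 3:
        raise ValueError("offset estimation needs at least 3 bipolar echoes")
    ref.meta.delta_te  # raises on non-uniform spacing


def estimate_theta_g_flash(ref: CoilStack) -> ReadoutRamp:
    """Per-slice FLASH readout ramp slope (rad/voxel), unwrap-free.

    Forms ``exp(i*(2*theta2 - theta1 - theta3))`` voxelwise (field and
    offset terms cancel, leaving the ramp four-fold), combines coils with
    magnitude-squared weights, and reads the slope off the phase of the
    lag-1 autocorrelation along the readout axis divided by 4. Valid for
    |slope| < pi/4 rad/voxel; beyond that the lag-1 angle aliases (real
    ramps are two orders of magnitude smaller).
    """
    _check_reference(ref)
    th = ref.phase
    q = 2.0 * th[..., 1] - th[..., 0] - th[..., 2]
    w = ref.magnitude[..., 1] ** 2
    z = (w * np.exp(1j * q)).sum(axis=3)  # over coils -> (nx, ny, nz)
    lag1 = (z[1:] * np.conj(z[:-1])).sum(axis=(0, 1))  # per slice
    # sign convention: with a negative first lobe the combination is +4*ramp
    conv = 1.0 if ref.meta.first_lobe_negative else -1.0
    slopes = conv * np.angle(lag1) / 4.0
    return ReadoutRamp(slopes, sequence="FLASH")


def compute_phase_offsets(ref: CoilStack, ramp: ReadoutRamp) -> PhaseOffsetMap:
    """Wrapped per-coil phase offsets theta0_c at the reference resolution.

    ``theta0_c = wrap(2*theta1 - theta2 - 3*s1*ramp_phase)`` per coil, where
    s1 is the ramp sign of the first echo (so the correction is ``+3*ramp``
    under the default first-lobe-negative convention). Independent of the
    field, hence of any shim change between reference scan and EPI.
    """
    _check_reference(ref)
    if ramp.sequence != "FLASH":
        raise ValueError("offset removal needs the FLASH ramp")
    nz = ref.grid[2]
    ramp.slope_for_slices(nz)  # raises on slice-count mismatch
    th = ref.phase
    s1 = ref.meta.echo_ramp_sign(1)
    ramp_phase = ramp.phase(ref.grid)[..., None]
    theta0 = wrap_phase(2.0 * th[..., 0] - th[..., 1] - 3.0 * s1 * ramp_phase)
    return PhaseOffsetMap(theta0, meta=ref.meta, source_grid=ref.grid)


def resample_offsets_to_epi(off: PhaseOffsetMap, target_grid) -> PhaseOffsetMap:
    """Resample offsets to the EPI grid over the same FOV.

    Interpolation is performed on the complex representation
    ``exp(i*theta0)`` — never on wrapped phase directly — and re-angled, so
    wraps cannot bleed across the interpolation stencil. Identical grids
    are the identity; a constant map survives any upsampling exactly.
    """
    target_grid = tuple(int(n) for n in target_grid)
    if len(target_grid) != 3:
        raise ValueError("target grid must be 3-D")
    src_grid = off.grid
    if src_grid == target_grid:
        return PhaseOffsetMap(off.offsets.copy(), meta=off.meta,
                              source_grid=src_grid)
    # voxel-centre aligned coordinates for a shared FOV
    coords = np.meshgrid(*[
        (np.arange(nt) + 0.5) * ns / nt - 0.5
        for ns, nt in zip(src_grid, target_grid)
    ], indexing="ij")
    coords = np.stack(coords)
    z = np.exp(1j * off.offsets)
    out = np.empty(target_grid + (off.n_coils,))
    for c in range(off.n_coils):
        re = ndimage.map_coordinates(z[..., c].real, coords, order=1,
                                     mode="nearest")
        im = ndimage.map_coordinates(z[..., c].imag, coords, order=1,
                                     mode="nearest")
        out[..., c] = np.angle(re + 1j * im)
    return PhaseOffsetMap(wrap_phase(out), meta=off.meta, source_grid=src_grid)
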