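"""Offset-removed EPI coil combination, EPI readout ramp, k-space centring.

The EPI readout ramp is measured once per run from a pair of volumes with
opposite readout polarity (the readout-reversed calibration volume and the
first regular volume): their offset-removed phase difference is twice the
ramp, with the field contribution cancelling because both volumes see the
same distortion (same PE polarity — a PE-reversed pair is refused, since
its volumes are differently distorted and voxelwise subtraction is
invalid).

Sign convention: ``estimate_phi_g_epi(regular, reversed)`` returns the
ramp *of the regular-polarity volumes*, and the field-map stage subtracts
its ramp phase from the combined EPI phase. Self-consistency of this
convention is enforced by simulator round-trip tests rather than trusting
any printed operand order.
"""

from __future__ import annotations

import numpy as np

from .datamodel_io import (
    CoilStack,
    PhaseOffsetMap,
    ReadoutRamp,
    Volume,
    readout_coordinate,
    wrap_phase,
)

__all__ = [
    "combine_coils_remove_offsets",
    "estimate_phi_g_epi",
    "kspace_center_shift",
]


def combine_coils_remove_offsets(epi: CoilStack, off: PhaseOffsetMap):
    """Magnitude-squared-weighted coil combination with offsets removed.

    theta' = angle( sum_c M_c^2 * exp(i*(theta_c - theta0_c)) )

    Returns the wrapped combined phase and the combined magnitude
    ``sum_c M_c^2`` (kept for weighting and quality computation).
    """
    if epi.stack_axis is not None:
        raise ValueError("combine one volume at a time (4-D CoilStack)")
    if epi.grid != off.grid:
        raise ValueError("offsets are not on the EPI grid")
    if epi.n_coils != off.n_coils:
        raise ValueError("coil count mismatch between EPI and offsets")
    z = (epi.magnitude ** 2 * np.exp(1j * (epi.phase - off.offsets))).sum(axis=3)
    phase = Volume(wrap_phase(np.angle(z)), kind="phase", meta=epi.meta)
    mag = Volume((epi.magnitude ** 2).sum(axis=3), kind="magnitude",
                 meta=epi.meta)
    return phase, mag


def estimate_phi_g_epi(vol_regular: Volume, vol_reversed: Volume,
                       mag: Volume, mode: str = "linear") -> ReadoutRamp:
    """EPI readout ramp from an opposite-readout-polarity volume pair.

    Both volumes must be coil-combined with offsets removed and share the
    PE polarity. The voxelwise half phase-difference equals the ramp of the
    regular volume; ``mode="linear"`` (default) fits one scalar slope per
    slice via the magnitude-weighted lag-1 autocorrelation along readout
    (robust to a small uniform field change between the two volumes, which
    shifts all lag-1 phases equally and cancels in the autocorrelation
    product); ``mode="map"`` keeps the per-voxel half-angle for
    diagnostics. Antisymmetric: swapping the inputs negates the slope.
    """
    for v in (vol_regular, vol_reversed):
        if v.values.shape != mag.values.shape:
            raise ValueError("volume/magnitude grids differ")
    m_reg = vol_regular.meta
    m_rev = vol_reversed.meta
    if (m_reg is not None and m_rev is not None
            and m_reg.pe_polarity != m_rev.pe_polarity):
        raise ValueError(
            "volumes declare opposite PE polarity: their distortions differ "
            "and voxelwise subtraction is invalid")
    if mode not in ("linear", "map"):
        raise ValueError("mode must be 'linear' or 'map'")
    d = np.exp(1j * (vol_regular.values - vol_reversed.values))
    z = mag.values * d
    lag1 = (z[1:] * np.conj(z[:-1])).sum(axis=(0, 1))
    slopes = np.angle(lag1) / 2.0
    per_voxel = None
    if mode == "map":
        per_voxel = np.angle(d) / 2.0
    return ReadoutRamp(slopes, sequence="EPI", per_voxel_map=per_voxel)


def kspace_center_shift(img: CoilStack):
    """Detect and correct an off-centre echo along the readout axis.

    Per slice: the complex data of every coil is Fourier-transformed to
    k-space, interpolated to 2*RO+1 samples along readout, readout lines
    are summed in magnitude over PE and coils, and the offset of the summed
    profile's maximum from the k-space centre is found. All lines are then
    shifted by that (integer, on the interpolated axis) offset — applied
    equivalently as the corresponding linear phase ramp in image space, so
    the magnitude is untouched — giving half-voxel shift resolution on the
    original grid.

    Returns ``(shifts, corrected)``: per-slice echo shifts in original
    k-space sample units (multiples of 0.5) and the corrected CoilStack.
    """
    if img.stack_axis is not None:
        raise ValueError("centre one volume at a time (4-D CoilStack)")
    nx, ny, nz = img.grid
    c = img.complex()
    x = readout_coordinate(nx)
    # fine k-space readout frequencies: 2*RO+1 samples at half-sample spacing
    kappa = 0.5 * (np.arange(2 * nx + 1) - nx)
    dft = np.exp(-1j * 2 * np.pi * np.outer(kappa, x) / nx)  # (2nx+1, nx)
    shifts = np.empty(nz)
    corrected = np.empty_like(c)
    for z in range(nz):
        sl = np.fft.fft(c[:, :, z, :], axis=1)  # PE transform -> ky lines
        fine = np.einsum("kx,xyc->kyc", dft, sl)
        profile = np.abs(fine).sum(axis=(1, 2))
        offset_fine = int(profile.argmax()) - nx  # integer, fine-axis units
        shift = offset_fine / 2.0  # original k-space samples
        shifts[z] = shift
        # shifting every k-space line by -offset == removing the image ramp
        corr = np.exp(-1j * 2 * np.pi * shift * x / nx)[:, None, None]
        corrected[:, :, z, :] = c[:, :, z, :] * corr
    out = CoilStack(np.abs(corrected), wrap_phase(np.angle(corrected)),
                    img.meta, None)
    return shifts, out
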