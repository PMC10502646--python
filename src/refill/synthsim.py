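"""Forward simulator for multi-coil FLASH reference and EPI phase data.

Produces everything the dynamic field-mapping pipeline consumes — a
triple-echo bipolar FLASH reference scan, readout-reversed and regular EPI
volumes, and dynamic EPI time series — together with the ground truth
(fields, coil phase offsets, readout ramp slopes, voxel shift maps), so the
whole chain is testable without any acquired data.

Signal model (image space; no k-space effects):

* FLASH echo j (1-based):  theta_jc = wrap(TE_j*w + theta0_c + s_j*G_F*x)
  with w the field in rad/s, s_j the alternating readout-lobe sign and
  G_F the FLASH readout ramp slope (rad/voxel), x measured from the array
  centre.
* EPI: geometric forward displacement along PE by w/(2*pi*bw) voxels; the
  phase model samples the field at the displaced location (phase and
  displacement are consistent):  theta_c = wrap(TE*w_d + theta0_c + p*G_E*x)
  with p the readout polarity. The coil sensitivity is applied at the
  rendered (distorted) location — a documented simplification.
* Noise: i.i.d. complex Gaussian per coil added to real/imaginary parts
  before the magnitude/phase split (Rician magnitude emerges naturally).

Dynamic field modulators emulate the regimes reported for 7 T fMRI: drift,
~1 Hz-scale respiration, a motion-like regional perturbation of a few Hz,
and shim steps of up to +/-80 Hz at the FOV edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage

from .datamodel_io import (
    AcquisitionMeta,
    CoilStack,
    TWO_PI,
    Volume,
    readout_coordinate,
    wrap_phase,
)
from .unwarp import apply_vsm

__all__ = [
    "FieldSpec",
    "GroundTruth",
    "layered_phantom",
    "grid_phantom",
    "make_coil_sensitivities",
    "static_field",
    "make_field",
    "consistent_vsm",
    "simulate_flash_reference",
    "simulate_epi_volume",
    "simulate_timeseries",
    "default_flash_meta",
    "default_epi_meta",
    "noise_sd_for_snr",
]


def _norm_coords(grid):
    """Normalized coordinates in [-1, 1] per axis, broadcastable 3-D arrays."""
    out = []
    for a, n in enumerate(grid):
        c = (np.arange(n) - (n - 1) / 2.0) / max((n - 1) / 2.0, 1.0)
        shape = [1, 1, 1]
        shape[a] = n
        out.append(c.reshape(shape))
    return out


def default_flash_meta(delta_te: float = 2.5e-3, **kw) -> AcquisitionMeta:
    """Triple-echo bipolar FLASH protocol metadata (TEs 2.5/5/7.5 ms style)."""
    return AcquisitionMeta(echo_times=(delta_te, 2 * delta_te, 3 * delta_te), **kw)


def default_epi_meta(te: float = 22e-3, pe_bandwidth_per_pixel: float = 25.0,
                     **kw) -> AcquisitionMeta:
    return AcquisitionMeta(echo_times=(te,),
                           pe_bandwidth_per_pixel=pe_bandwidth_per_pixel, **kw)


# ---------------------------------------------------------------------------
# Phantoms and coils
# ---------------------------------------------------------------------------

def layered_phantom(grid=(64, 64, 8), smooth_sigma: float = 1.0) -> np.ndarray:
    """Layered ellipsoid phantom with interior structure, intensity ~1."""
    ux, uy, uz = _norm_coords(grid)
    r2 = (ux / 0.80) ** 2 + (uy / 0.85) ** 2 + (uz / 0.95) ** 2
    obj = np.zeros(grid)
    obj[r2 <= 1.0] = 1.0
    inner = (ux / 0.45) ** 2 + (uy / 0.50) ** 2 + (uz / 0.70) ** 2
    obj[inner <= 1.0] = 0.7
    ring = (r2 > 0.45) & (r2 <= 0.62)
    obj[ring] = 1.3
    if smooth_sigma > 0:
        obj = ndimage.gaussian_filter(obj, smooth_sigma)
    return np.clip(obj, 0.0, None)


def grid_phantom(grid=(64, 64, 8), spacing: int = 5) -> np.ndarray:
    """Grid of unit-intensity lines traversing the readout axis at fixed
    PE intervals (the distortion-visualisation phantom)."""
    obj = np.zeros(grid)
    obj[:, spacing::spacing, :] = 1.0
    return obj


def make_coil_sensitivities(grid=(64, 64, 8), n_coils: int = 8,
                            smoothness: float = 1.0, seed: int = 0):
    """Smooth complex receive sensitivities and the derived phase offsets.

    Coils sit on a circle around the object in the x-y plane with Gaussian
    magnitude falloff; each coil's phase is a random low-order (<=2)
    polynomial whose coefficient scale is ``smoothness`` (rad across the
    half-FOV). ``smoothness=0`` gives spatially constant phases. A single
    coil is treated as a uniform (body-coil-like) magnitude.

    Returns ``(sens, theta0)`` with ``sens`` complex (nx, ny, nz, n_coils)
    and ``theta0 = wrap(angle(sens))``.
    """
    if n_coils < 1:
        raise ValueError("n_coils must be >= 1")
    rng = np.random.default_rng(seed)
    ux, uy, uz = _norm_coords(grid)
    sens = np.empty(grid + (n_coils,), dtype=complex)
    for c in range(n_coils):
        ang = 2 * np.pi * c / n_coils
        cx, cy = 1.3 * np.cos(ang), 1.3 * np.sin(ang)
        if n_coils == 1:
            mag = np.ones(grid)
        else:
            d2 = (ux - cx) ** 2 + (uy - cy) ** 2 + (0.5 * uz) ** 2
            mag = 0.05 + np.exp(-d2 / (2 * 0.85 ** 2))
        a0 = rng.uniform(-np.pi, np.pi)
        lin = rng.normal(0.0, smoothness, size=3)
        quad = rng.normal(0.0, 0.5 * smoothness, size=3)
        ph = (a0 + lin[0] * ux + lin[1] * uy + lin[2] * uz
              + quad[0] * ux ** 2 + quad[1] * uy ** 2 + quad[2] * uz ** 2)
        sens[..., c] = mag * np.exp(1j * (ph + np.zeros(grid)))
    theta0 = wrap_phase(np.angle(sens))
    return sens, theta0


# ---------------------------------------------------------------------------
# Fields
# ---------------------------------------------------------------------------

@dataclass
class FieldSpec:
    """Static field plus per-volume modulators, all in rad/s.

    Spatial terms use normalized coordinates in [-1, 1]:

    * ``uniform`` + ``linear`` (3,) + ``quadratic`` (3,) static polynomial;
    * ``blobs``: local dipole-like Gaussian bumps
      ``(centre_frac(3), width_frac, amplitude_rad_s)``;
    * ``drift``: rad/s added per volume index;
    * ``resp_amplitude``/``resp_period``: global respiration sinusoid
      (period in volumes);
    * ``shim_step_*``: uniform + linear step applied from ``shim_step_volume``
      onwards (emulates a sudden shim/position change);
    * ``motion_*``: regional Gaussian-weighted sinusoid (the field effect of
      periodic limb/head motion; an emulation, not a reproduction of any
      particular movement).
    """

    uniform: float = 0.0
    linear: tuple = (0.0, 0.0, 0.0)
    quadratic: tuple = (0.0, 0.0, 0.0)
    blobs: tuple = ()
    drift: float = 0.0
    resp_amplitude: float = 0.0
    resp_period: float = 10.0
    shim_step_volume: int | None = None
    shim_step_uniform: float = 0.0
    shim_step_linear: tuple = (0.0, 0.0, 0.0)
    motion_amplitude: float = 0.0
    motion_period: float = 12.0
    motion_center: tuple = (0.5, -0.5, 0.0)
    motion_width: float = 0.4


def _gaussian_blob(grid, center_frac, width_frac):
    ux, uy, uz = _norm_coords(grid)
    d2 = ((ux - center_frac[0]) ** 2 + (uy - center_frac[1]) ** 2
          + (uz - center_frac[2]) ** 2)
    return np.exp(-d2 / (2 * width_frac ** 2))


def static_field(grid, spec: FieldSpec) -> np.ndarray:
    ux, uy, uz = _norm_coords(grid)
    f = np.full(grid, float(spec.uniform))
    f += spec.linear[0] * ux + spec.linear[1] * uy + spec.linear[2] * uz
    f += (spec.quadratic[0] * ux ** 2 + spec.quadratic[1] * uy ** 2
          + spec.quadratic[2] * uz ** 2)
    for center, width, amp in spec.blobs:
        f += amp * _gaussian_blob(grid, center, width)
    return f


def make_field(grid, spec: FieldSpec, n_volumes: int, seed: int | None = None
               ) -> np.ndarray:
    """Per-volume true field (rad/s), shape (nx, ny, nz, n_volumes).

    Volume 0 equals the static component; modulators are additive per
    volume. Fully deterministic given the spec (the seed argument is kept
    for interface symmetry with the stochastic operations and is unused:
    every modulator is parametric).
    """
    base = static_field(grid, spec)
    ux, uy, uz = _norm_coords(grid)
    step_spatial = (spec.shim_step_uniform
                    + spec.shim_step_linear[0] * ux
                    + spec.shim_step_linear[1] * uy
                    + spec.shim_step_linear[2] * uz)
    motion_spatial = (spec.motion_amplitude
                      * _gaussian_blob(grid, spec.motion_center, spec.motion_width))
    out = np.empty(grid + (n_volumes,))
    for t in range(n_volumes):
        f = base + spec.drift * t
        if spec.resp_amplitude:
            f = f + spec.resp_amplitude * np.sin(TWO_PI * t / spec.resp_period)
        if spec.shim_step_volume is not None and t >= spec.shim_step_volume:
            f = f + step_spatial
        if spec.motion_amplitude:
            f = f + motion_spatial * np.sin(TWO_PI * t / spec.motion_period)
        out[..., t] = f
    return out


# ---------------------------------------------------------------------------
# Acquisition forward models
# ---------------------------------------------------------------------------

def _ramp_phase(grid, slope: float) -> np.ndarray:
    x = readout_coordinate(grid[0])[:, None, None]
    return np.broadcast_to(slope * x, grid)


def _add_noise(cplx: np.ndarray, noise_sd: float, rng) -> np.ndarray:
    if noise_sd <= 0:
        return cplx
    return (cplx
            + rng.normal(0.0, noise_sd, cplx.shape)
            + 1j * rng.normal(0.0, noise_sd, cplx.shape))


def _to_coilstack(cplx: np.ndarray, meta, stack_axis) -> CoilStack:
    return CoilStack(np.abs(cplx), wrap_phase(np.angle(cplx)), meta, stack_axis)


def noise_sd_for_snr(obj: np.ndarray, sens: np.ndarray, snr: float) -> float:
    """Complex-noise sd giving the requested per-coil magnitude SNR inside
    the object (mean per-coil magnitude / sd)."""
    inside = obj > 0.1 * obj.max()
    mags = (obj[..., None] * np.abs(sens))[inside]
    return float(mags.mean() / snr)


def simulate_flash_reference(obj, sens, field, meta: AcquisitionMeta,
                             phi_g_flash: float = 0.0, noise_sd: float = 0.0,
                             seed: int = 0) -> CoilStack:
    """Triple-echo bipolar FLASH reference scan (echo axis last).

    FLASH is treated as distortion-free (high PE bandwidth). Echo j's ramp
    sign follows the bipolar convention in ``meta``.
    """
    if meta.n_echoes < 3:
        raise ValueError("the offset calculation needs at least 3 echoes")
    meta.delta_te  # raises if spacing is non-uniform
    grid = obj.shape
    rng = np.random.default_rng(seed)
    ramp = _ramp_phase(grid, phi_g_flash)
    echoes = []
    for j, te in enumerate(meta.echo_times, start=1):
        ph = (te * field)[..., None] + np.angle(sens) \
            + (meta.echo_ramp_sign(j) * ramp)[..., None]
        cplx = obj[..., None] * np.abs(sens) * np.exp(1j * ph)
        echoes.append(_add_noise(cplx, noise_sd, rng))
    return _to_coilstack(np.stack(echoes, axis=-1), meta, "echo")


def consistent_vsm(field: np.ndarray, meta: AcquisitionMeta,
                   n_iter: int = 15) -> np.ndarray:
    """Voxel shift map in distorted space, self-consistent with the field.

    Solves the fixed point s(y) = p * w(y - s(y)) / (2*pi*bw) so that the
    displaced magnitude and the field sampled by the phase model agree
    exactly with what a real EPI acquires.
    """
    if meta.pe_bandwidth_per_pixel is None:
        raise ValueError("pe_bandwidth_per_pixel required")
    s0 = meta.pe_polarity * field / (TWO_PI * meta.pe_bandwidth_per_pixel)
    vol0 = Volume(s0, kind="vsm_voxels")
    s = s0.copy()
    for _ in range(n_iter):
        warped = apply_vsm(vol0, Volume(s, kind="vsm_voxels"),
                           direction="warp", fill="edge")
        s = warped.values
    return s


def simulate_epi_volume(obj, sens, field, meta: AcquisitionMeta,
                        phi_g_epi: float = 0.0, readout_polarity: int = 1,
                        noise_sd: float = 0.0, seed: int = 0,
                        return_truth: bool = False):
    """Single-echo EPI volume with PE-direction geometric distortion.

    The object magnitude is forward-warped along PE by the self-consistent
    voxel shift map; the phase samples the field at the distorted location;
    the readout ramp carries ``readout_polarity`` (+1 regular, -1 for the
    readout-reversed calibration volume).
    """
    grid = obj.shape
    rng = np.random.default_rng(seed)
    te = meta.echo_times[0]
    vsm = consistent_vsm(field, meta)
    svol = Volume(vsm, kind="vsm_voxels")
    obj_d = apply_vsm(Volume(obj, kind="magnitude"), svol,
                      direction="warp", fill=0.0).values
    field_d = apply_vsm(Volume(field, kind="fieldmap_rad_s"), svol,
                        direction="warp", fill="edge").values
    ramp = _ramp_phase(grid, phi_g_epi)
    ph = (te * field_d + readout_polarity * ramp)[..., None] + np.angle(sens)
    cplx = obj_d[..., None] * np.abs(sens) * np.exp(1j * ph)
    cplx = _add_noise(cplx, noise_sd, rng)
    stack = _to_coilstack(cplx, meta.with_(readout_polarity=readout_polarity),
                          None)
    if return_truth:
        return stack, field_d, vsm
    return stack


@dataclass
class GroundTruth:
    """Known truth accompanying a simulated time series (test oracle)."""

    fields: np.ndarray            # (nx, ny, nz, nt), undistorted space, rad/s
    fields_distorted: np.ndarray  # same, sampled in distorted space
    vsm: np.ndarray               # (nx, ny, nz, nt) true shifts, voxels
    theta0: np.ndarray            # (nx, ny, nz, n_coils) wrapped offsets
    phi_g_flash: float = 0.0      # rad/voxel
    phi_g_epi: float = 0.0        # rad/voxel
    object: np.ndarray | None = None
    sens: np.ndarray | None = None
    reversed_first: bool = True


def simulate_timeseries(obj, sens, fieldspec: FieldSpec,
                        meta: AcquisitionMeta, n_volumes: int,
                        phi_g_epi: float = 0.0, noise_sd: float = 0.0,
                        seed: int = 0, reversed_first: bool = True):
    """EPI time series; volume 0 is the readout-reversed calibration volume.

    Returns ``(CoilStack with a time axis, GroundTruth)``. All randomness is
    determined by (parameters, seed); per-volume noise streams are spawned
    from the seed.
    """
    if n_volumes < 2:
        raise ValueError("need at least 2 volumes (calibration + series)")
    grid = obj.shape
    fields = make_field(grid, fieldspec, n_volumes)
    seeds = np.random.SeedSequence(seed).generate_state(n_volumes) % (2 ** 31)
    mags, phases = [], []
    fields_d = np.empty_like(fields)
    vsms = np.empty_like(fields)
    for t in range(n_volumes):
        pol = -1 if (t == 0 and reversed_first) else 1
        stack, fd, vsm = simulate_epi_volume(
            obj, sens, fields[..., t], meta, phi_g_epi=phi_g_epi,
            readout_polarity=pol, noise_sd=noise_sd, seed=int(seeds[t]),
            return_truth=True)
        mags.append(stack.magnitude)
        phases.append(stack.phase)
        fields_d[..., t] = fd
        vsms[..., t] = vsm
    series = CoilStack(np.stack(mags, axis=-1), np.stack(phases, axis=-1),
                       meta, "time")
    truth = GroundTruth(fields=fields, fields_distorted=fields_d, vsm=vsms,
                        theta0=wrap_phase(np.angle(sens)),
                        phi_g_epi=phi_g_epi, object=obj, sens=sens,
                        reversed_first=reversed_first)
    return series, truth
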