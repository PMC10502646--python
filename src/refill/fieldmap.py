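"""Dynamic field-map assembly, filtering, smoothing and the full pipeline.

The canonical field-map unit is rad/s (angular frequency offset): the
masking range filter is defined in rad/s, and converters to Hz and Tesla
live in :mod:`refill.datamodel_io`. A single-echo field map is the
spatially-unwrapped, ramp-corrected combined EPI phase divided by TE.

Because spatial unwrapping fixes phase only up to one global multiple of
2*pi per volume (per connected component), each map is anchored
temporally: volume 1 is shifted by the multiple of 2*pi/TE that brings its
masked median closest to zero (the usual near-zero-mean-field assumption),
and every later volume to the multiple closest to volume 1's median. A
uniform field component is therefore only determined modulo 2*pi/TE
(~286 rad/s at TE = 22 ms) — an inherent limit of single-echo mapping, not
of the implementation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .datamodel_io import (
    AcquisitionMeta,
    CoilStack,
    PhaseOffsetMap,
    ReadoutRamp,
    TWO_PI,
    Volume,
    wrap_phase,
)
from .epiphase import combine_coils_remove_offsets, estimate_phi_g_epi
from .refscan import compute_phase_offsets, estimate_theta_g_flash, \
    resample_offsets_to_epi
from .unwrap import compute_quality_map, mask_from_quality, unwrap_spatial
from .unwarp import apply_vsm, fieldmap_to_vsm

__all__ = [
    "FieldMapSeries",
    "refill_fieldmap",
    "refill_series",
    "flash_fieldmap",
    "filter_fieldmap",
    "smooth_fieldmap",
    "run_refill_pipeline",
    "PipelineResult",
]

#: masking range for EPI-based field maps, rad/s
FILTER_LO = -600.0
FILTER_HI = 2000.0


@dataclass
class FieldMapSeries:
    """Per-volume field maps (rad/s) sharing one mask.

    ``fields`` is (nx, ny, nz, nt) with NaN outside the mask; ``ramp`` and
    ``offsets`` record the calibration actually used (provenance).
    """

    fields: np.ndarray
    mask: Volume
    quality: Volume
    meta: AcquisitionMeta
    ramp: ReadoutRamp | None = None
    offsets: PhaseOffsetMap | None = None

    @property
    def n_volumes(self) -> int:
        return self.fields.shape[3]

    def volume(self, t: int) -> Volume:
        return Volume(self.fields[..., t], kind="fieldmap_rad_s", meta=self.meta)


def _anchor(fm: np.ndarray, mask: np.ndarray, period: float,
            ref_median: float) -> np.ndarray:
    med = np.nanmedian(fm[mask])
    k = np.rint((ref_median - med) / period)
    return fm + k * period


def refill_fieldmap(theta_t: Volume, ramp: ReadoutRamp, mask: Volume,
                    quality: Volume, meta: AcquisitionMeta,
                    ref_median: float = 0.0) -> Volume:
    """Field map (rad/s) from one combined, offset-removed EPI phase volume.

    The regular-volume readout ramp is subtracted, the result is spatially
    unwrapped within the mask (quality-guided), divided by TE_EPI, and the
    global 2*pi/TE ambiguity is resolved by shifting the masked median as
    close as possible to ``ref_median``. NaN outside the mask.
    """
    te = meta.echo_times[0] if meta.echo_times else 0.0
    if te <= 0:
        raise ValueError("TE_EPI must be positive")
    corrected = Volume(wrap_phase(theta_t.values - ramp.phase(theta_t.values.shape)),
                       kind="phase", meta=meta)
    unwrapped, _ = unwrap_spatial(corrected, quality, mask)
    fm = unwrapped.values / te
    m = mask.values.astype(bool)
    fm = _anchor(fm, m, TWO_PI / te, ref_median)
    fm = np.where(m, fm, np.nan)
    return Volume(fm, kind="fieldmap_rad_s", meta=meta)


def refill_series(series: CoilStack, off: PhaseOffsetMap,
                  meta: AcquisitionMeta | None = None,
                  quality_threshold: float = 0.5,
                  reversed_first: bool = True,
                  mask_per_volume: bool = False) -> FieldMapSeries:
    """Dynamic field-map series from an EPI time series.

    Volume 0 must be the readout-reversed calibration volume; the EPI ramp
    is estimated from volumes (1, 0), and a field map is produced for every
    regular volume t >= 1. One quality map and mask are derived from
    volume 1 and reused for the whole run unless ``mask_per_volume``.
    Range filtering and smoothing are separate, optional steps
    (:func:`filter_fieldmap`, :func:`smooth_fieldmap`).
    """
    if series.stack_axis != "time":
        raise ValueError("expected a CoilStack with a time axis")
    if series.n_stacked < 2:
        raise ValueError("need at least 2 volumes")
    if not reversed_first:
        raise ValueError(
            "the readout-reversed calibration volume must be volume 0; "
            "acquire one (readout polarity reversed) or reorder the series")
    meta = meta or series.meta
    te = meta.echo_times[0]

    theta_rev, mag_rev = combine_coils_remove_offsets(series.volume(0), off)
    theta_1, mag_1 = combine_coils_remove_offsets(series.volume(1), off)
    ramp = estimate_phi_g_epi(theta_1, theta_rev, mag_1)

    quality = compute_quality_map(theta_1, mag_1)
    mask = mask_from_quality(quality, quality_threshold)

    nt = series.n_stacked
    fields = np.empty(series.grid + (nt - 1,))
    ref_median = 0.0
    for t in range(1, nt):
        if t == 1:
            theta_t, mag_t = theta_1, mag_1
        else:
            theta_t, mag_t = combine_coils_remove_offsets(series.volume(t), off)
        if mask_per_volume and t > 1:
            q_t = compute_quality_map(theta_t, mag_t)
            m_t = mask_from_quality(q_t, quality_threshold)
        else:
            q_t, m_t = quality, mask
        fm = refill_fieldmap(theta_t, ramp, m_t, q_t, meta,
                             ref_median=ref_median)
        if t == 1:
            ref_median = float(np.nanmedian(fm.values[mask.values.astype(bool)]))
        fields[..., t - 1] = fm.values
    return FieldMapSeries(fields=fields, mask=mask, quality=quality,
                          meta=meta, ramp=ramp, offsets=off)


def flash_fieldmap(ref: CoilStack, echo_a: int = 1, echo_b: int = 3,
                   quality_threshold: float = 0.5,
                   mask: Volume | None = None) -> Volume:
    """Static reference field map from the Hermitian product of two echoes.

    angle( sum_c M_b * M_a * exp(i*(theta_b - theta_a)) ), spatially
    unwrapped and divided by TE_b - TE_a, in rad/s. The two echoes must
    share the readout polarity (e.g. 1 and 3 of a bipolar train) so the
    ramp cancels in the difference; otherwise the call is refused.
    """
    if ref.stack_axis != "echo":
        raise ValueError("reference scan must carry an echo axis")
    m = ref.meta
    if echo_a < 1 or echo_b < 1 or echo_b > m.n_echoes or echo_a > m.n_echoes:
        raise ValueError("echo index out of range")
    if m.echo_ramp_sign(echo_a) != m.echo_ramp_sign(echo_b):
        raise ValueError(
            "echoes of opposite readout polarity selected: the readout ramp "
            "would not cancel in the Hermitian product")
    dte = m.echo_times[echo_b - 1] - m.echo_times[echo_a - 1]
    if dte <= 0:
        raise ValueError("echo_b must be later than echo_a")
    ma = ref.magnitude[..., echo_a - 1]
    mb = ref.magnitude[..., echo_b - 1]
    dphi = ref.phase[..., echo_b - 1] - ref.phase[..., echo_a - 1]
    z = (mb * ma * np.exp(1j * dphi)).sum(axis=3)
    phase = Volume(wrap_phase(np.angle(z)), kind="phase", meta=m)
    magv = Volume(np.abs(z), kind="magnitude", meta=m)
    quality = compute_quality_map(phase, magv)
    if mask is None:
        mask = mask_from_quality(quality, quality_threshold)
    unwrapped, _ = unwrap_spatial(phase, quality, mask)
    fm = unwrapped.values / dte
    mbool = mask.values.astype(bool)
    fm = _anchor(fm, mbool, TWO_PI / dte, 0.0)
    return Volume(np.where(mbool, fm, np.nan), kind="fieldmap_rad_s", meta=m)


def filter_fieldmap(fm: Volume, lo: float = FILTER_LO,
                    hi: float = FILTER_HI) -> Volume:
    """Set field values outside (lo, hi) rad/s to the NaN sentinel."""
    if lo >= hi:
        raise ValueError("lo must be < hi")
    v = fm.values.copy()
    with np.errstate(invalid="ignore"):
        bad = (v <= lo) | (v >= hi)
    v[bad] = np.nan
    return Volume(v, kind="fieldmap_rad_s", meta=fm.meta)


def smooth_fieldmap(fm: Volume, sigma_voxels: float = 2.0,
                    max_iter: int = 50) -> Volume:
    """Missing-aware Gaussian smoothing (normalized convolution).

    ``smoothed = G*(fm*valid) / G*(valid)``; NaN voxels are omitted from
    the kernel and receive the smoothed estimate, iterating until every
    voxel is filled (holes far from data fill in later iterations). A
    constant map with holes is restored exactly; ``sigma=0`` is the
    identity on finite voxels.
    """
    v = fm.values
    if not np.isfinite(v).any():
        raise ValueError("field map has no finite voxels")
    if sigma_voxels == 0:
        return Volume(v.copy(), kind="fieldmap_rad_s", meta=fm.meta)
    out = np.full(v.shape, np.nan)
    src = v.copy()
    for _ in range(max_iter):
        valid = np.isfinite(src)
        num = ndimage.gaussian_filter(np.where(valid, src, 0.0), sigma_voxels)
        den = ndimage.gaussian_filter(valid.astype(float), sigma_voxels)
        with np.errstate(invalid="ignore", divide="ignore"):
            sm = np.where(den > 1e-8, num / np.where(den > 0, den, 1.0), np.nan)
        if np.isnan(out).all():
            out = sm
        else:
            out = np.where(np.isnan(out), sm, out)
        if np.isfinite(out).all():
            break
        src = out
    return Volume(out, kind="fieldmap_rad_s", meta=fm.meta)


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineResult:
    fieldmaps: FieldMapSeries
    corrected: np.ndarray     # (nx, ny, nz, nt-1) unwarped magnitude series
    vsm: np.ndarray           # (nx, ny, nz, nt-1) shift maps used
    uncorrected: np.ndarray   # (nx, ny, nz, nt-1) distorted magnitude series


def correct_timeseries(series: CoilStack, ref: CoilStack,
                       meta_epi: AcquisitionMeta | None = None,
                       quality_threshold: float = 0.5,
                       filter_lo: float = FILTER_LO,
                       filter_hi: float = FILTER_HI,
                       smooth_sigma: float | None = None,
                       mask_per_volume: bool = False) -> PipelineResult:
    """Full chain: offsets -> ramps -> combined phase -> field maps -> VSM
    -> unwarped magnitude series.

    ``smooth_sigma=None`` skips the smoothing step (noiseless data);
    real-data configurations enable it (sigma ~2 voxels). Deterministic:
    identical inputs give identical outputs.
    """
    meta_epi = meta_epi or series.meta
    flash_ramp = estimate_theta_g_flash(ref)
    off = compute_phase_offsets(ref, flash_ramp)
    if off.grid != series.grid:
        off = resample_offsets_to_epi(off, series.grid)
    fms = refill_series(series, off, meta_epi,
                        quality_threshold=quality_threshold,
                        mask_per_volume=mask_per_volume)
    nt = fms.n_volumes
    grid = series.grid
    corrected = np.empty(grid + (nt,))
    uncorrected = np.empty(grid + (nt,))
    vsms = np.empty(grid + (nt,))
    combined_mag = (series.magnitude ** 2).sum(axis=3)  # (x, y, z, t)
    for t in range(nt):
        fm = filter_fieldmap(fms.volume(t), filter_lo, filter_hi)
        if smooth_sigma is not None:
            fm = smooth_fieldmap(fm, smooth_sigma)
        vsm = fieldmap_to_vsm(fm, meta_epi)
        mag = Volume(np.sqrt(combined_mag[..., t + 1]), kind="magnitude",
                     meta=meta_epi)
        corrected[..., t] = apply_vsm(mag, vsm, direction="unwarp").values
        uncorrected[..., t] = mag.values
        vsms[..., t] = vsm.values
    return PipelineResult(fieldmaps=fms, corrected=corrected, vsm=vsms,
                          uncorrected=uncorrected)


def run_refill_pipeline(config) -> PipelineResult:
    """File-based pipeline entry point driven by a config mapping/YAML path.

    Required keys: ``reference`` (mag/phase NIfTI paths), ``series``
    (mag/phase NIfTI paths, volume 0 readout-reversed), ``flash_echo_times``
    (s), ``epi_te`` (s), ``pe_bandwidth_per_pixel`` (Hz/px). Optional:
    ``pe_polarity``, ``quality_threshold`` (0.5), ``filter_lo``/``filter_hi``
    (-600/2000 rad/s), ``smooth_sigma`` (voxels), ``out_dir``.
    """
    import logging
    import time
    from pathlib import Path

    from .datamodel_io import load_combined_coil_stack, save_array, save_volume

    if not isinstance(config, dict):
        import yaml
        with open(config) as fh:
            config = yaml.safe_load(fh)

    log = logging.getLogger("refill")
    t0 = time.time()
    meta_flash = AcquisitionMeta(
        echo_times=tuple(config["flash_echo_times"]),
        first_lobe_negative=config.get("first_lobe_negative", True))
    meta_epi = AcquisitionMeta(
        echo_times=(config["epi_te"],),
        pe_bandwidth_per_pixel=config["pe_bandwidth_per_pixel"],
        pe_polarity=config.get("pe_polarity", 1))
    ref = load_combined_coil_stack(config["reference"]["magnitude"],
                                   config["reference"]["phase"],
                                   meta_flash, stack_axis="echo")
    series = load_combined_coil_stack(config["series"]["magnitude"],
                                      config["series"]["phase"],
                                      meta_epi, stack_axis="time")
    log.info("loaded inputs in %.2fs", time.time() - t0)
    result = correct_timeseries(
        series, ref, meta_epi,
        quality_threshold=config.get("quality_threshold", 0.5),
        filter_lo=config.get("filter_lo", FILTER_LO),
        filter_hi=config.get("filter_hi", FILTER_HI),
        smooth_sigma=config.get("smooth_sigma"),
        mask_per_volume=config.get("mask_per_volume", False))
    log.info("pipeline done in %.2fs", time.time() - t0)
    out_dir = config.get("out_dir")
    if out_dir:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        save_array(result.fieldmaps.fields, out / "fieldmaps_rad_s.nii.gz",
                   meta_epi)
        save_volume(result.fieldmaps.mask, out / "mask.nii.gz")
        save_volume(result.fieldmaps.quality, out / "quality.nii.gz")
        save_array(result.vsm, out / "vsm_voxels.nii.gz", meta_epi)
        save_array(result.corrected, out / "corrected.nii.gz", meta_epi)
        log.info("wrote outputs to %s", out)
    return result
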