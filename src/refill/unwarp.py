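"""Voxel shift maps, 1-D unwarping along the phase-encode axis, and metrics.

EPI distortion is a per-voxel displacement along the phase-encode (PE)
axis equal to the local field offset in Hz divided by the PE bandwidth per
pixel. Correction here is purely geometric (FUGUE-style): 1-D linear
interpolation per PE column, no intensity Jacobian by default.
"""

from __future__ import annotations

import numpy as np

from .datamodel_io import AcquisitionMeta, TWO_PI, Volume

__all__ = [
    "fieldmap_to_vsm",
    "apply_vsm",
    "self_unwarp_fieldmap",
    "tsnr_map",
    "grid_phantom_residual",
]


def fieldmap_to_vsm(fm: Volume, meta: AcquisitionMeta) -> Volume:
    """Convert a field map (rad/s) to a voxel shift map along PE.

    shift = pe_polarity * fm / (2*pi * pe_bandwidth_per_pixel)  [voxels]

    NaN (out-of-mask) field values map to zero shift. Linear in the field.
    """
    if meta.pe_bandwidth_per_pixel is None:
        raise ValueError("pe_bandwidth_per_pixel is required for a VSM")
    shift = meta.pe_polarity * fm.values / (TWO_PI * meta.pe_bandwidth_per_pixel)
    shift = np.where(np.isfinite(shift), shift, 0.0)
    return Volume(shift, kind="vsm_voxels", meta=meta)


def _interp_pe(values: np.ndarray, coords: np.ndarray, fill) -> np.ndarray:
    """Linear interpolation of `values` along axis 1 at fractional `coords`.

    ``fill`` is a constant for out-of-FOV samples, or the string ``"edge"``
    to clamp to the boundary value.
    """
    ny = values.shape[1]
    if isinstance(fill, str):
        if fill != "edge":
            raise ValueError("fill must be a number or 'edge'")
        coords = np.clip(coords, 0, ny - 1)
    valid = (coords >= 0) & (coords <= ny - 1)
    y0c = np.clip(np.floor(coords).astype(int), 0, ny - 2)
    frac = coords - y0c
    a = np.take_along_axis(values, y0c, axis=1)
    b = np.take_along_axis(values, y0c + 1, axis=1)
    out = (1.0 - frac) * a + frac * b
    if isinstance(fill, str):
        return out
    return np.where(valid, out, fill)


def apply_vsm(img: Volume, vsm: Volume, direction: str = "unwarp",
              fill=np.nan, jacobian: bool = False) -> Volume:
    """Apply a voxel shift map along the PE axis by 1-D linear interpolation.

    ``unwarp`` samples the distorted image at ``y + shift(y)`` to recover the
    undistorted value; ``warp`` is the forward model ``y - shift(y)`` (used by
    the simulator and the grid-phantom evaluation). The two are approximate
    inverses for smooth shift maps. Samples falling outside the FOV become
    ``fill`` (NaN sentinel by default, so downstream statistics can exclude
    them). ``jacobian=True`` additionally modulates intensity by
    ``1 + d(shift)/dy`` in ``unwarp`` (off by default: geometric correction
    only).
    """
    if img.values.shape != vsm.values.shape:
        raise ValueError("image and VSM grids differ")
    if direction not in ("unwarp", "warp"):
        raise ValueError("direction must be 'unwarp' or 'warp'")
    sgn = 1.0 if direction == "unwarp" else -1.0
    ny = img.values.shape[1]
    base = np.arange(ny, dtype=float)[None, :, None]
    coords = base + sgn * vsm.values
    out = _interp_pe(img.values, coords, fill)
    if jacobian and direction == "unwarp":
        dsdy = np.gradient(vsm.values, axis=1)
        out = out * (1.0 + sgn * dsdy)
    return Volume(out, kind=img.kind, meta=img.meta)


def self_unwarp_fieldmap(fm: Volume, meta: AcquisitionMeta) -> Volume:
    """Bring a field map measured in distorted space to undistorted space.

    Single pass: the VSM is derived from the map itself and the map is then
    resampled with ``unwarp``. Adequate for shifts up to a few voxels; a
    uniform field is unchanged (uniform shift of a constant).
    """
    vsm = fieldmap_to_vsm(fm, meta)
    out = apply_vsm(Volume(fm.values, kind="fieldmap_rad_s", meta=meta), vsm,
                    direction="unwarp")
    return Volume(out.values, kind="fieldmap_rad_s", meta=meta)


def tsnr_map(series: np.ndarray, meta: AcquisitionMeta | None = None) -> Volume:
    """Temporal SNR: voxelwise temporal mean / temporal std (ddof=1).

    ``series`` is (nx, ny, nz, nt) with nt >= 3. Voxels with zero temporal
    std (e.g. a constant series) are flagged as NaN rather than infinity.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 4 or series.shape[3] < 3:
        raise ValueError("need a 4-D series with at least 3 volumes")
    valid = np.isfinite(series)
    n = valid.sum(axis=3)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(valid, series, 0.0).sum(axis=3) / np.maximum(n, 1)
        dev = np.where(valid, series - mean[..., None], 0.0)
        var = (dev ** 2).sum(axis=3) / np.maximum(n - 1, 1)
        std = np.sqrt(var)
        t = np.where((n >= 3) & (std > 0), mean / np.where(std > 0, std, 1.0),
                     np.nan)
    return Volume(t, kind="magnitude", meta=meta)


def _line_positions(grid: np.ndarray, min_rel_height: float = 0.25) -> np.ndarray:
    """Nominal PE positions of grid lines from the mean PE profile."""
    prof = np.nanmean(np.nan_to_num(grid), axis=(0, 2))
    thresh = min_rel_height * prof.max()
    peaks = [
        y for y in range(1, len(prof) - 1)
        if prof[y] >= thresh and prof[y] >= prof[y - 1] and prof[y] > prof[y + 1]
    ]
    return np.asarray(peaks, dtype=int)


def grid_phantom_residual(corrected_grid: np.ndarray, true_grid: np.ndarray,
                          window: int = 2) -> float:
    """RMS residual displacement (voxels) between two line-grid images.

    Lines traverse the readout axis at regular PE intervals. For every
    readout column and every line, the line position is located by the
    intensity centroid within ``window`` voxels of the nominal position;
    the result is the RMS over all (column, line) pairs of the centroid
    differences. Identical grids give 0; a rigid 1-voxel PE shift gives 1.
    """
    corrected_grid = np.nan_to_num(np.asarray(corrected_grid, dtype=float))
    true_grid = np.nan_to_num(np.asarray(true_grid, dtype=float))
    if corrected_grid.shape != true_grid.shape:
        raise ValueError("grid geometries differ")
    ny = true_grid.shape[1]
    lines = _line_positions(true_grid)
    diffs = []
    for y0 in lines:
        sl = slice(max(0, y0 - window), min(ny, y0 + window + 1))
        ys = np.arange(sl.start, sl.stop, dtype=float)[None, :, None]
        wt = true_grid[:, sl, :]
        wc = corrected_grid[:, sl, :]
        st, sc = wt.sum(axis=1), wc.sum(axis=1)
        ok = (st > 1e-9) & (sc > 1e-9)
        if not ok.any():
            continue
        ct = (wt * ys).sum(axis=1)[ok] / st[ok]
        cc = (wc * ys).sum(axis=1)[ok] / sc[ok]
        diffs.append(cc - ct)
    if not diffs:
        raise ValueError("no grid lines found")
    d = np.concatenate(diffs)
    return float(np.sqrt(np.mean(d ** 2)))
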