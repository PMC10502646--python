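"""Quality-guided spatial phase unwrapping and quality-threshold masking.

The unwrapper is path-based in the ROMEO style: a reliable seed voxel is
chosen from a voxelwise quality map, and region growing proceeds best-first
along the highest-quality edges, deciding at each step whether -1, 0 or +1
wraps separate a new voxel from its already-unwrapped neighbour. No
least-squares or Laplacian relaxation is involved, so the output is
congruent with the input modulo 2*pi at every voxel.

The edge quality combines phase coherence and magnitude similarity of the
two voxels it connects (a simplified single-echo weight):

    w = max(0, 1 - |wrap(dtheta)| / pi) * min(M_i, M_j) / max(M_i, M_j)

and the voxelwise quality map is the product of a voxel's edge weights.
"""

from __future__ import annotations

import heapq

import numpy as np
from scipy import ndimage

from .datamodel_io import TWO_PI, Volume, wrap_phase

__all__ = [
    "compute_quality_map",
    "edge_weights",
    "unwrap_spatial",
    "unwrap_1d_oracle",
    "mask_from_quality",
]


def _edge_weight(theta_a, theta_b, mag_a, mag_b):
    dphi = np.abs(wrap_phase(theta_b - theta_a))
    w_phase = np.maximum(0.0, 1.0 - dphi / np.pi)
    hi = np.maximum(mag_a, mag_b)
    lo = np.minimum(mag_a, mag_b)
    with np.errstate(invalid="ignore", divide="ignore"):
        w_mag = np.where(hi > 0, lo / np.where(hi > 0, hi, 1.0), 0.0)
    return w_phase * w_mag


def edge_weights(phase: np.ndarray, mag: np.ndarray) -> list:
    """Edge weights along each axis; weights[a] has axis ``a`` shortened by 1."""
    ws = []
    for a in range(phase.ndim):
        lo = [slice(None)] * phase.ndim
        hi = [slice(None)] * phase.ndim
        lo[a] = slice(None, -1)
        hi[a] = slice(1, None)
        ws.append(
            _edge_weight(phase[tuple(lo)], phase[tuple(hi)],
                         mag[tuple(lo)], mag[tuple(hi)])
        )
    return ws


def compute_quality_map(phase: Volume, mag: Volume) -> Volume:
    """Voxelwise reliability in [0, 1]: geometric mean of a voxel's edge weights.

    Boundary voxels use the neighbours they have. Constant phase over
    constant positive magnitude gives quality 1; random phase or signal
    voids drive it towards 0. The geometric mean (rather than the bare
    product) keeps the scale independent of the number of neighbours, so
    one 0.5 threshold behaves the same at faces, edges and interior.
    """
    th, m = phase.values, mag.values
    if th.shape != m.shape:
        raise ValueError("phase and magnitude grids differ")
    q = np.ones_like(th)
    n_edges = np.zeros_like(th)
    for a, w in enumerate(edge_weights(th, m)):
        lo = [slice(None)] * th.ndim
        hi = [slice(None)] * th.ndim
        lo[a] = slice(None, -1)
        hi[a] = slice(1, None)
        q[tuple(lo)] *= w
        q[tuple(hi)] *= w
        n_edges[tuple(lo)] += 1
        n_edges[tuple(hi)] += 1
    q = np.power(q, 1.0 / np.maximum(n_edges, 1))
    return Volume(np.clip(q, 0.0, 1.0), kind="quality", meta=phase.meta)


def unwrap_1d_oracle(phase_line: np.ndarray) -> np.ndarray:
    """Classical Itoh 1-D unwrapping: cumulative sum of wrapped differences.

    Exact whenever every true sample-to-sample increment is below pi in
    magnitude; above that bound aliasing is unavoidable (this is the
    oracle's documented validity domain, not a defect).
    """
    phase_line = np.asarray(phase_line, dtype=float)
    if phase_line.ndim != 1:
        raise ValueError("oracle is 1-D only")
    if phase_line.size == 0:
        return phase_line.copy()
    steps = wrap_phase(np.diff(phase_line))
    return phase_line[0] + np.concatenate([[0.0], np.cumsum(steps)])


def mask_from_quality(q: Volume, threshold: float = 0.5) -> Volume:
    """Binary mask: quality >= threshold, largest connected component kept.

    The component filter removes islands created by signal voids; with an
    empty thresholded set the mask is all-zero.
    """
    binary = np.asarray(q.values >= threshold)
    labels, n = ndimage.label(binary)
    if n == 0:
        return Volume(np.zeros(q.values.shape), kind="mask", meta=q.meta)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    keep = counts.argmax()
    return Volume((labels == keep).astype(float), kind="mask", meta=q.meta)


def unwrap_spatial(phase: Volume, quality: Volume, mask: Volume):
    """Quality-guided region-growing unwrap within a mask.

    Growing starts at the highest-quality masked voxel (ties: lowest linear
    index) and proceeds best-first on edge quality using a priority queue;
    each new voxel receives ``neighbour + wrap(theta_new - theta_neighbour)``.
    Disconnected mask components are unwrapped independently, each anchored
    to its own seed, so the result carries one free multiple of 2*pi per
    component.

    Returns
    -------
    (Volume, ndarray)
        The unwrapped phase (NaN outside the mask) and the integer
        wrap-count map ``n`` with ``unwrapped = theta + 2*pi*n``.
    """
    theta = phase.values
    q = quality.values
    m = mask.values.astype(bool)
    if theta.shape != q.shape or theta.shape != m.shape:
        raise ValueError("phase/quality/mask grids differ")
    if not m.any():
        raise ValueError("mask is empty")

    shape = theta.shape
    nx, ny, nz = shape
    strides = (ny * nz, nz, 1)
    tf = theta.ravel()
    mf = m.ravel()
    qf = q.ravel()
    # phase-coherence edge weights, padded to full-shape flat arrays for
    # O(1) lookup; combined with the endpoint voxel qualities so that
    # low-quality voxels are reached last even through coherent edges
    ew = edge_weights(theta, np.ones_like(theta))
    ew_flat = []
    for a in range(3):
        full = np.zeros(shape)
        sl = [slice(None)] * 3
        sl[a] = slice(None, -1)
        qa = [slice(None)] * 3
        qa[a] = slice(1, None)
        full[tuple(sl)] = ew[a] * np.minimum(q[tuple(sl)], q[tuple(qa)])
        ew_flat.append(full.ravel())

    visited = ~mf  # outside-mask voxels are never entered
    unwrapped = np.full(tf.shape, np.nan)
    counter = 0
    heap: list = []

    coords = np.stack(np.unravel_index(np.arange(tf.size), shape))

    def push_edges(i):
        nonlocal counter
        ci = coords[:, i]
        for a in range(3):
            s = strides[a]
            if ci[a] + 1 < shape[a]:
                j = i + s
                if not visited[j]:
                    counter += 1
                    heapq.heappush(heap, (-ew_flat[a][i], counter, j, i))
            if ci[a] > 0:
                j = i - s
                if not visited[j]:
                    counter += 1
                    heapq.heappush(heap, (-ew_flat[a][j], counter, j, i))

    remaining = int(np.count_nonzero(~visited))
    while remaining > 0:
        # seed: maximum quality among unvisited masked voxels, first index wins
        seed_q = np.where(~visited, qf, -1.0)
        seed = int(seed_q.argmax())
        unwrapped[seed] = tf[seed]
        visited[seed] = True
        remaining -= 1
        component = [seed]
        heap.clear()
        push_edges(seed)
        while heap:
            _, _, j, i = heapq.heappop(heap)
            if visited[j]:
                continue
            unwrapped[j] = unwrapped[i] + wrap_phase(tf[j] - tf[i])
            visited[j] = True
            remaining -= 1
            component.append(j)
            push_edges(j)
        # re-anchor the component at its lowest linear index so the global
        # 2*pi choice does not depend on floating-point ties in the seed
        anchor = min(component)
        k = np.rint((unwrapped[anchor] - tf[anchor]) / TWO_PI)
        if k != 0:
            unwrapped[component] -= k * TWO_PI

    out = unwrapped.reshape(shape)
    with np.errstate(invalid="ignore"):
        n = np.rint((out - theta) / TWO_PI)
    n = np.where(np.isfinite(n), n, 0).astype(int)
    return Volume(out, kind="phase", meta=phase.meta), n
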