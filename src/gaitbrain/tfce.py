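"""Threshold-free cluster enhancement (TFCE) for volumetric statistic maps.

TFCE integrates, over all cluster-forming thresholds ``h``, the extent of the
supra-threshold connected component containing each voxel, weighted by
``extent**E * h**H``:

    TFCE(v) = ∫_0^{t_v} e_v(h)**E · h**H dh

where ``t_v`` is the statistic at voxel ``v`` and ``e_v(h)`` the size (in
voxels) of the component of ``{t > h}`` containing ``v``.  This boosts
spatially coherent signal without committing to a single cluster-forming
threshold.  The integral is evaluated by a midpoint Riemann sum with step
``dh`` (midpoint rather than endpoint sampling keeps the quadrature error
second order in ``dh``).

Negative statistics are enhanced on the negated map and re-signed, so the
output is an odd function of the input.

The hot path uses an incremental union-find over voxels sorted by height,
compiled with numba: descending through the thresholds, voxels are activated
once and merged with active neighbours, so each threshold only requires root
lookups rather than a full relabelling of the volume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = ["TFCEParams", "tfce_enhance"]


@dataclass(frozen=True)
class TFCEParams:
    """TFCE settings.

    Parameters
    ----------
    h_power, e_power:
        Height and extent exponents (H and E). Defaults H=2, E=0.5 are the
        literature standard for volumetric data.
    n_steps:
        Number of integration steps when ``dh`` is not given; the step is
        then ``max(|stat|) / n_steps`` (adaptive per map).
    dh:
        Explicit integration step in statistic units; overrides ``n_steps``.
    connectivity:
        Voxel neighbourhood: 6 (faces), 18 (faces+edges) or 26 (full cube).
    """

    h_power: float = 2.0
    e_power: float = 0.5
    n_steps: int = 200
    dh: float | None = None
    connectivity: int = 26

    def __post_init__(self) -> None:
        if self.h_power <= 0 or self.e_power <= 0:
            raise ValueError("TFCE exponents h_power and e_power must be > 0")
        if self.dh is not None and self.dh <= 0:
            raise ValueError("TFCE step dh must be > 0")
        if self.n_steps < 1:
            raise ValueError("TFCE n_steps must be >= 1")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")


def _neighbor_offsets(shape: tuple[int, int, int], connectivity: int) -> np.ndarray:
    """Flat-index offsets of the neighbourhood on a zero-padded grid."""
    deltas = []
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if dz == dy == dx == 0:
                    continue
                order = abs(dz) + abs(dy) + abs(dx)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                deltas.append((dz, dy, dx))
    nz, ny, nx = (s + 2 for s in shape)
    return np.array([dz * ny * nx + dy * nx + dx for dz, dy, dx in deltas], dtype=np.int64)


@njit(cache=True)
def _find(parent: np.ndarray, i: int) -> int:
    root = i
    while parent[root] != root:
        root = parent[root]
    while parent[i] != root:  # path compression
        nxt = parent[i]
        parent[i] = root
        i = nxt
    return root


@njit(cache=True)
def _tfce_kernel(
    values: np.ndarray,
    order: np.ndarray,
    offsets: np.ndarray,
    heights: np.ndarray,
    dh: float,
    e_power: float,
    h_power: float,
    out: np.ndarray,
) -> None:
    """Accumulate midpoint-rule TFCE contributions into ``out`` (flat, padded).

    ``order`` lists candidate voxels by descending value; ``heights`` must be
    descending.  At each height the supra-threshold set is ``values > h``;
    components are maintained incrementally with union-find.
    """
    n = values.size
    parent = np.full(n, -1, dtype=np.int64)
    size = np.zeros(n, dtype=np.int64)
    ptr = 0
    m = order.size
    for h in heights:
        while ptr < m and values[order[ptr]] > h:
            v = order[ptr]
            parent[v] = v
            size[v] = 1
            for k in range(offsets.size):
                w = v + offsets[k]
                if parent[w] >= 0:
                    rv = _find(parent, v)
                    rw = _find(parent, w)
                    if rv != rw:
                        if size[rv] < size[rw]:
                            rv, rw = rw, rv
                        parent[rw] = rv
                        size[rv] += size[rw]
            ptr += 1
        weight = h**h_power * dh
        for i in range(ptr):
            v = order[i]
            r = _find(parent, v)
            out[v] += size[r] ** e_power * weight


def _enhance_positive(vol: np.ndarray, params: TFCEParams, dh: float) -> np.ndarray:
    """TFCE of the positive part of ``vol`` (3D, already masked)."""
    out = np.zeros_like(vol, dtype=np.float64)
    vmax = float(vol.max(initial=0.0))
    if vmax <= 0 or dh <= 0:
        return out
    padded = np.zeros(tuple(s + 2 for s in vol.shape), dtype=np.float64)
    padded[1:-1, 1:-1, 1:-1] = np.maximum(vol, 0.0)
    flat = padded.ravel()
    cand = np.flatnonzero(flat > 0)
    order = cand[np.argsort(flat[cand])[::-1]]
    n_heights = int(np.ceil(vmax / dh))
    heights = (np.arange(n_heights, 0, -1) - 0.5) * dh  # descending midpoints
    heights = heights[heights < vmax]
    offsets = _neighbor_offsets(vol.shape, params.connectivity)
    acc = np.zeros(flat.size, dtype=np.float64)
    _tfce_kernel(flat, order, offsets, heights, dh, params.e_power, params.h_power, acc)
    out[:] = acc.reshape(padded.shape)[1:-1, 1:-1, 1:-1]
    return out


def tfce_enhance(
    stat: np.ndarray,
    params: TFCEParams | None = None,
    mask: np.ndarray | None = None,
    two_sided: bool = True,
) -> np.ndarray:
    """Enhance a 3D statistic map with TFCE.

    Parameters
    ----------
    stat:
        3D statistic volume (e.g. voxelwise t values).
    params:
        :class:`TFCEParams`; defaults to H=2, E=0.5, 26-connectivity with an
        adaptive step ``max(|stat|)/200``.
    mask:
        Optional boolean volume; voxels outside are zeroed before enhancement.
    two_sided:
        When true, negative values are enhanced on the negated map and
        re-signed; otherwise they are ignored.

    Returns
    -------
    numpy.ndarray
        Signed enhanced map, same shape as ``stat``.
    """
    params = params or TFCEParams()
    stat = np.asarray(stat, dtype=np.float64)
    if stat.ndim != 3:
        raise ValueError("stat map must be 3D")
    if mask is not None:
        stat = np.where(mask, stat, 0.0)
    dh = params.dh
    if dh is None:
        vmax = float(np.abs(stat).max(initial=0.0))
        if vmax == 0:
            return np.zeros_like(stat)
        dh = vmax / params.n_steps
    enhanced = _enhance_positive(stat, params, dh)
    if two_sided:
        enhanced -= _enhance_positive(-stat, params, dh)
    return enhanced
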