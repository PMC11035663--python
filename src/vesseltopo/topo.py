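"""Binary-mask topology operators.

Surface extraction, exact Euclidean distance transform from the vessel
surface, morphological dilation, and homotopic skeletonization by sequential
deletion of simple points under the (26, 6) digital-topology pair
(26-connected foreground, 6-connected background).

All operators treat voxels outside the image bounds as background, so a
foreground voxel on the image border counts as a surface voxel.
"""

from __future__ import annotations

import numpy as np
from numba import njit
from scipy import ndimage

from .core import DistanceMap, LabelMap

__all__ = [
    "SkeletonMap",
    "DilationMap",
    "surface_voxels",
    "distance_transform",
    "dilate",
    "skeletonize",
]

_CUBE = np.ones((3, 3, 3), dtype=bool)  # 26-connected structuring element


class SkeletonMap(LabelMap):
    """A homotopic curve skeleton: subset of its source mask with the same
    number of 26-connected foreground and 6-connected background components."""


class DilationMap(LabelMap):
    """A morphological dilation: superset of its source mask."""


def _as_mask(L) -> np.ndarray:
    if isinstance(L, LabelMap):
        return L.data.astype(np.uint8)
    arr = np.asarray(L)
    if arr.ndim != 3:
        raise ValueError(f"expected a 3D mask, got shape {arr.shape}")
    return (arr > 0).astype(np.uint8)


def surface_voxels(L) -> LabelMap:
    """Foreground voxels with at least one background 6-neighbour.

    The set S = {s | L(s)=1 and some 6-neighbour u has L(u)=0}; neighbours
    outside the image count as background, so border foreground is surface.
    """
    m = _as_mask(L)
    p = np.pad(m, 1)
    interior = (
        (p[:-2, 1:-1, 1:-1] == 1)
        & (p[2:, 1:-1, 1:-1] == 1)
        & (p[1:-1, :-2, 1:-1] == 1)
        & (p[1:-1, 2:, 1:-1] == 1)
        & (p[1:-1, 1:-1, :-2] == 1)
        & (p[1:-1, 1:-1, 2:] == 1)
    )
    surf = (m == 1) & ~interior
    sp = L.spacing if isinstance(L, LabelMap) else (1.0, 1.0, 1.0)
    return LabelMap(surf.astype(np.uint8), spacing=sp)


def distance_transform(L, units: str = "voxel") -> DistanceMap:
    """Euclidean distance from each vessel voxel to the nearest surface voxel.

    D(v) = min_{s in S} ||v - s||_2 for voxels with L(v)=1 (zero if v is
    itself a surface voxel), and 0 on background.  ``units='mm'`` scales
    distances by the voxel spacing; the default works in voxel units so that
    values are exact integers-or-surds comparable with a brute-force oracle.
    """
    m = _as_mask(L)
    sp = L.spacing if isinstance(L, LabelMap) else (1.0, 1.0, 1.0)
    if units not in ("voxel", "mm"):
        raise ValueError(f"units must be 'voxel' or 'mm', got {units!r}")
    if m.sum() == 0:
        return DistanceMap(np.zeros(m.shape), spacing=sp, units=units)
    surf = surface_voxels(L).data
    sampling = sp if units == "mm" else None
    d = ndimage.distance_transform_edt(surf == 0, sampling=sampling)
    return DistanceMap(d * (m > 0), spacing=sp, units=units)


def dilate(L, radius: int = 1) -> DilationMap:
    """Binary dilation with a 3x3x3 (26-connected) cube, ``radius`` times."""
    if int(radius) != radius or radius < 1:
        raise ValueError(f"dilation radius must be a positive integer, got {radius}")
    m = _as_mask(L)
    out = ndimage.binary_dilation(m, structure=_CUBE, iterations=int(radius))
    sp = L.spacing if isinstance(L, LabelMap) else (1.0, 1.0, 1.0)
    return DilationMap(out.astype(np.uint8), spacing=sp)


# ---------------------------------------------------------------------------
# Homotopic thinning.
#
# A foreground voxel is simple (deletable without changing topology) under
# the (26, 6) pair iff
#   (a) its 26 foreground neighbours form exactly one 26-connected component,
#   (b) the background voxels of its 18-neighbourhood that are 6-reachable
#       from a face neighbour form exactly one 6-connected component.
# (Malandain & Bertrand characterisation via the topological numbers T26/T6.)
# ---------------------------------------------------------------------------


@njit(cache=True)
def _fg_simple(nb):
    # exactly one 26-component of foreground in the punctured 3x3x3 block
    nfg = 0
    start = -1
    for i in range(27):
        if i == 13:
            continue
        if nb[i // 9, (i // 3) % 3, i % 3] == 1:
            nfg += 1
            if start < 0:
                start = i
    if nfg == 0:
        return False
    visited = np.zeros(27, np.uint8)
    stack = np.empty(27, np.int64)
    top = 0
    stack[top] = start
    top += 1
    visited[start] = 1
    count = 1
    while top > 0:
        top -= 1
        i = stack[top]
        z = i // 9
        y = (i // 3) % 3
        x = i % 3
        for dz in range(-1, 2):
            for dy in range(-1, 2):
                for dx in range(-1, 2):
                    nz = z + dz
                    ny = y + dy
                    nx = x + dx
                    if nz < 0 or nz > 2 or ny < 0 or ny > 2 or nx < 0 or nx > 2:
                        continue
                    j = nz * 9 + ny * 3 + nx
                    if j == 13 or visited[j] == 1:
                        continue
                    if nb[nz, ny, nx] == 0:
                        continue
                    visited[j] = 1
                    stack[top] = j
                    top += 1
                    count += 1
    return count == nfg


@njit(cache=True)
def _bg_simple(nb):
    # exactly one 6-component of background within the 18-neighbourhood
    # containing a face neighbour
    start = -1
    for i in range(27):
        z = i // 9
        y = (i // 3) % 3
        x = i % 3
        nz = (z != 1) + (y != 1) + (x != 1)
        if nz == 1 and nb[z, y, x] == 0:
            start = i
            break
    if start < 0:
        return False  # no background face neighbour: not a border point
    visited = np.zeros(27, np.uint8)
    stack = np.empty(27, np.int64)
    top = 0
    stack[top] = start
    top += 1
    visited[start] = 1
    while top > 0:
        top -= 1
        i = stack[top]
        z = i // 9
        y = (i // 3) % 3
        x = i % 3
        for d in range(6):
            dz = 0
            dy = 0
            dx = 0
            if d == 0:
                dz = -1
            elif d == 1:
                dz = 1
            elif d == 2:
                dy = -1
            elif d == 3:
                dy = 1
            elif d == 4:
                dx = -1
            else:
                dx = 1
            nz = z + dz
            ny = y + dy
            nx = x + dx
            if nz < 0 or nz > 2 or ny < 0 or ny > 2 or nx < 0 or nx > 2:
                continue
            nnz = (nz != 1) + (ny != 1) + (nx != 1)
            if nnz == 0 or nnz == 3:  # stay inside the 18-neighbourhood
                continue
            j = nz * 9 + ny * 3 + nx
            if visited[j] == 1 or nb[nz, ny, nx] == 1:
                continue
            visited[j] = 1
            stack[top] = j
            top += 1
    # every background face neighbour must have been reached
    for i in range(27):
        z = i // 9
        y = (i // 3) % 3
        x = i % 3
        nz = (z != 1) + (y != 1) + (x != 1)
        if nz == 1 and nb[z, y, x] == 0 and visited[i] == 0:
            return False
    return True


@njit(cache=True)
def _thin(mask):
    """Sequential directional thinning on a zero-padded uint8 mask (in place)."""
    D, W, H = mask.shape
    dirs = np.array(
        [[-1, 0, 0], [1, 0, 0], [0, -1, 0], [0, 1, 0], [0, 0, -1], [0, 0, 1]],
        dtype=np.int64,
    )
    changed = True
    while changed:
        changed = False
        for d in range(6):
            dz = dirs[d, 0]
            dy = dirs[d, 1]
            dx = dirs[d, 2]
            for z in range(1, D - 1):
                for y in range(1, W - 1):
                    for x in range(1, H - 1):
                        if mask[z, y, x] != 1:
                            continue
                        if mask[z + dz, y + dy, x + dx] != 0:
                            continue
                        s = 0
                        for iz in range(z - 1, z + 2):
                            for iy in range(y - 1, y + 2):
                                for ix in range(x - 1, x + 2):
                                    s += mask[iz, iy, ix]
                        if s - 1 <= 1:
                            continue  # endpoint or isolated: keep curve ends
                        nb = mask[z - 1 : z + 2, y - 1 : y + 2, x - 1 : x + 2].copy()
                        if _fg_simple(nb) and _bg_simple(nb):
                            mask[z, y, x] = 0
                            changed = True
    return mask


def skeletonize(L) -> SkeletonMap:
    """Homotopic curve skeleton by iterative simple-point thinning.

    Border voxels are visited in six directional sub-iterations (up, down,
    north, south, east, west) in lexicographic order within each; only
    (26, 6)-simple points are deleted and curve endpoints are preserved, so
    26-connected foreground components, 6-connected background components,
    and loops/cavities are all preserved exactly.
    """
    m = _as_mask(L)
    padded = np.pad(m, 1).astype(np.uint8)
    _thin(padded)
    out = padded[1:-1, 1:-1, 1:-1]
    sp = L.spacing if isinstance(L, LabelMap) else (1.0, 1.0, 1.0)
    return SkeletonMap(out, spacing=sp)
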