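"""Shared fixtures and independent oracles for the test suite."""

import numpy as np
import pytest
from scipy import ndimage

CUBE = np.ones((3, 3, 3), dtype=bool)
FACE = ndimage.generate_binary_structure(3, 1)


# ---------------------------------------------------------------------------
# independent oracles (used to check the package, never built from it)
# ---------------------------------------------------------------------------


def brute_surface(mask: np.ndarray) -> np.ndarray:
    """Direct evaluation of the surface definition: foreground voxel with a
    background 6-neighbour (outside counts as background)."""
    m = np.pad(np.asarray(mask, dtype=np.uint8), 1)
    out = np.zeros_like(m)
    for z in range(1, m.shape[0] - 1):
        for y in range(1, m.shape[1] - 1):
            for x in range(1, m.shape[2] - 1):
                if m[z, y, x] != 1:
                    continue
                nbrs = [
                    m[z - 1, y, x], m[z + 1, y, x],
                    m[z, y - 1, x], m[z, y + 1, x],
                    m[z, y, x - 1], m[z, y, x + 1],
                ]
                if min(nbrs) == 0:
                    out[z, y, x] = 1
    return out[1:-1, 1:-1, 1:-1]


def brute_distance(mask: np.ndarray) -> np.ndarray:
    """O(|V|*|S|) nearest-surface-voxel minimisation."""
    mask = np.asarray(mask, dtype=bool)
    surf = np.argwhere(brute_surface(mask) > 0)
    out = np.zeros(mask.shape, dtype=float)
    if surf.size == 0:
        return out
    for v in np.argwhere(mask):
        out[tuple(v)] = np.sqrt(((surf - v) ** 2).sum(axis=1)).min()
    return out


def count_components(mask: np.ndarray, connectivity: int) -> int:
    struct = CUBE if connectivity == 26 else FACE
    return int(ndimage.label(np.asarray(mask, dtype=np.uint8), structure=struct)[1])


def count_background_components(mask: np.ndarray) -> int:
    """6-components of the background under the outside-is-background
    convention (the mask is embedded in an infinite zero field)."""
    bg = np.pad(np.asarray(mask, dtype=np.uint8) == 0, 1, constant_values=True)
    return int(ndimage.label(bg, structure=FACE)[1])


def euler_characteristic(mask: np.ndarray) -> int:
    """Euler characteristic of the cubical complex spanned by the voxels.

    chi = #vertices - #edges + #faces - #cubes, counting every lattice
    element incident to at least one foreground voxel exactly once.
    """
    m = np.asarray(mask, dtype=bool)
    sh = m.shape

    def mark(deltas):
        acc = np.zeros([s + 1 for s in sh], dtype=bool)
        for d in deltas:
            sl = tuple(slice(dd, dd + s) for dd, s in zip(d, sh))
            acc[sl] |= m
        return int(acc.sum())

    corners = [(a, b, c) for a in (0, 1) for b in (0, 1) for c in (0, 1)]
    n_vertices = mark(corners)
    n_edges = 0
    for ax in range(3):
        deltas = []
        for a in (0, 1):
            for b in (0, 1):
                d = [0, 0, 0]
                others = [i for i in range(3) if i != ax]
                d[others[0]], d[others[1]] = a, b
                deltas.append(tuple(d))
        n_edges += mark(deltas)
    n_faces = 0
    for ax in range(3):
        deltas = []
        for a in (0, 1):
            d = [0, 0, 0]
            d[ax] = a
            deltas.append(tuple(d))
        n_faces += mark(deltas)
    n_cubes = int(m.sum())
    return n_vertices - n_edges + n_faces - n_cubes


# ---------------------------------------------------------------------------
# geometric helpers
# ---------------------------------------------------------------------------


def make_tube(shape=(9, 9, 30), radius=2, axis=2, start=4, stop=None):
    """Solid straight tube along ``axis``."""
    m = np.zeros(shape, dtype=np.uint8)
    if stop is None:
        stop = shape[axis] - 4
    centre = [s // 2 for s in shape]
    grids = np.mgrid[tuple(slice(0, s) for s in shape)]
    cross = np.zeros(shape, dtype=float)
    for i in range(3):
        if i != axis:
            cross += (grids[i] - centre[i]) ** 2
    along = grids[axis]
    m[(cross <= radius**2) & (along >= start) & (along < stop)] = 1
    return m


def make_torus(shape=(20, 40, 40), major=12, minor=4):
    z, y, x = np.mgrid[0 : shape[0], 0 : shape[1], 0 : shape[2]]
    cz, cy, cx = shape[0] / 2, shape[1] / 2, shape[2] / 2
    d = (np.sqrt((y - cy) ** 2 + (x - cx) ** 2) - major) ** 2 + (z - cz) ** 2
    return (d <= minor**2).astype(np.uint8)


def make_ball(shape=(13, 13, 13), radius=5):
    z, y, x = np.mgrid[tuple(slice(0, s) for s in shape)]
    c = [s // 2 for s in shape]
    return (
        ((z - c[0]) ** 2 + (y - c[1]) ** 2 + (x - c[2]) ** 2) <= radius**2
    ).astype(np.uint8)


def random_mask(rng, max_side=20, p=0.25):
    shape = tuple(rng.integers(3, max_side + 1, size=3))
    return (rng.random(shape) < p).astype(np.uint8)


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240422)


@pytest.fixture(scope="session")
def small_phantom_cases():
    """Six small phantom cases (two per domain), session-cached."""
    from vesseltopo import phantom

    cfg = phantom.PhantomConfig(shape=(16, 64, 64), max_depth=40)
    return phantom.generate_dataset(2, cfg, seed=404)
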