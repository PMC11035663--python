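"""Centerline-based training-patch extraction and non-overlapping tiling.

Training patches are centred on voxels sampled uniformly from the vessel
skeleton with a bounded random jitter (up to a quarter of the patch extent
per axis), which keeps thin branches, crossovers and bifurcations well
represented without centring every patch exactly on the centerline.
Inference uses a regular non-overlapping grid that covers every voxel
exactly once, zero-padding each axis to the next multiple of the patch
extent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np

__all__ = ["PatchRecord", "extract_training_patches", "tile_volume", "stitch"]


@dataclass
class PatchRecord:
    """Aligned (image, label, skeleton, distance) sub-volumes of one case."""

    image: np.ndarray
    label: np.ndarray
    skeleton: np.ndarray
    distance: np.ndarray
    origin: Tuple[int, int, int]
    domain_index: int = 0
    case_id: str = ""

    def __post_init__(self):
        shapes = {self.image.shape, self.label.shape, self.skeleton.shape, self.distance.shape}
        if len(shapes) != 1:
            raise ValueError(f"patch sub-volumes disagree in shape: {shapes}")

    @property
    def shape(self):
        return self.image.shape


def _unwrap(v) -> np.ndarray:
    if isinstance(v, np.ndarray):
        return v
    if hasattr(v, "data"):
        return np.asarray(v.data)
    return np.asarray(v)


def _get(case, name):
    v = getattr(case, name, None)
    if v is None and isinstance(case, dict):
        v = case.get(name)
    if v is None:
        raise ValueError(f"case is missing field {name!r}")
    return _unwrap(v)


def _crop_padded(arr: np.ndarray, origin, shape) -> np.ndarray:
    """Crop ``arr`` at ``origin`` to ``shape``, zero-padding out of bounds."""
    out = np.zeros(shape, dtype=arr.dtype)
    src, dst = [], []
    for o, s, n in zip(origin, shape, arr.shape):
        lo, hi = max(o, 0), min(o + s, n)
        if lo >= hi:
            return out
        src.append(slice(lo, hi))
        dst.append(slice(lo - o, hi - o))
    out[tuple(dst)] = arr[tuple(src)]
    return out


def extract_training_patches(
    case,
    n_patches: int,
    patch_shape: Sequence[int] = (16, 128, 128),
    seed: int = 0,
    rng: np.random.Generator = None,
) -> List[PatchRecord]:
    """Sample ``n_patches`` skeleton-centred patches from one case.

    Patch centres are skeleton voxels drawn uniformly with replacement,
    jittered by an independent uniform integer offset in
    [-extent//4, extent//4] per axis.  Because the jitter never exceeds a
    quarter of the patch extent, the sampled skeleton voxel always remains
    inside the patch, so every patch contains at least one skeleton voxel.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    patch_shape = tuple(int(p) for p in patch_shape)
    def _first(names):
        for nm in names:
            try:
                return _get(case, nm)
            except ValueError:
                continue
        raise ValueError(f"case has none of the fields {names}")

    image = _first(("volume", "image"))
    label = _get(case, "label")
    skeleton = _first(("centerline", "skeleton"))
    distance = _get(case, "distance")
    domain_index = 0
    dom = getattr(case, "domain", None) if not isinstance(case, dict) else case.get("domain")
    if dom is not None:
        domain_index = dom if isinstance(dom, (int, np.integer)) else dom.domain_index
    case_id = (
        case.get("case_id", "") if isinstance(case, dict) else getattr(case, "case_id", "")
    )
    coords = np.argwhere(skeleton > 0)
    if coords.shape[0] == 0:
        raise ValueError("cannot extract patches: the skeleton is empty")
    half = np.array(patch_shape) // 2
    jitter_max = np.array(patch_shape) // 4
    records = []
    for _ in range(int(n_patches)):
        centre = coords[rng.integers(0, coords.shape[0])]
        jitter = rng.integers(-jitter_max, jitter_max + 1)
        origin = tuple(int(c + j - h) for c, j, h in zip(centre, jitter, half))
        records.append(
            PatchRecord(
                image=_crop_padded(image, origin, patch_shape),
                label=_crop_padded(label, origin, patch_shape),
                skeleton=_crop_padded(skeleton, origin, patch_shape),
                distance=_crop_padded(distance, origin, patch_shape),
                origin=origin,
                domain_index=int(domain_index),
                case_id=str(case_id),
            )
        )
    return records


def tile_volume(v, patch_shape: Sequence[int] = (16, 128, 128)):
    """Non-overlapping tiling covering every voxel exactly once.

    Each axis is zero-padded up to the next multiple of the patch extent.
    Returns ``(tiles, origins, padded_shape)`` where origins index into the
    padded volume.
    """
    data = _unwrap(v)
    patch_shape = tuple(int(p) for p in patch_shape)
    padded_shape = tuple(
        int(np.ceil(s / p) * p) for s, p in zip(data.shape, patch_shape)
    )
    padded = np.zeros(padded_shape, dtype=data.dtype)
    padded[tuple(slice(0, s) for s in data.shape)] = data
    tiles, origins = [], []
    for z in range(0, padded_shape[0], patch_shape[0]):
        for y in range(0, padded_shape[1], patch_shape[1]):
            for x in range(0, padded_shape[2], patch_shape[2]):
                sl = (
                    slice(z, z + patch_shape[0]),
                    slice(y, y + patch_shape[1]),
                    slice(x, x + patch_shape[2]),
                )
                tiles.append(padded[sl].copy())
                origins.append((z, y, x))
    return tiles, origins, padded_shape


def stitch(patches, origins, original_shape) -> np.ndarray:
    """Inverse of :func:`tile_volume`: reassemble tiles and crop the padding.

    Raises if tiles overlap or fail to cover the padded grid exactly once.
    """
    patches = list(patches)
    origins = [tuple(int(c) for c in o) for o in origins]
    if not patches:
        raise ValueError("no tiles to stitch")
    patch_shape = patches[0].shape
    original_shape = tuple(int(s) for s in original_shape)
    padded_shape = tuple(
        int(np.ceil(s / p) * p) for s, p in zip(original_shape, patch_shape)
    )
    out = np.zeros(padded_shape, dtype=np.asarray(patches[0]).dtype)
    count = np.zeros(padded_shape, dtype=np.int32)
    for tile, o in zip(patches, origins):
        tile = np.asarray(tile)
        if tile.shape != patch_shape:
            raise ValueError("tiles disagree in shape")
        sl = tuple(slice(c, c + p) for c, p in zip(o, patch_shape))
        if any(s.stop > n for s, n in zip(sl, padded_shape)):
            raise ValueError(f"tile at {o} exceeds the padded grid {padded_shape}")
        out[sl] = tile
        count[sl] += 1
    if count.max() > 1:
        raise ValueError("overlapping tiles")
    if count.min() < 1:
        raise ValueError("missing tiles: the grid is not fully covered")
    return out[tuple(slice(0, s) for s in original_shape)]
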