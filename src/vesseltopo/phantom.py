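"""Synthetic multi-domain TOF-MRA-like phantom generator.

Emulates the features of multi-site time-of-flight MR angiography that the
segmentation pipeline depends on: hyperintense tubular vessel trees on a
darker background, per-site intensity-distribution shifts (different vessel
contrast and noise level per synthetic "scanner"), a smooth multiplicative
bias field, and optional spherical aneurysm protrusions attached to the
tree.  Every case carries its generative ground truth: binary vessel label,
true centerline, surface distance map, optional aneurysm mask, and a
one-hot domain label.

The generator is the package's test bed; it makes no claim to anatomical
realism (no circle of Willis geometry, no MR physics, no flow artifacts).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from . import topo
from .core import DistanceMap, DomainRecord, LabelMap, VolumeImage

__all__ = [
    "DomainParams",
    "PhantomConfig",
    "VesselTree",
    "PhantomCase",
    "grow_tree",
    "rasterize_tree",
    "add_aneurysm",
    "render_intensities",
    "generate_dataset",
    "default_domains",
]

# minimum tube radius so the rounded centerline voxel is always inside the
# swept sphere (voxel half-diagonal)
_MIN_RADIUS = 0.9


@dataclass
class DomainParams:
    """Intensity model of one synthetic acquisition site."""

    name: str = "site0"
    background_mean: float = 0.2
    background_std: float = 0.03
    vessel_mean: float = 0.8
    vessel_std: float = 0.05
    noise_std: float = 0.04
    bias_amplitude: float = 0.1

    def __post_init__(self):
        if self.vessel_mean <= self.background_mean:
            raise ValueError("vessels must be hyperintense: vessel_mean > background_mean")
        if min(self.background_std, self.vessel_std, self.noise_std) < 0:
            raise ValueError("standard deviations must be non-negative")


def default_domains() -> List[DomainParams]:
    """Three synthetic sites with shifted vessel contrast and noise level.

    Mimics, at reduced scale, the spread of per-site intensity histograms
    seen across multi-center MRA cohorts.  The differences survive
    per-volume z-scoring (contrast-to-noise varies), so a domain signal is
    present for the unlearning experiments.
    """
    return [
        DomainParams("siteA", vessel_mean=0.7, noise_std=0.02),
        DomainParams("siteB", vessel_mean=0.8, noise_std=0.05),
        DomainParams("siteC", vessel_mean=0.9, noise_std=0.08),
    ]


@dataclass
class PhantomConfig:
    """Geometry and appearance parameters of the phantom generator."""

    shape: Tuple[int, int, int] = (32, 160, 160)
    n_trees: int = 2
    step_length: float = 2.0
    radius_root: float = 2.5
    radius_decay: float = 0.8
    branch_prob: float = 0.12
    max_depth: int = 60
    turn_sigma: float = 0.35
    domain_params: List[DomainParams] = field(default_factory=default_domains)
    aneurysm: Optional[dict] = None  # {"count": int, "radius_range": (lo, hi)}
    seed: int = 0

    def __post_init__(self):
        if self.radius_root <= 0 or not (0 < self.radius_decay <= 1):
            raise ValueError("radii must be positive and decay in (0, 1]")
        if not (0 <= self.branch_prob <= 1):
            raise ValueError("branch_prob must be a probability")
        if any(s < 1 for s in self.shape):
            raise ValueError("shape must be positive")
        if self.aneurysm is not None:
            lo, hi = self.aneurysm.get("radius_range", (3.0, 5.0))
            if lo <= 0 or hi < lo:
                raise ValueError("invalid aneurysm radius_range")


@dataclass
class VesselTree:
    """Polyline tree: node positions with per-node radius and parent edges."""

    positions: np.ndarray  # (n, 3) float
    radii: np.ndarray  # (n,) float
    parents: np.ndarray  # (n,) int, -1 for the root

    @property
    def n_nodes(self) -> int:
        return self.positions.shape[0]

    def edges(self):
        for i, p in enumerate(self.parents):
            if p >= 0:
                yield int(p), i


@dataclass
class PhantomCase:
    """One synthetic study: image, ground truth and domain label."""

    volume: VolumeImage
    label: LabelMap
    centerline: topo.SkeletonMap
    distance: DistanceMap
    domain: DomainRecord
    aneurysm_mask: Optional[LabelMap] = None
    case_id: str = ""

    @property
    def domain_index(self) -> int:
        return self.domain.domain_index


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 0 else np.array([0.0, 0.0, 1.0])


def grow_tree(cfg: PhantomConfig, rng: np.random.Generator) -> VesselTree:
    """Grow one random vascular tree by a perturbed random walk.

    Each step advances ``step_length`` along a direction re-drawn as the
    previous direction plus isotropic Gaussian perturbation
    (``turn_sigma``); with probability ``branch_prob`` a child branch spawns
    with radius multiplied by ``radius_decay``.  Growth stops at
    ``max_depth`` steps or at the volume boundary, so every node radius is
    at least ``radius_root * radius_decay ** max_depth``.
    """
    shape = np.array(cfg.shape, dtype=float)
    margin = 2.0
    root = np.array(
        [rng.uniform(margin, s - margin) for s in shape], dtype=float
    )
    d0 = _unit(rng.normal(size=3) * np.array([0.3, 1.0, 1.0]))  # mostly in-plane
    positions = [root]
    radii = [max(cfg.radius_root, _MIN_RADIUS)]
    parents = [-1]
    # stack of (node_index, direction, radius, depth)
    stack = [(0, d0, float(radii[0]), 0)]
    while stack:
        idx, direction, radius, depth = stack.pop()
        pos = positions[idx]
        while depth < cfg.max_depth:
            direction = _unit(direction + rng.normal(scale=cfg.turn_sigma, size=3))
            new_pos = pos + direction * cfg.step_length
            if np.any(new_pos < margin) or np.any(new_pos > shape - margin):
                break
            positions.append(new_pos)
            radii.append(max(radius, _MIN_RADIUS))
            parents.append(idx)
            idx = len(positions) - 1
            pos = new_pos
            depth += 1
            if rng.random() < cfg.branch_prob:
                child_dir = _unit(direction + rng.normal(scale=3 * cfg.turn_sigma, size=3))
                stack.append((idx, child_dir, radius * cfg.radius_decay, depth + 1))
    return VesselTree(
        positions=np.array(positions),
        radii=np.array(radii),
        parents=np.array(parents, dtype=int),
    )


def _sphere_offsets(radius: float) -> np.ndarray:
    r = int(np.ceil(radius))
    z, y, x = np.mgrid[-r : r + 1, -r : r + 1, -r : r + 1]
    return np.argwhere(z * z + y * y + x * x <= radius * radius) - r


def _stamp_sphere(mask: np.ndarray, centre: np.ndarray, offsets: np.ndarray) -> None:
    pts = np.rint(centre).astype(int) + offsets
    ok = np.all((pts >= 0) & (pts < np.array(mask.shape)), axis=1)
    pts = pts[ok]
    mask[pts[:, 0], pts[:, 1], pts[:, 2]] = 1


def rasterize_tree(
    tree: VesselTree, shape: Sequence[int]
) -> Tuple[LabelMap, topo.SkeletonMap]:
    """Voxelize a tree: label = spheres swept along each edge at its radius;
    centerline = the rounded polyline (26-connected by 0.5-voxel sampling)."""
    shape = tuple(int(s) for s in shape)
    label = np.zeros(shape, dtype=np.uint8)
    centerline = np.zeros(shape, dtype=np.uint8)
    cache = {}
    for a, b in tree.edges():
        p0, p1 = tree.positions[a], tree.positions[b]
        r = float(tree.radii[b])
        key = round(r, 2)
        if key not in cache:
            cache[key] = _sphere_offsets(r)
        offsets = cache[key]
        seg = p1 - p0
        n_steps = max(1, int(np.ceil(np.linalg.norm(seg) / 0.5)))
        for t in np.linspace(0.0, 1.0, n_steps + 1):
            pt = p0 + t * seg
            _stamp_sphere(label, pt, offsets)
            c = np.rint(pt).astype(int)
            if np.all(c >= 0) and np.all(c < np.array(shape)):
                centerline[c[0], c[1], c[2]] = 1
    if tree.n_nodes == 1:  # degenerate single-node tree
        _stamp_sphere(label, tree.positions[0], _sphere_offsets(float(tree.radii[0])))
        c = np.rint(tree.positions[0]).astype(int)
        centerline[c[0], c[1], c[2]] = 1
    return LabelMap(label), topo.SkeletonMap(centerline)


def add_aneurysm(
    label: LabelMap,
    tree: VesselTree,
    radius: float,
    rng: np.random.Generator,
) -> Tuple[LabelMap, LabelMap]:
    """Attach a spherical aneurysm at a random tree node.

    The sphere is unioned into the vessel label and returned separately as
    the pathology mask, so by construction the pathology is fully preserved
    in the updated label.  Raises if no node admits a sphere of the given
    radius inside the volume.
    """
    if tree.n_nodes == 0:
        raise ValueError("cannot place an aneurysm on an empty tree")
    shape = np.array(label.shape)
    r = float(radius)
    candidates = np.arange(tree.n_nodes)
    rng.shuffle(candidates)
    for idx in candidates:
        c = tree.positions[idx]
        if np.all(c - r >= 0) and np.all(c + r <= shape - 1):
            offsets = _sphere_offsets(r)
            aneurysm = np.zeros(label.shape, dtype=np.uint8)
            _stamp_sphere(aneurysm, c, offsets)
            merged = np.maximum(label.data, aneurysm)
            return LabelMap(merged, spacing=label.spacing), LabelMap(
                aneurysm, spacing=label.spacing
            )
    raise ValueError(f"no tree node admits an aneurysm of radius {radius} inside the volume")


def _bias_field(shape, amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """Smooth multiplicative field 1 + amplitude * (low-frequency noise)."""
    if amplitude == 0:
        return np.ones(shape)
    coarse = rng.normal(size=(4, 4, 4))
    zoom = [s / 4 for s in shape]
    smooth = ndimage.zoom(coarse, zoom, order=3, mode="nearest")
    smooth = smooth[: shape[0], : shape[1], : shape[2]]
    m = np.abs(smooth).max()
    if m > 0:
        smooth = smooth / m
    return 1.0 + amplitude * smooth


def render_intensities(
    label, domain_params: DomainParams, rng: np.random.Generator
) -> VolumeImage:
    """Render a label mask into a TOF-MRA-like intensity volume.

    Vessel and background voxels are drawn from the domain's two normal
    distributions (vessels hyperintense), the result is modulated by a
    smooth low-frequency bias field and corrupted with additive Gaussian
    noise.
    """
    mask = topo._as_mask(label).astype(bool)
    img = rng.normal(
        domain_params.background_mean, domain_params.background_std, size=mask.shape
    )
    img[mask] = rng.normal(
        domain_params.vessel_mean, domain_params.vessel_std, size=int(mask.sum())
    )
    img *= _bias_field(mask.shape, domain_params.bias_amplitude, rng)
    if domain_params.noise_std > 0:
        img += rng.normal(0.0, domain_params.noise_std, size=mask.shape)
    sp = label.spacing if isinstance(label, LabelMap) else (1.0, 1.0, 1.0)
    return VolumeImage(img, spacing=sp)


def _one_hot(i: int, n: int) -> np.ndarray:
    v = np.zeros(n)
    v[i] = 1
    return v


def generate_case(
    cfg: PhantomConfig,
    domain_index: int,
    rng: np.random.Generator,
    case_id: str = "",
) -> PhantomCase:
    """Generate a single phantom case for one domain."""
    n_domains = len(cfg.domain_params)
    label = np.zeros(cfg.shape, dtype=np.uint8)
    centerline = np.zeros(cfg.shape, dtype=np.uint8)
    trees = []
    for _ in range(cfg.n_trees):
        tree = grow_tree(cfg, rng)
        lab_t, cl_t = rasterize_tree(tree, cfg.shape)
        label = np.maximum(label, lab_t.data)
        centerline = np.maximum(centerline, cl_t.data)
        trees.append(tree)
    label_map = LabelMap(label)
    aneurysm_mask = None
    if cfg.aneurysm is not None and cfg.aneurysm.get("count", 0) > 0:
        lo, hi = cfg.aneurysm.get("radius_range", (3.0, 5.0))
        total = np.zeros(cfg.shape, dtype=np.uint8)
        for _ in range(int(cfg.aneurysm["count"])):
            r = rng.uniform(lo, hi)
            order = rng.permutation(len(trees))
            for j, ti in enumerate(order):  # fall back over trees if one is degenerate
                try:
                    label_map, one = add_aneurysm(label_map, trees[ti], r, rng)
                    break
                except ValueError:
                    if j == len(order) - 1:
                        raise
            total = np.maximum(total, one.data)
        aneurysm_mask = LabelMap(total)
    params = cfg.domain_params[domain_index]
    volume = render_intensities(label_map, params, rng)
    distance = topo.distance_transform(label_map)
    return PhantomCase(
        volume=volume,
        label=label_map,
        centerline=topo.SkeletonMap(centerline),
        distance=distance,
        domain=DomainRecord(_one_hot(domain_index, n_domains)),
        aneurysm_mask=aneurysm_mask,
        case_id=case_id or f"{params.name}",
    )


def generate_dataset(
    n_per_domain: int,
    cfg: PhantomConfig = None,
    seed: int = 0,
) -> List[PhantomCase]:
    """Generate ``n_per_domain`` cases for each configured domain.

    Fully deterministic under ``seed``: every case draws from its own
    child generator spawned from one seed sequence, so the dataset is
    bit-identical across runs and insensitive to generation order.
    """
    cfg = cfg or PhantomConfig()
    n_domains = len(cfg.domain_params)
    if n_domains < 1:
        raise ValueError("at least one domain is required")
    seq = np.random.SeedSequence(seed)
    children = seq.spawn(n_domains * n_per_domain)
    cases = []
    k = 0
    for d in range(n_domains):
        for i in range(n_per_domain):
            rng = np.random.default_rng(children[k])
            k += 1
            cases.append(
                generate_case(cfg, d, rng, case_id=f"{cfg.domain_params[d].name}_{i:03d}")
            )
    return cases
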