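"""Segmentation evaluation: Dice, Precision, ASD, Topological Coincidence,
and pathology-overlap percentage.

Degenerate conventions (both masks empty): Dice = 1, TC = 1, ASD undefined
(returned as NaN and reported as missing, never coerced to 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage

from . import topo
from .core import LabelMap

__all__ = [
    "MetricsReport",
    "dice",
    "precision",
    "asd",
    "topological_coincidence",
    "pathology_overlap",
    "evaluate_case",
]

TC_EPS = 1e-6


def _masks(L, P):
    a = topo._as_mask(L).astype(bool)
    b = topo._as_mask(P).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return a, b


def dice(L, P) -> float:
    """Dice coefficient 2|L∩P| / (|L|+|P|); 1.0 when both masks are empty."""
    a, b = _masks(L, P)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(a, b).sum() / denom


def precision(L, P) -> float:
    """|L∩P| / |P| with L the reference; NaN (undefined) when P is empty."""
    a, b = _masks(L, P)
    nb = b.sum()
    if nb == 0:
        return math.nan
    return float(np.logical_and(a, b).sum() / nb)


def asd(L, P, units: str = "voxel") -> float:
    """Average symmetric surface distance.

    Mean over each mask's surface voxels of the Euclidean distance to the
    other mask's surface, averaged over the two directions.  NaN when either
    mask is empty.  ``units='mm'`` uses the LabelMap voxel spacing.
    """
    a, b = _masks(L, P)
    if a.sum() == 0 or b.sum() == 0:
        return math.nan
    sp = L.spacing if isinstance(L, LabelMap) else (1.0, 1.0, 1.0)
    sampling = sp if units == "mm" else None
    sa = topo.surface_voxels(L).data.astype(bool)
    sb = topo.surface_voxels(P).data.astype(bool)
    d_to_b = ndimage.distance_transform_edt(~sb, sampling=sampling)
    d_to_a = ndimage.distance_transform_edt(~sa, sampling=sampling)
    return float((d_to_b[sa].mean() + d_to_a[sb].mean()) / 2.0)


def topological_coincidence(L, P, dilation_radius: int = 1) -> float:
    """Topological Coincidence between a reference mask L and prediction P.

    TC = (Σ φ_P·δ_L + Σ δ_P·φ_L + ε) / (Σ φ_P + Σ φ_L + ε)

    where φ is the homotopic skeleton and δ the radius-``dilation_radius``
    cube dilation, so the score rewards each mask's centerline lying inside
    a small tolerance band around the other mask.  Equals 1 when P = L and
    ≈ 0 when P is empty against a non-empty L.  Clipped to [0, 1].
    """
    a, b = _masks(L, P)
    phi_L = topo.skeletonize(a).data.astype(np.float64)
    phi_P = topo.skeletonize(b).data.astype(np.float64)
    if a.any():
        delta_L = topo.dilate(a, dilation_radius).data.astype(np.float64)
    else:
        delta_L = np.zeros(a.shape)
    if b.any():
        delta_P = topo.dilate(b, dilation_radius).data.astype(np.float64)
    else:
        delta_P = np.zeros(b.shape)
    num = (phi_P * delta_L).sum() + (delta_P * phi_L).sum() + TC_EPS
    den = phi_P.sum() + phi_L.sum() + TC_EPS
    return float(np.clip(num / den, 0.0, 1.0))


def pathology_overlap(pathology, vessel_seg) -> float:
    """Percentage of pathology voxels preserved inside the vessel segmentation."""
    a, b = _masks(pathology, vessel_seg)
    na = a.sum()
    if na == 0:
        raise ValueError("pathology mask is empty")
    return float(100.0 * np.logical_and(a, b).sum() / na)


@dataclass
class MetricsReport:
    """Per-case evaluation scores; NaN marks an undefined metric."""

    dice: float
    precision: float
    asd: float
    tc: float
    pathology_overlap_percent: Optional[float] = None
    asd_units: str = "voxel"

    def as_dict(self) -> dict:
        d = {
            "dice": self.dice,
            "precision": self.precision,
            "asd": self.asd,
            "tc": self.tc,
        }
        d["pathology_overlap_percent"] = (
            self.pathology_overlap_percent
            if self.pathology_overlap_percent is not None
            else math.nan
        )
        return d


def evaluate_case(
    L,
    P,
    pathology=None,
    dilation_radius: int = 1,
    units: str = "voxel",
) -> MetricsReport:
    """Compute the full metric suite for one (reference, prediction) pair."""
    return MetricsReport(
        dice=dice(L, P),
        precision=precision(L, P),
        asd=asd(L, P, units=units),
        tc=topological_coincidence(L, P, dilation_radius=dilation_radius),
        pathology_overlap_percent=(
            pathology_overlap(pathology, P) if pathology is not None else None
        ),
        asd_units=units,
    )
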