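"""High-level modelling interface: configure, fit, inspect, predict.

``VesselSegmentationModel`` bundles the phantom-or-clinical training cases,
the network/loss/optimizer configuration and the patch-sampling policy;
``fit()`` runs the multi-task training and returns a
``SegmentationResults`` object carrying the trained network, the per-epoch
loss history, and evaluation / prediction / probing methods with a
``summary()`` table in the spirit of statistical modelling packages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence

import numpy as np
import pandas as pd

from . import losses, metrics, network, patching
from .core import LabelMap, ProbabilityMap, VolumeImage, normalize_intensity

__all__ = ["VesselSegmentationModel", "SegmentationResults"]


class VesselSegmentationModel:
    """Topology-aware multi-task segmentation model over a set of cases.

    Parameters
    ----------
    cases : sequence of PhantomCase-like objects
        Each must expose ``volume``, ``label``, a centerline/skeleton map,
        a ``distance`` map and a domain label (see ``patching``).  Volumes
        are z-score normalized on ingestion.
    model_config, loss_config, train_config : optional configuration
        dataclasses; sensible defaults otherwise.
    n_patches_per_case : patches sampled per training case per epoch set.
    val_cases : held-out cases used for per-epoch validation scores.
    """

    def __init__(
        self,
        cases: Sequence,
        model_config: network.ModelConfig = None,
        loss_config: losses.LossConfig = None,
        train_config: network.TrainConfig = None,
        n_patches_per_case: int = 8,
        val_cases: Sequence = None,
        normalize: bool = True,
    ):
        if len(cases) == 0:
            raise ValueError("no training cases supplied")
        self.cases = list(cases)
        self.val_cases = list(val_cases) if val_cases else []
        n_domains = getattr(cases[0].domain, "n_domains", None) or 2
        self.model_config = model_config or network.ModelConfig(n_domains=n_domains)
        self.loss_config = loss_config or losses.LossConfig(reduction="mean")
        self.train_config = train_config or network.TrainConfig()
        self.n_patches_per_case = int(n_patches_per_case)
        self.normalize = normalize
        if normalize:
            for c in self.cases + self.val_cases:
                c.volume = normalize_intensity(c.volume)

    def _sample_patches(self, cases, seed: int) -> List[patching.PatchRecord]:
        out: List[patching.PatchRecord] = []
        for i, c in enumerate(cases):
            out += patching.extract_training_patches(
                c,
                self.n_patches_per_case,
                self.model_config.patch_shape,
                seed=seed + 1000 * i,
            )
        return out

    def fit(self, verbose: bool = False) -> "SegmentationResults":
        """Train the network and return the results object."""
        seed = self.train_config.seed
        net = network.build_model(self.model_config, seed=seed)
        train_patches = self._sample_patches(self.cases, seed)
        val_patches = (
            self._sample_patches(self.val_cases, seed + 7919) if self.val_cases else None
        )
        history = network.train_model(
            net,
            train_patches,
            loss_cfg=self.loss_config,
            train_cfg=self.train_config,
            val_patches=val_patches,
            verbose=verbose,
        )
        return SegmentationResults(self, net, history, train_patches)


@dataclass
class SegmentationResults:
    """Fitted model: trained network, training history and diagnostics."""

    model: VesselSegmentationModel
    net: network.MultiTaskVesselNet
    history: pd.DataFrame
    train_patches: List[patching.PatchRecord] = field(repr=False, default=None)

    # -- prediction ---------------------------------------------------------
    def predict(self, volume: VolumeImage, threshold: float = 0.5):
        """Segment one volume; returns (ProbabilityMap, LabelMap)."""
        return network.predict_volume(
            self.net, volume, threshold=threshold, normalize=self.model.normalize
        )

    def evaluate(self, cases: Sequence, threshold: float = 0.5) -> pd.DataFrame:
        """Full metric suite per case against the ground-truth labels."""
        rows = []
        for c in cases:
            vol = c.volume
            prob, seg = network.predict_volume(
                self.net, vol, threshold=threshold, normalize=False
            )
            rep = metrics.evaluate_case(
                c.label, seg, pathology=getattr(c, "aneurysm_mask", None)
            )
            rows.append({"case_id": getattr(c, "case_id", ""), **rep.as_dict()})
        return pd.DataFrame(rows)

    def domain_probe(self, cases: Sequence = None, seed: int = 0) -> float:
        """Linear-probe domain accuracy on encoder latents (chance = 1/n)."""
        patches = (
            self.model._sample_patches(list(cases), seed + 31)
            if cases is not None
            else self.train_patches
        )
        return network.domain_probe_accuracy(self.net, patches, seed=seed)

    # -- reporting ----------------------------------------------------------
    def summary(self) -> str:
        """Text summary of the fit: configuration, losses, validation scores."""
        cfg = self.model.model_config
        last = self.history.iloc[-1]
        lines = [
            "Topology-aware multi-task vessel segmentation",
            "=" * 52,
            f"encoder levels       : {cfg.levels}",
            f"base channels        : {cfg.base_channels}",
            f"shared decoder blocks: {cfg.shared_decoder_levels}",
            f"domains              : {cfg.n_domains}",
            f"patch shape          : {cfg.patch_shape}",
            f"parameters           : {network.count_parameters(self.net):,}",
            f"epochs trained       : {len(self.history)}",
            "-" * 52,
            f"final total loss     : {last['total']:.4f}",
            f"  soft Dice (theta3) : {last['theta3']:.4f}",
            f"  distance (theta1)  : {last['theta1']:.4f}",
            f"  topology (theta2)  : {last['theta2']:.4f}",
            f"  decorrelation      : {last['dcl']:.4f}",
        ]
        if np.isfinite(last.get("val_dice", np.nan)):
            lines.append(f"validation Dice      : {last['val_dice']:.4f}")
        if np.isfinite(last.get("val_tc", np.nan)):
            lines.append(f"validation TC        : {last['val_tc']:.4f}")
        return "\n".join(lines)

    def save(self, path) -> None:
        self.net.save(path)
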