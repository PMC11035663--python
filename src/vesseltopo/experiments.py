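"""Reproducible desk-scale phantom experiments.

These are the package's standard study recipes: a fixed-seed segmentation
benchmark on three synthetic acquisition sites, a paired domain-unlearning
comparison (with and without the decorrelation penalty), and a
patch-extraction census.  The sizes are deliberately small — tiny network,
short schedules, reduced cohorts — so a full study runs on one CPU core in
minutes; docs/methods.md records the chosen problem sizes.

All randomness derives from a single ``seed`` argument.
"""

from __future__ import annotations

from typing import List

import numpy as np

from . import losses, metrics, network, patching, phantom
from .core import normalize_intensity

__all__ = [
    "make_study_cases",
    "segmentation_benchmark",
    "unlearning_benchmark",
    "patch_extraction_census",
]


def make_study_cases(
    n_per_domain: int,
    volume_shape=(16, 96, 96),
    seed: int = 0,
    max_depth: int = 40,
):
    """Generate and z-score a multi-site phantom cohort."""
    cfg = phantom.PhantomConfig(shape=volume_shape, max_depth=max_depth)
    cases = phantom.generate_dataset(n_per_domain, cfg, seed=seed)
    for c in cases:
        c.volume = normalize_intensity(c.volume)
    return cases


def _split(cases, n_per_domain: int, n_test: int):
    """Last ``n_test`` cases of each domain are held out."""
    train = [c for i, c in enumerate(cases) if i % n_per_domain < n_per_domain - n_test]
    test = [c for i, c in enumerate(cases) if i % n_per_domain >= n_per_domain - n_test]
    return train, test


def _extract(cases, n_patches: int, patch_shape, seed: int) -> List[patching.PatchRecord]:
    out: List[patching.PatchRecord] = []
    for i, c in enumerate(cases):
        out += patching.extract_training_patches(c, n_patches, patch_shape, seed=seed + 101 * i)
    return out


def segmentation_benchmark(seed: int = 0, epochs: int = 15, verbose: bool = False) -> dict:
    """Fixed-seed end-to-end benchmark on high-contrast 3-domain phantoms.

    Tiny network (3 levels, 8 base channels, 8x64x64 patches) trained for
    ``epochs`` epochs with Adam at the desk-scale learning rate 1e-3; the
    held-out volume of each domain is segmented by non-overlapping tiling
    and scored with the full metric suite.
    """
    cases = make_study_cases(3, volume_shape=(16, 96, 96), seed=seed + 11)
    train_cases, test_cases = _split(cases, 3, 1)
    train_patches = _extract(train_cases, 3, (8, 64, 64), seed=seed + 100)
    cfg = network.ModelConfig(
        levels=3, base_channels=8, patch_shape=(8, 64, 64), n_domains=3
    )
    model = network.build_model(cfg, seed=seed)
    history = network.train_model(
        model,
        train_patches,
        loss_cfg=losses.LossConfig(reduction="mean"),
        train_cfg=network.TrainConfig(epochs=epochs, batch_size=4, lr=1e-3, seed=seed),
        verbose=verbose,
    )
    reports = []
    for c in test_cases:
        _, seg = network.predict_volume(model, c.volume, normalize=False)
        reports.append(metrics.evaluate_case(c.label, seg))
    return {
        "dice": float(np.mean([r.dice for r in reports])),
        "precision": float(np.mean([r.precision for r in reports])),
        "asd": float(np.mean([r.asd for r in reports])),
        "tc": float(np.mean([r.tc for r in reports])),
        "history": history,
        "model": model,
        "test_cases": test_cases,
    }


def unlearning_benchmark(seed: int = 0, epochs: int = 25, verbose: bool = False) -> dict:
    """Paired runs with decorrelation weight 0 and 0.1, identical seeds.

    The unlearning schedule is longer than the segmentation benchmark
    because decorrelation completes after the main task converges.  A
    dedicated patch cohort spanning many volumes (few patches each) feeds
    the per-epoch latent-decorrelation step — a minibatch estimates domain
    correlations too noisily, and the erasure generalizes only as well as
    the cohort's between-volume diversity.  The probe is a fresh logistic
    regression on encoder latents of patches from ten independent volumes
    per site, split by volume and averaged over five splits.  Chance is
    1/3.
    """
    cases = make_study_cases(5, volume_shape=(16, 64, 64), seed=seed + 21)
    train_cases, test_cases = _split(cases, 5, 1)
    patch_shape = (8, 32, 32)
    train_patches = _extract(train_cases, 2, patch_shape, seed=seed + 300)
    dcl_cases = make_study_cases(11, volume_shape=(16, 64, 64), seed=seed + 9000)
    dcl_patches = _extract(dcl_cases, 2, patch_shape, seed=seed + 900)
    probe_cases = make_study_cases(10, volume_shape=(16, 64, 64), seed=seed + 5000)
    probe_patches = _extract(probe_cases, 20, patch_shape, seed=seed + 7000)
    out = {"chance": 1.0 / 3.0}
    for tag, wd in (("without_dcl", 0.0), ("with_dcl", 0.1)):
        cfg = network.ModelConfig(
            levels=3, base_channels=8, patch_shape=patch_shape, n_domains=3
        )
        model = network.build_model(cfg, seed=seed)
        network.train_model(
            model,
            train_patches,
            loss_cfg=losses.LossConfig(reduction="mean", weight_dcl=wd),
            train_cfg=network.TrainConfig(
                epochs=epochs, batch_size=4, lr=1e-3, seed=seed,
                head_lr_multiplier=10.0, head_reset_every=5,
            ),
            dcl_patches=dcl_patches,
            verbose=verbose,
        )
        probe = float(
            np.mean(
                [
                    network.domain_probe_accuracy(model, probe_patches, seed=seed + k)
                    for k in range(1, 6)
                ]
            )
        )
        dices = []
        for c in test_cases:
            _, seg = network.predict_volume(model, c.volume, normalize=False)
            dices.append(metrics.dice(c.label, seg))
        out[f"probe_acc_{tag}"] = probe
        out[f"dice_{tag}"] = float(np.mean(dices))
    return out


def patch_extraction_census(
    n_volumes: int = 227,
    patches_per_volume: int = 100,
    seed: int = 0,
) -> int:
    """Count patch records from centerline-based extraction over a cohort.

    Volumes are generated one at a time and their patch records discarded
    after counting, so the census stays memory-light even for hundreds of
    volumes.
    """
    cfg = phantom.PhantomConfig(shape=(16, 64, 64), n_trees=1, max_depth=25)
    seq = np.random.SeedSequence(seed)
    children = seq.spawn(n_volumes)
    n_domains = len(cfg.domain_params)
    total = 0
    for i in range(n_volumes):
        rng = np.random.default_rng(children[i])
        case = phantom.generate_case(cfg, i % n_domains, rng, case_id=f"census_{i:04d}")
        recs = patching.extract_training_patches(
            case, patches_per_volume, (8, 32, 32), seed=seed + i
        )
        total += len(recs)
    return total
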