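# vesseltopo

Topology-aware, domain-generalized 3D vessel segmentation for
TOF-MRA-like volumes.

Cerebrovascular segmentation from Time-Of-Flight MR angiography has two
notorious failure modes.  Voxel-overlap scores such as Dice barely
distinguish a prediction that silently drops a thin branch from one that
traces the whole vascular tree with a one-voxel offset — yet only the
second preserves the connectivity that matters for reading an angiogram.
And encoders trained on multi-site cohorts absorb scanner/site intensity
signatures ("domain shift"), which hurts generalization to unseen
scanners.  `vesseltopo` implements a multi-task 3D encoder–decoder that
addresses both:

* a **Topological Coincidence (TC)** metric and loss built on homotopic
  skeletonization φ and morphological dilation δ:

  `TC = (Σ φ_L̂·δ_L + Σ δ_L̂·φ_L + ε) / (Σ φ_L̂ + Σ φ_L + ε)`

  which rewards each mask's centerline lying inside a one-voxel tolerance
  band around the other mask;
* an auxiliary **surface distance-transform regression**
  (`D(v) = min_{s∈S} ‖v−s‖₂`, smooth-L1 loss) and an auxiliary
  **centerline prediction** task sharing the encoder and initial decoder;
* **MIP/RIP layers** — 2×2×2 max-intensity-projection pooling with argmax
  records and index-driven reverse projection for upsampling;
* a **decorrelation (DcL) domain-regularization head** that minimizes the
  Pearson correlation between predicted and true site labels so the
  shared encoder unlearns scanner identity;
* a **synthetic multi-site phantom generator** (random vascular trees,
  hyperintense tubes, per-site intensity shifts, bias field, optional
  spherical aneurysms) so the full pipeline is testable without clinical
  data.

Everything runs on numpy: the network, its losses and Adam are built on a
small tape-based autodiff engine included in the package.  See
`docs/methods.md` for the model, conventions and design rationale.

## Worked example

```python
from vesseltopo import (
    PhantomConfig, generate_dataset, ModelConfig, TrainConfig,
    LossConfig, VesselSegmentationModel,
)

cases = generate_dataset(3, PhantomConfig(shape=(16, 96, 96)), seed=11)
train = [c for i, c in enumerate(cases) if i % 3 != 2]
test = [c for i, c in enumerate(cases) if i % 3 == 2]   # one volume per site

model = VesselSegmentationModel(
    train,
    model_config=ModelConfig(levels=3, base_channels=8,
                             patch_shape=(8, 64, 64), n_domains=3),
    loss_config=LossConfig(reduction="mean"),
    train_config=TrainConfig(epochs=15, batch_size=4, lr=1e-3, seed=0),
    n_patches_per_case=3,
    val_cases=test,
)
res = model.fit()
print(res.summary())

df = res.evaluate(test)
print(df[["case_id", "dice", "tc", "asd"]].round(3).to_string(index=False))
```

which prints:

```
Topology-aware multi-task vessel segmentation
====================================================
encoder levels       : 3
base channels        : 8
shared decoder blocks: 2
domains              : 3
patch shape          : (8, 64, 64)
parameters           : 112,614
epochs trained       : 15
----------------------------------------------------
final total loss     : 1.8744
  soft Dice (theta3) : 0.0314
  distance (theta1)  : 0.2854
  topology (theta2)  : 0.0052
  decorrelation      : 0.5370
validation Dice      : 0.9637
validation TC        : 0.7208

  case_id  dice    tc   asd
siteA_002 0.850 0.193 6.278
siteB_002 0.945 0.618 1.176
siteC_002 0.962 0.972 0.251
```

The `dice`/`tc` columns are overlap and topology scores against each
held-out phantom's generative ground truth; `asd` is the symmetric average
surface distance in voxels.  The spread is informative: the low-contrast
site A volume is segmented with decent overlap (0.85) but its thin
branches fragment, which the topology score exposes (TC 0.19) far more
sharply than Dice does — exactly the phenomenon the TC metric is built to
measure.  Fifteen epochs of this tiny recipe sit right at the edge of
convergence; the fixed-seed benchmark in `vesseltopo.experiments` is the
reference setting.

A command-line layer wraps the same pipeline:

```bash
vesseltopo simulate --out-dir data/ --n-per-domain 2 --seed 3
vesseltopo train    --config cfg.yaml --out-dir run/ --seed 1
vesseltopo predict  --checkpoint run/checkpoint.npz --volume v.nii.gz --out-dir preds/
vesseltopo evaluate --truth lab.nii.gz --pred preds/v_seg.nii.gz --out-csv metrics.csv
```

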