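"""Multi-task 3D encoder-decoder with MIP/RIP layers and a domain head.

Architecture
------------
A shared encoder of ``levels`` blocks (each: two 3x3x3 conv+ReLU with a
residual add, then a 2x2x2 MIP max-projection pooling that records argmax
indices).  A main decoder of ``levels`` blocks (each: RIP unpooling driven
by the matching encoder indices, concatenation skip from the matching
encoder stage, then two conv+ReLU with a residual add).  The first
``shared_decoder_levels`` decoder blocks are shared by all three tasks;
after them the two auxiliary tasks (distance regression and centerline
prediction) branch into exclusive decoder stacks of the same block
structure without encoder skips.  Heads: 1x1x1 conv + sigmoid for the main
segmentation and the centerline map, 1x1x1 conv + softplus for the
non-negative distance map.  The domain-regularization head global-average
pools the bottleneck features through two fully connected layers and a
softmax over the ``n_domains`` sites.

Training minimizes the weighted multi-task objective (soft Dice +
smooth-L1 distance regression + topological-coincidence loss + squared
domain decorrelation) with Adam.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd

from . import losses as L
from . import metrics as M
from . import patching, topo
from .autodiff import Adam, Tensor, as_tensor, concat
from .core import LabelMap, ProbabilityMap, VolumeImage, normalize_intensity

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "MultiTaskVesselNet",
    "mip_pool",
    "rip_unpool",
    "build_model",
    "count_parameters",
    "train_model",
    "predict_volume",
    "encoder_latents",
    "domain_probe_accuracy",
]


@dataclass
class ModelConfig:
    """Structural hyper-parameters of the network."""

    levels: int = 4
    base_channels: int = 16
    shared_decoder_levels: int = 2
    n_domains: int = 3
    patch_shape: Tuple[int, int, int] = (16, 128, 128)
    domain_hidden: int = 32

    def __post_init__(self):
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        if not (0 <= self.shared_decoder_levels < self.levels):
            raise ValueError("shared_decoder_levels must be < levels")
        if self.n_domains < 2:
            raise ValueError("n_domains must be >= 2")
        f = 2**self.levels
        if any(int(p) % f for p in self.patch_shape):
            raise ValueError(
                f"every patch dimension must be divisible by 2^levels={f}, got {self.patch_shape}"
            )
        self.patch_shape = tuple(int(p) for p in self.patch_shape)


@dataclass
class TrainConfig:
    """Optimization settings; learning rate follows the Adam default of the
    full-scale recipe (1e-4), overridable for small desk-scale runs."""

    epochs: int = 50
    batch_size: int = 4
    lr: float = 1e-4
    head_lr_multiplier: float = 10.0
    head_reset_every: int = 0  # 0 disables periodic domain-head re-initialization
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1 or self.lr <= 0:
            raise ValueError("invalid training configuration")
        if self.head_lr_multiplier <= 0:
            raise ValueError("head_lr_multiplier must be positive")


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------


class _Conv3:
    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        fan_in = cin * k**3
        std = np.sqrt(2.0 / fan_in)
        self.w = Tensor(
            rng.normal(0.0, std, size=(cout, cin, k, k, k)).astype(np.float32),
            requires_grad=True,
        )
        self.b = Tensor(np.zeros(cout, dtype=np.float32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x.conv3d(self.w, self.b)

    def params(self):
        return [self.w, self.b]


class _ConvBlock:
    """conv-ReLU x2 with a residual add (1x1x1 projection if channels change)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.conv1 = _Conv3(cin, cout, 3, rng)
        self.conv2 = _Conv3(cout, cout, 3, rng)
        self.proj = _Conv3(cin, cout, 1, rng) if cin != cout else None

    def __call__(self, x: Tensor) -> Tensor:
        h = self.conv1(x).relu()
        h = self.conv2(h).relu()
        s = self.proj(x) if self.proj is not None else x
        return h + s

    def params(self):
        p = self.conv1.params() + self.conv2.params()
        if self.proj is not None:
            p += self.proj.params()
        return p


class _Linear:
    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        std = np.sqrt(2.0 / cin)
        self.w = Tensor(rng.normal(0.0, std, size=(cin, cout)).astype(np.float32), requires_grad=True)
        self.b = Tensor(np.zeros(cout, dtype=np.float32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x.matmul(self.w) + self.b

    def params(self):
        return [self.w, self.b]


def mip_pool(x):
    """2x2x2 stride-2 maximum-intensity projection with an argmax record.

    Accepts a numpy array or Tensor of shape (N, C, D, H, W) with even
    spatial dimensions; ties break toward the lowest linear index within
    each window.  Returns ``(pooled, index_record)``.
    """
    t = as_tensor(x)
    if t.data.ndim != 5:
        raise ValueError("mip_pool expects an (N, C, D, H, W) tensor")
    out, rec = t.max_pool3d()
    return (out if isinstance(x, Tensor) else out.data), rec


def rip_unpool(x, record):
    """Reverse intensity projection: place values at recorded argmax
    positions at double resolution; all other positions are zero."""
    t = as_tensor(x)
    out = t.max_unpool3d(record)
    return out if isinstance(x, Tensor) else out.data


class MultiTaskVesselNet:
    """The multi-task segmentation network (see module docstring)."""

    def __init__(self, cfg: ModelConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        b, lv = cfg.base_channels, cfg.levels
        enc_channels = [b * 2**l for l in range(lv)]
        self.encoder: List[_ConvBlock] = []
        cin = 1
        for c in enc_channels:
            self.encoder.append(_ConvBlock(cin, c, rng))
            cin = c
        self._enc_channels = enc_channels
        # main decoder, deepest stage first; each block's output channel
        # count matches the encoder stage whose MIP indices the next RIP
        # unpooling will consume
        self.decoder_main: List[_ConvBlock] = []
        cprev = enc_channels[-1]
        for j in range(lv):
            e = lv - 1 - j
            cout = enc_channels[max(e - 1, 0)]
            self.decoder_main.append(_ConvBlock(cprev + enc_channels[e], cout, rng))
            cprev = cout
        # auxiliary branches take over after the shared decoder blocks
        self.decoder_t1: List[_ConvBlock] = []
        self.decoder_t2: List[_ConvBlock] = []
        c_aux = enc_channels[lv - 1] if cfg.shared_decoder_levels == 0 else enc_channels[
            lv - 1 - cfg.shared_decoder_levels
        ]
        for j in range(cfg.shared_decoder_levels, lv):
            e = lv - 1 - j
            cout = enc_channels[max(e - 1, 0)]
            self.decoder_t1.append(_ConvBlock(c_aux, cout, rng))
            self.decoder_t2.append(_ConvBlock(c_aux, cout, rng))
            c_aux = cout
        self.head_main = _Conv3(enc_channels[0], 1, 1, rng)
        self.head_t1 = _Conv3(enc_channels[0], 1, 1, rng)
        self.head_t2 = _Conv3(enc_channels[0], 1, 1, rng)
        cb = enc_channels[-1]
        self.fc1 = _Linear(cb, cfg.domain_hidden, rng)
        self.fc2 = _Linear(cfg.domain_hidden, cfg.n_domains, rng)
        # running per-feature statistics of the latent, used to standardize
        # the domain head's input (keeps its softmax out of saturation
        # while preserving the between-sample differences it must read)
        self.head_norm_mean = np.zeros(cb, dtype=np.float32)
        self.head_norm_var = np.ones(cb, dtype=np.float32)

    # -- parameters ---------------------------------------------------------
    def params(self) -> List[Tensor]:
        p: List[Tensor] = []
        for blk in self.encoder + self.decoder_main + self.decoder_t1 + self.decoder_t2:
            p += blk.params()
        for head in (self.head_main, self.head_t1, self.head_t2):
            p += head.params()
        p += self.fc1.params() + self.fc2.params()
        return p

    def set_requires_grad(self, flag: bool) -> None:
        for p in self.params():
            p.requires_grad = flag

    # -- forward ------------------------------------------------------------
    def forward(self, x, train: bool = True) -> dict:
        """Run the network on an (N, 1, D, H, W) batch.

        Returns a dict with Tensors: ``main`` (sigmoid probabilities),
        ``aux_distance`` (softplus, non-negative), ``aux_skeleton``
        (sigmoid), ``domain`` (softmax, (N, n_domains)) and ``latent``
        (global-average-pooled bottleneck features, (N, C_bottleneck)).
        """
        t = as_tensor(np.asarray(x, dtype=np.float32) if not isinstance(x, Tensor) else x)
        if t.data.ndim == 3:
            t = t.reshape((1, 1) + t.data.shape)
        if t.data.ndim != 5:
            raise ValueError("forward expects an (N, 1, D, H, W) batch")
        if not train:
            self.set_requires_grad(False)
        feats, records = [], []
        h = t
        for blk in self.encoder:
            f = blk(h)
            feats.append(f)
            h, rec = f.max_pool3d()
            records.append(rec)
        bottleneck = h
        lv, shared = self.cfg.levels, self.cfg.shared_decoder_levels
        # shared + main decoder path
        hm = h
        aux_feed = None
        for j, blk in enumerate(self.decoder_main):
            e = lv - 1 - j
            up = hm.max_unpool3d(records[e])
            hm = blk(concat([up, feats[e]], axis=1))
            if j == shared - 1:
                aux_feed = hm
        if shared == 0:
            aux_feed = bottleneck
        # auxiliary exclusive decoders (no encoder skip concatenation)
        h1 = h2 = aux_feed
        for j, (b1, b2) in enumerate(zip(self.decoder_t1, self.decoder_t2)):
            e = lv - 1 - (shared + j)
            h1 = b1(h1.max_unpool3d(records[e]))
            h2 = b2(h2.max_unpool3d(records[e]))
        main = self.head_main(hm).sigmoid()
        aux_distance = self.head_t1(h1).softplus()
        aux_skeleton = self.head_t2(h2).sigmoid()
        # domain head on globally averaged bottleneck features.  The head is
        # applied twice: once through the encoder (the decorrelation path,
        # whose gradient unlearns site identity from the shared features)
        # and once on a detached copy of the latent (the classification
        # path that keeps the head an honest domain predictor without
        # feeding domain-supervision gradients back into the encoder).
        latent = bottleneck.mean(axis=(2, 3, 4))

        if train and latent.data.shape[0] > 1:
            bm = latent.data.mean(axis=0)
            bv = latent.data.var(axis=0)
            self.head_norm_mean = 0.9 * self.head_norm_mean + 0.1 * bm.astype(np.float32)
            self.head_norm_var = 0.9 * self.head_norm_var + 0.1 * bv.astype(np.float32)
        inv_std = (1.0 / np.sqrt(self.head_norm_var + 1e-6)).astype(latent.data.dtype)
        norm_shift = self.head_norm_mean.astype(latent.data.dtype)

        def head(lat, fc1, fc2):
            # standardize with the running statistics (constants w.r.t. the
            # tape) so the softmax stays out of saturation while the
            # between-sample differences the head must read are preserved
            h = (lat - norm_shift) * inv_std
            h = (h.matmul(fc1[0]) + fc1[1]).relu()
            return (h.matmul(fc2[0]) + fc2[1]).softmax(axis=-1)

        live = ((self.fc1.w, self.fc1.b), (self.fc2.w, self.fc2.b))
        frozen = tuple(
            (Tensor(w.data), Tensor(b.data)) for (w, b) in live
        )
        # decorrelation path: frozen head weights, live latent — its
        # gradient reaches only the shared encoder and unlearns site
        # identity there.  Classification path: live head weights on a
        # detached latent — keeps the head an honest domain predictor
        # without pushing domain supervision into the encoder.
        domain = head(latent, *frozen)
        domain_detached = head(Tensor(latent.data), *live)
        if not train:
            self.set_requires_grad(True)
        return {
            "main": main,
            "aux_distance": aux_distance,
            "aux_skeleton": aux_skeleton,
            "domain": domain,
            "domain_detached": domain_detached,
            "latent": latent,
        }

    __call__ = forward

    def forward_encoder(self, x, train: bool = True) -> Tensor:
        """Encoder-only pass returning the pooled bottleneck latent (N, C)."""
        t = as_tensor(np.asarray(x, dtype=np.float32) if not isinstance(x, Tensor) else x)
        if t.data.ndim != 5:
            raise ValueError("forward_encoder expects an (N, 1, D, H, W) batch")
        if not train:
            self.set_requires_grad(False)
        h = t
        for blk in self.encoder:
            h, _ = blk(h).max_pool3d()
        latent = h.mean(axis=(2, 3, 4))
        if not train:
            self.set_requires_grad(True)
        return latent

    # -- serialization ------------------------------------------------------
    def state_arrays(self) -> List[np.ndarray]:
        return [p.data for p in self.params()]

    def save(self, path) -> None:
        arrays = {f"p{i}": a for i, a in enumerate(self.state_arrays())}
        np.savez(
            path,
            __levels=self.cfg.levels,
            __base=self.cfg.base_channels,
            __shared=self.cfg.shared_decoder_levels,
            __ndom=self.cfg.n_domains,
            __patch=np.array(self.cfg.patch_shape),
            __hidden=self.cfg.domain_hidden,
            __hnm=self.head_norm_mean,
            __hnv=self.head_norm_var,
            **arrays,
        )

    @classmethod
    def load(cls, path) -> "MultiTaskVesselNet":
        with np.load(path) as z:
            cfg = ModelConfig(
                levels=int(z["__levels"]),
                base_channels=int(z["__base"]),
                shared_decoder_levels=int(z["__shared"]),
                n_domains=int(z["__ndom"]),
                patch_shape=tuple(int(v) for v in z["__patch"]),
                domain_hidden=int(z["__hidden"]),
            )
            model = cls(cfg, seed=0)
            for i, p in enumerate(model.params()):
                p.data = z[f"p{i}"].copy()
            model.head_norm_mean = z["__hnm"].copy()
            model.head_norm_var = z["__hnv"].copy()
        return model


def build_model(cfg: ModelConfig, seed: int = 0) -> MultiTaskVesselNet:
    """Construct the network with deterministic seeded initialization."""
    return MultiTaskVesselNet(cfg, seed=seed)


def count_parameters(model: MultiTaskVesselNet) -> int:
    return int(sum(p.data.size for p in model.params()))


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def _prepare_batch(patch_list: Sequence[patching.PatchRecord], dilation_radius: int):
    """Stack patches into arrays and precompute the hard theta2 maps."""
    img = np.stack([p.image for p in patch_list])[:, None].astype(np.float32)
    lab = np.stack([p.label for p in patch_list])[:, None].astype(np.float32)
    dist = np.stack([p.distance for p in patch_list])[:, None].astype(np.float32)
    phi = np.stack([p.skeleton for p in patch_list])[:, None].astype(np.float32)
    delta = np.stack(
        [
            topo.dilate(p.label, dilation_radius).data if p.label.any() else np.zeros_like(p.label)
            for p in patch_list
        ]
    )[:, None].astype(np.float32)
    return img, lab, dist, phi, delta


def _batch_loss(model, img, lab, dist, phi, delta, onehot, loss_cfg: L.LossConfig):
    out = model.forward(img, train=True)
    t3 = L.theta3(lab, out["main"], loss_cfg)
    terms = {"theta3": float(t3.data)}
    total = t3
    if loss_cfg.weight_theta1 > 0:
        t1 = L.theta1(dist, out["aux_distance"], lab, loss_cfg)
        total = total + loss_cfg.weight_theta1 * t1
        terms["theta1"] = float(as_tensor(t1).data)
    else:
        terms["theta1"] = 0.0
    if loss_cfg.weight_theta2 > 0:
        t2 = L.theta2_from_maps(phi, delta, out["main"], out["aux_skeleton"], loss_cfg)
        total = total + loss_cfg.weight_theta2 * t2
        terms["theta2"] = float(as_tensor(t2).data)
    else:
        terms["theta2"] = 0.0
    if loss_cfg.weight_dcl > 0:
        dcl = L.batch_decorrelation(out["domain"], onehot, loss_cfg, squared=True)
        # cross-entropy on the detached path keeps the head a credible
        # domain predictor; its gradient stops at the head, so the encoder
        # is shaped only by the decorrelation term
        p = out["domain_detached"]
        ce = -((p + 1e-12).log() * onehot).sum() * (1.0 / onehot.shape[0])
        total = total + loss_cfg.weight_dcl * dcl + ce
        terms["dcl"] = float(dcl.data)
        terms["domain_ce"] = float(ce.data)
    else:
        terms["dcl"] = 0.0
        terms["domain_ce"] = 0.0
    terms["total"] = float(as_tensor(total).data)
    return total, terms


def _validation_scores(model, val_patches, max_tc_patches: int = 4):
    """Mean Dice over all validation patches and TC over a small subset."""
    dices, tcs = [], []
    for i, p in enumerate(val_patches):
        out = model.forward(p.image[None, None].astype(np.float32), train=False)
        pred = (out["main"].data[0, 0] >= 0.5).astype(np.uint8)
        dices.append(M.dice(p.label, pred))
        if i < max_tc_patches and p.label.any():
            tcs.append(M.topological_coincidence(p.label, pred))
    return float(np.mean(dices)) if dices else np.nan, (
        float(np.mean(tcs)) if tcs else np.nan
    )


def train_model(
    model: MultiTaskVesselNet,
    patches: Sequence[patching.PatchRecord],
    loss_cfg: L.LossConfig = None,
    train_cfg: TrainConfig = None,
    val_patches: Sequence[patching.PatchRecord] = None,
    dcl_patches: Sequence[patching.PatchRecord] = None,
    verbose: bool = False,
) -> pd.DataFrame:
    """Train with Adam; returns the per-epoch history DataFrame.

    The default loss configuration uses per-vessel-voxel mean reduction for
    the distance term so the four task losses stay on comparable scales.
    Deterministic for a fixed seed; aborts with a diagnostic on NaN loss.
    """
    if len(patches) == 0:
        raise ValueError("empty training dataset")
    loss_cfg = loss_cfg or L.LossConfig(reduction="mean")
    train_cfg = train_cfg or TrainConfig()
    rng = np.random.default_rng(train_cfg.seed)
    head_params = model.fc1.params() + model.fc2.params()
    head_ids = {id(p) for p in head_params}
    body_params = [p for p in model.params() if id(p) not in head_ids]
    opt = Adam(body_params, lr=train_cfg.lr)
    # the domain predictor tracks the moving encoder features, so it learns
    # faster than the body it observes
    opt_head = Adam(head_params, lr=train_cfg.lr * train_cfg.head_lr_multiplier)
    n_dom = model.cfg.n_domains
    prepared = list(patches)
    if loss_cfg.weight_dcl > 0:
        # stacked images and one-hot labels for the per-epoch latent
        # decorrelation step.  A dedicated (larger) cohort sharpens the
        # correlation estimate — its sampling noise floor is ~1/(N-1) —
        # while only the cheap encoder pass runs over it.
        dcl_pool = list(dcl_patches) if dcl_patches else prepared
        dcl_pool = dcl_pool[:96]
        dcl_imgs = np.stack([p.image for p in dcl_pool])[:, None].astype(np.float32)
        dcl_onehot = np.zeros((len(dcl_pool), n_dom))
        for k, p in enumerate(dcl_pool):
            dcl_onehot[k, p.domain_index] = 1.0
        # its own optimizer: mixing this gradient into the main Adam's
        # moment estimates dilutes both objectives
        opt_dcl = Adam(body_params, lr=3 * train_cfg.lr)
    rows = []
    for epoch in range(train_cfg.epochs):
        if (
            train_cfg.head_reset_every > 0
            and epoch > 0
            and epoch % train_cfg.head_reset_every == 0
        ):
            # re-initialize the domain predictor so each phase locks onto a
            # fresh residual domain-informative direction for the encoder
            # to erase (successive-projection style unlearning)
            hrng = np.random.default_rng(train_cfg.seed + 7000 + epoch)
            model.fc1 = _Linear(model.cfg.base_channels * 2 ** (model.cfg.levels - 1),
                                model.cfg.domain_hidden, hrng)
            model.fc2 = _Linear(model.cfg.domain_hidden, model.cfg.n_domains, hrng)
            head_params = model.fc1.params() + model.fc2.params()
            opt_head = Adam(head_params, lr=train_cfg.lr * train_cfg.head_lr_multiplier)
        order = rng.permutation(len(prepared))
        epoch_terms = []
        for start in range(0, len(order), train_cfg.batch_size):
            batch = [prepared[i] for i in order[start : start + train_cfg.batch_size]]
            img, lab, dist, phi, delta = _prepare_batch(batch, loss_cfg.dilation_radius)
            onehot = np.zeros((len(batch), n_dom))
            for i, p in enumerate(batch):
                onehot[i, p.domain_index] = 1.0
            opt.zero_grad()
            opt_head.zero_grad()
            total, terms = _batch_loss(model, img, lab, dist, phi, delta, onehot, loss_cfg)
            if not np.isfinite(terms["total"]):
                raise RuntimeError(
                    f"NaN/inf loss at epoch {epoch}: {terms} — aborting training"
                )
            total.backward()
            opt.step()
            opt_head.step()
            epoch_terms.append(terms)
        if loss_cfg.weight_dcl > 0:
            # dedicated latent-decorrelation step: a fresh, full-cohort
            # correlation estimate through the encoder only.  Driving every
            # pooled feature's correlation with the site label to zero
            # equalizes per-feature site means, which is what removes the
            # linearly decodable site identity from the representation.
            opt_dcl.zero_grad()
            latent = model.forward_encoder(dcl_imgs, train=True)
            md = L.domain_mean_discrepancy(latent, dcl_onehot)
            (loss_cfg.weight_dcl * 10.0 * md).backward()
            opt_dcl.step()
            for t in epoch_terms:
                t["feature_dcl"] = float(md.data)
        else:
            for t in epoch_terms:
                t["feature_dcl"] = 0.0
        mean_terms = {k: float(np.mean([t[k] for t in epoch_terms])) for k in epoch_terms[0]}
        val_dice, val_tc = (np.nan, np.nan)
        if val_patches:
            val_dice, val_tc = _validation_scores(model, val_patches)
        row = {"epoch": epoch, **mean_terms, "val_dice": val_dice, "val_tc": val_tc}
        rows.append(row)
        if verbose:
            print(
                f"epoch {epoch:3d} total={mean_terms['total']:.4f} "
                f"theta3={mean_terms['theta3']:.4f} val_dice={val_dice:.4f}"
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# inference and probing
# ---------------------------------------------------------------------------


def predict_volume(
    model: MultiTaskVesselNet,
    v: VolumeImage,
    threshold: float = 0.5,
    normalize: bool = True,
) -> Tuple[ProbabilityMap, LabelMap]:
    """Segment a whole volume with non-overlapping patch tiling.

    The stitched probability at any voxel equals the forward output of the
    unique patch containing it; padding introduced by tiling is cropped.
    """
    vol = normalize_intensity(v) if normalize else v
    tiles, origins, _ = patching.tile_volume(vol.data, model.cfg.patch_shape)
    probs = []
    for tile in tiles:
        out = model.forward(tile[None, None].astype(np.float32), train=False)
        probs.append(out["main"].data[0, 0])
    stitched = patching.stitch(probs, origins, vol.data.shape)
    prob = ProbabilityMap(np.clip(stitched, 0.0, 1.0), spacing=v.spacing)
    return prob, prob.threshold(threshold)


def encoder_latents(model: MultiTaskVesselNet, patches, batch_size: int = 8) -> np.ndarray:
    """Global-average-pooled bottleneck features for a list of patches."""
    feats = []
    for start in range(0, len(patches), batch_size):
        chunk = patches[start : start + batch_size]
        img = np.stack([p.image for p in chunk])[:, None].astype(np.float32)
        feats.append(model.forward_encoder(img, train=False).data)
    return np.concatenate(feats, axis=0)


def domain_probe_accuracy(
    model: MultiTaskVesselNet,
    patches,
    seed: int = 0,
    test_fraction: float = 0.5,
) -> float:
    """Accuracy of a fresh linear probe predicting the domain from latents.

    Trains a multinomial logistic regression on the encoder latents of the
    supplied patches and reports held-out accuracy.  When the patches carry
    case ids with more than one volume per domain, the split is by volume,
    so the probe cannot score by memorizing volume identity — it must use
    features that generalize across volumes of a site.  Near-chance
    accuracy means the encoder no longer carries site identity.
    """
    from sklearn.linear_model import LogisticRegression

    X = encoder_latents(model, patches)
    y = np.array([p.domain_index for p in patches])
    rng = np.random.default_rng(seed)
    groups = np.array([p.case_id for p in patches])
    by_domain = {}
    for g, d in zip(groups, y):
        by_domain.setdefault(int(d), set()).add(g)
    groupable = all(len(v) > 1 for v in by_domain.values()) and len(set(groups)) > len(
        by_domain
    )
    if groupable:
        test_groups = set()
        for d, gs in sorted(by_domain.items()):
            gs = sorted(gs)
            k = max(1, int(round(len(gs) * test_fraction)))
            test_groups.update(rng.permutation(gs)[:k])
        test_mask = np.isin(groups, sorted(test_groups))
    else:
        order = rng.permutation(len(y))
        test_mask = np.zeros(len(y), dtype=bool)
        test_mask[order[: max(1, int(len(y) * test_fraction))]] = True
    train_idx, test_idx = np.where(~test_mask)[0], np.where(test_mask)[0]
    mu, sd = X[train_idx].mean(axis=0), X[train_idx].std(axis=0) + 1e-9
    Xs = (X - mu) / sd
    clf = LogisticRegression(max_iter=2000, C=0.1)
    clf.fit(Xs[train_idx], y[train_idx])
    return float((clf.predict(Xs[test_idx]) == y[test_idx]).mean())
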