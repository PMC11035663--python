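"""Differentiable training objectives for the multi-task network.

Four terms:

* ``theta1`` — smooth-L1 regression of the surface distance transform,
  summed over vessel voxels only (the auxiliary distance task);
* ``theta2`` — topological-coincidence loss coupling the predicted
  centerline map to the ground-truth skeleton/dilation and, through a
  differentiable soft dilation, to the main-task prediction;
* ``theta3`` — soft Dice on the main segmentation;
* ``decorrelation_loss`` — Pearson correlation between the predicted and
  one-hot true domain vectors, whose minimisation removes scanner/site
  identity from the shared encoder.

Every public function accepts either plain numpy arrays (returning a float)
or autodiff :class:`~vesseltopo.autodiff.Tensor` objects (returning a
Tensor through which gradients flow).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import topo
from .autodiff import Tensor, as_tensor, where

__all__ = [
    "LossConfig",
    "smooth_l1",
    "theta1",
    "theta2",
    "theta3",
    "decorrelation_loss",
    "total_loss",
]


@dataclass
class LossConfig:
    """Loss hyper-parameters.

    beta : smooth-L1 quadratic/linear crossover (distance-map units).
    epsilon : stabiliser in the soft-Dice and TC-loss ratios.
    weight_theta1 / weight_theta2 / weight_dcl : task weights; the main soft
        Dice always has weight 1.
    reduction : 'sum' (default) or 'mean' over vessel voxels for theta1.
    dcl_form : 'pearson' (standard correlation, default) or 'printed'
        (denominator sqrt(sum (p-p̄)²(d-d̄)²)).
    dilation_radius : radius of the hard ground-truth dilation in theta2.
    """

    beta: float = 1.0
    epsilon: float = 1e-6
    weight_theta1: float = 1.0
    weight_theta2: float = 1.0
    weight_dcl: float = 0.1
    reduction: str = "sum"
    dcl_form: str = "pearson"
    dilation_radius: int = 1

    def __post_init__(self):
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if min(self.weight_theta1, self.weight_theta2, self.weight_dcl) < 0:
            raise ValueError("loss weights must be non-negative")
        if self.reduction not in ("sum", "mean"):
            raise ValueError("reduction must be 'sum' or 'mean'")
        if self.dcl_form not in ("pearson", "printed"):
            raise ValueError("dcl_form must be 'pearson' or 'printed'")


def _maybe_float(out: Tensor, *inputs) -> "Tensor | float":
    if any(isinstance(x, Tensor) for x in inputs):
        return out
    return float(out.data)


def _arr(x) -> np.ndarray:
    if isinstance(x, Tensor):
        return x.data
    if hasattr(x, "data"):
        x = x.data
    arr = np.asarray(x)
    return arr if arr.dtype.kind == "f" else arr.astype(np.float64)


def smooth_l1(z, beta: float = 1.0):
    """Piecewise loss: 0.5 z²/β for |z| < β, |z| − 0.5 β otherwise.

    Quadratic near zero, linear in the tails, continuous at |z| = β; the
    linear tails keep large residuals from dominating the gradient.
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    zt = as_tensor(z)
    quad = zt.square() * (0.5 / beta)
    lin = zt.abs() - 0.5 * beta
    out = where(np.abs(zt.data) < beta, quad, lin)
    return _maybe_float(out, z)


def theta1(D_true, J1_pred, L, cfg: LossConfig = None):
    """Smooth-L1 distance-regression loss over vessel voxels only.

    Background voxels contribute nothing; an empty vessel set yields zero
    loss with a warning.
    """
    cfg = cfg or LossConfig()
    d = _arr(D_true)
    mask = (_arr(L) > 0).astype(d.dtype)
    if d.shape != mask.shape:
        raise ValueError("theta1: shape mismatch")
    pred_shape = _arr(J1_pred).shape
    if pred_shape != mask.shape:
        if pred_shape[-3:] != mask.shape[-3:] or mask.ndim != 3:
            raise ValueError("theta1: shape mismatch")
        d = np.broadcast_to(d, pred_shape)
        mask = np.broadcast_to(mask, pred_shape)
    nv = mask.sum()
    if nv == 0:
        warnings.warn("theta1: empty vessel set, loss is 0", stacklevel=2)
        return _maybe_float(as_tensor(0.0), J1_pred)
    j1 = as_tensor(J1_pred)
    resid = (as_tensor(d) - j1) * mask  # smooth_l1(0) = 0 on background
    per_voxel = smooth_l1(resid, beta=cfg.beta)
    out = per_voxel.sum()
    if cfg.reduction == "mean":
        out = out * (1.0 / nv)
    return _maybe_float(out, J1_pred)


def theta2(L, L_pred, J2_pred, cfg: LossConfig = None):
    """Topological-coincidence loss.

    1 − (Σ Ĵ2·δ_L + Σ δ_{L̂}·φ_L + ε) / (Σ Ĵ2 + Σ φ_L + ε)

    φ_L and δ_L are the hard skeleton/dilation of the ground truth; δ_{L̂}
    is a stride-1 3x3x3 max filter of the main-task probability map so the
    term stays differentiable w.r.t. both network outputs.
    """
    cfg = cfg or LossConfig()
    mask = (_arr(L) > 0).astype(np.uint8)
    lp = as_tensor(L_pred)
    if lp.data.shape[-3:] != mask.shape[-3:]:
        raise ValueError("theta2: shape mismatch")
    phi = topo.skeletonize(mask).data.astype(np.float64)
    delta = (
        topo.dilate(mask, cfg.dilation_radius).data.astype(np.float64)
        if mask.any()
        else np.zeros(mask.shape)
    )
    extra = lp.data.ndim - 3
    if extra:  # broadcast the hard maps over leading batch/channel axes
        phi = np.broadcast_to(phi, lp.data.shape)
        delta = np.broadcast_to(delta, lp.data.shape)
    out = theta2_from_maps(phi, delta, L_pred, J2_pred, cfg)
    return _maybe_float(as_tensor(out), L_pred, J2_pred)


def theta2_from_maps(phi, delta, L_pred, J2_pred, cfg: LossConfig = None):
    """Topological-coincidence loss from precomputed hard skeleton/dilation.

    ``phi`` and ``delta`` must already have the predictions' full shape
    (per-sample maps stacked for a batch).  This is the training-loop entry
    point: skeletons of the ground truth are computed once per patch, not
    per step.
    """
    cfg = cfg or LossConfig()
    phi = _arr(phi)
    delta = _arr(delta)
    lp, j2 = as_tensor(L_pred), as_tensor(J2_pred)
    if lp.data.shape != phi.shape or j2.data.shape != phi.shape or delta.shape != phi.shape:
        raise ValueError("theta2: shape mismatch")
    if lp.data.ndim == 5:
        soft_dil = lp.max_filter3()
    else:
        soft_dil = lp.reshape((1, 1) + lp.data.shape[-3:]).max_filter3().reshape(lp.data.shape)
    eps = cfg.epsilon
    num = (j2 * delta).sum() + (soft_dil * phi).sum() + eps
    den = j2.sum() + phi.sum() + eps
    out = 1.0 - num / den
    return _maybe_float(out, L_pred, J2_pred)


def theta3(L, L_pred, cfg: LossConfig = None):
    """Soft Dice loss 1 − (2 Σ L·L̂ + ε)/(Σ L + Σ L̂ + ε)."""
    cfg = cfg or LossConfig()
    lp = as_tensor(L_pred)
    lab = (_arr(L) > 0).astype(lp.data.dtype)
    if lp.data.shape != lab.shape:
        if lp.data.shape[-3:] != lab.shape[-3:] or lab.ndim != 3:
            raise ValueError("theta3: shape mismatch")
        lab = np.broadcast_to(lab, lp.data.shape)
    eps = cfg.epsilon
    num = (lp * lab).sum() * 2.0 + eps
    den = lab.sum() + lp.sum() + eps
    out = 1.0 - num / den
    return _maybe_float(out, L_pred)


def _pearson(p: Tensor, d: np.ndarray, form: str):
    n = d.size
    dm = d - d.mean()
    pm = p - p.sum() * (1.0 / n)
    if form == "pearson":
        denom_sq = pm.square().sum() * float((dm**2).sum())
    else:  # the alternative printed form
        denom_sq = (pm.square() * (dm**2)).sum()
    if float(denom_sq.data) < 1e-24:  # zero-variance guard (e.g. uniform p)
        return as_tensor(0.0)
    return (pm * dm).sum() / denom_sq.sqrt()


def decorrelation_loss(rec=None, prediction=None, true_label=None, cfg: LossConfig = None):
    """Pearson correlation between predicted and one-hot true domain vectors.

    Accepts either a :class:`~vesseltopo.core.DomainRecord` or explicit
    ``prediction`` / ``true_label`` vectors.  Returns a value in [−1, 1];
    0 when either vector is (numerically) constant, e.g. a uniform
    prediction — the fully domain-agnostic output.
    """
    cfg = cfg or LossConfig()
    if rec is not None and prediction is None:
        prediction, true_label = rec.prediction, rec.true_label
    d = np.asarray(_arr(true_label), dtype=np.float64)
    if d.size < 2:
        raise ValueError("decorrelation loss needs at least 2 domains")
    p = as_tensor(prediction)
    if p.data.shape != d.shape:
        raise ValueError("domain prediction/label length mismatch")
    out = _pearson(p, d, cfg.dcl_form)
    return _maybe_float(out, prediction)


def batch_decorrelation(pred: Tensor, onehot: np.ndarray, cfg: LossConfig, squared: bool = True):
    """Per-sample domain correlation, optionally squared, averaged over a batch.

    Squaring makes zero correlation — rather than anti-correlation — the
    optimum, which is the domain-agnostic target of the unlearning scheme.
    """
    n = pred.data.shape[0]
    terms = []
    for i in range(n):
        c = _pearson(_row(pred, i), onehot[i], cfg.dcl_form)
        terms.append(c.square() if squared else c)
    out = terms[0]
    for t in terms[1:]:
        out = out + t
    return out * (1.0 / n)


def batch_feature_decorrelation(latent: Tensor, onehot: np.ndarray):
    """Mean squared Pearson correlation, across the batch, between every
    latent feature and every domain indicator.

    This is the latent-level form of the decorrelation objective: its
    minimum is a representation in which no feature carries a first-order
    (linear) domain signal, which is what drives a linear domain probe
    toward chance.  Requires a batch containing more than one domain to be
    informative; batches from a single domain contribute zero (the domain
    indicators are constant).
    """
    lat = as_tensor(latent)
    d = np.asarray(onehot, dtype=np.float64)
    n = lat.data.shape[0]
    if n < 2:
        return as_tensor(0.0)
    dm = d - d.mean(axis=0, keepdims=True)
    d_norm = np.sqrt((dm**2).sum(axis=0))
    keep = d_norm > 1e-12
    if not keep.any():
        return as_tensor(0.0)
    dmn = np.where(keep, 1.0, 0.0) * dm / np.where(keep, d_norm, 1.0)
    zm = lat - lat.mean(axis=0, keepdims=True)
    z_norm_sq = zm.square().sum(axis=0)  # (C,)
    # correlations: (C, n) = zm^T @ dmn, normalized per feature
    cross = Tensor.matmul(_transpose2d(zm), as_tensor(dmn))
    denom = (z_norm_sq + 1e-12).reshape(z_norm_sq.data.shape[0], 1)
    corr_sq = cross.square() / denom
    return corr_sq.sum() * (1.0 / (lat.data.shape[1] * int(keep.sum())))


def domain_mean_discrepancy(latent: Tensor, onehot: np.ndarray, moments: int = 2):
    """Variance-normalized spread of per-domain latent statistics.

    For each feature, the squared deviations of the per-domain means from
    the grand mean are divided by the feature's overall variance; zero
    exactly when every feature has equal means across domains — the same
    optimum as zero feature-domain Pearson correlation, but with gradients
    well-scaled for every feature regardless of its variance.  With
    ``moments=2`` the same discrepancy is added for the centered squares,
    equalizing per-domain feature variances as well; a linear probe on
    standardized latents exploits both statistics.
    """
    lat = as_tensor(latent)
    d = np.asarray(onehot, dtype=np.float64)
    n, n_dom = d.shape
    counts = d.sum(axis=0)
    keep = counts > 0
    if keep.sum() < 2 or n < 2:
        return as_tensor(0.0)
    sel = (d / np.maximum(counts, 1)).T.astype(lat.data.dtype)  # (n_dom, N)
    w = (counts / n).reshape(n_dom, 1).astype(lat.data.dtype)

    def _discrepancy(feats: Tensor):
        mu_dom = as_tensor(sel).matmul(feats)  # (n_dom, C) per-domain means
        mu_all = feats.mean(axis=0, keepdims=True)  # (1, C)
        varf = (feats - mu_all).square().mean(axis=0, keepdims=True) + 1e-6
        dev = (mu_dom - mu_all).square() / varf
        return (dev * w).sum() * (1.0 / feats.data.shape[1])

    out = _discrepancy(lat)
    if moments >= 2:
        centered_sq = (lat - lat.mean(axis=0, keepdims=True)).square()
        out = out + _discrepancy(centered_sq)
    return out


def _transpose2d(t: Tensor) -> Tensor:
    out = Tensor(t.data.T.copy(), t.requires_grad)
    if out.requires_grad:
        out._parents = (t,)

        def bwd(g):
            t._accum(g.T)

        out._backward = bwd
    return out


def _row(t: Tensor, i: int) -> Tensor:
    """Differentiable row view of a 2D tensor."""
    out = Tensor(t.data[i], t.requires_grad)
    if out.requires_grad:
        out._parents = (t,)

        def bwd(g):
            gg = np.zeros_like(t.data)
            gg[i] = g
            t._accum(gg)

        out._backward = bwd
    return out


def total_loss(
    L,
    L_pred,
    J1_pred=None,
    J2_pred=None,
    D_true=None,
    domain_pred=None,
    domain_onehot=None,
    cfg: LossConfig = None,
):
    """Weighted multi-task objective and its per-term breakdown.

    total = θ3 + w1·θ1 + w2·θ2 + wd·DcL²

    The decorrelation term enters squared: the raw correlation is minimised
    at anti-correlation, which still encodes the domain, whereas the squared
    form is minimised exactly at zero correlation (domain-agnostic
    features).  Terms whose inputs are not supplied are skipped (weight
    effectively 0) and reported as 0.0 in the breakdown.
    """
    cfg = cfg or LossConfig()
    terms = {}
    t3 = theta3(L, L_pred, cfg)
    total = as_tensor(t3)
    terms["theta3"] = float(as_tensor(t3).data)
    if J1_pred is not None and cfg.weight_theta1 > 0:
        t1 = theta1(D_true, J1_pred, L, cfg)
        total = total + cfg.weight_theta1 * as_tensor(t1)
        terms["theta1"] = float(as_tensor(t1).data)
    else:
        terms["theta1"] = 0.0
    if J2_pred is not None and cfg.weight_theta2 > 0:
        t2 = theta2(L, L_pred, J2_pred, cfg)
        total = total + cfg.weight_theta2 * as_tensor(t2)
        terms["theta2"] = float(as_tensor(t2).data)
    else:
        terms["theta2"] = 0.0
    if domain_pred is not None and cfg.weight_dcl > 0:
        dp = as_tensor(domain_pred)
        onehot = np.atleast_2d(np.asarray(_arr(domain_onehot), dtype=np.float64))
        if dp.data.ndim == 1:
            dp = dp.reshape(1, dp.data.size)
        dcl = batch_decorrelation(dp, onehot, cfg, squared=True)
        total = total + cfg.weight_dcl * dcl
        terms["dcl"] = float(dcl.data)
    else:
        terms["dcl"] = 0.0
    terms["total"] = float(as_tensor(total).data)
    inputs = (L_pred, J1_pred, J2_pred, domain_pred)
    return _maybe_float(as_tensor(total), *inputs), terms
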