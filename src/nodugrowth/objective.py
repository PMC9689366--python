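"""Loss functions and the training loop.

The reconstruction loss is a soft intersection-over-union term between
the predicted and reference future masks plus a gamma-weighted L1 term
between the longest diameter measured on the prediction and the
annotated follow-up diameter (both in mm).  Since a hard Feret diameter
is not differentiable, the predicted diameter is measured with a
smooth caliper: pixel coordinates are projected onto a fan of
directions and, per direction, softmax- and softmin-weighted mean
projections give a differentiable extent; the largest directional
extent plus one (mass-gated) pixel, scaled by the spacing, is the soft
diameter.  The evidence lower bound adds the beta-weighted closed-form
KL divergence between the posterior and prior latent hierarchies,
estimated with the single reparameterized draw per step that also
drives the reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from ._autodiff import Adam, Tensor
from .cohort_io import Cohort, PATCH_SIZE
from .hpnet import HPNet, LatentHierarchy, NetworkConfig

__all__ = [
    "TrainingConfig",
    "soft_iou_loss",
    "soft_longest_diameter",
    "reconstruction_loss",
    "kl_hierarchy",
    "elbo_loss",
    "train",
]

_EPS = 1e-6


@dataclass
class TrainingConfig:
    gamma: float = 1.0 / 8.0  # diameter-loss weight
    beta: float = 1.0  # KL weight
    learning_rate: float = 1e-4
    batch_size: int = 8
    epochs: int = 200
    reconstruction_mode: str = "iou_l1"  # {iou_l1, iou_only, bce}
    #: "soft" measures the predicted diameter with the differentiable
    #: caliper; "hard" measures the 0.5-thresholded mask with the exact
    #: extractor (gradients then flow only through the IoU term)
    diameter_mode: str = "soft"
    rotation_deg: float = 15.0
    translation_px: int = 3
    augment: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.gamma < 0 or self.beta < 0:
            raise ValueError("gamma and beta must be >= 0")
        if self.learning_rate <= 0 or self.batch_size < 1 or self.epochs < 0:
            raise ValueError("invalid optimizer settings")
        if self.reconstruction_mode not in ("iou_l1", "iou_only", "bce"):
            raise ValueError(f"unknown reconstruction mode {self.reconstruction_mode}")
        if self.diameter_mode not in ("soft", "hard"):
            raise ValueError(f"unknown diameter mode {self.diameter_mode}")


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


def _flatten_pixels(t: Tensor) -> Tensor:
    """(..., H, W) -> (N, H*W) with N the product of leading axes."""
    shape = t.data.shape
    n = int(np.prod(shape[:-2])) if len(shape) > 2 else 1
    return t.reshape(n, shape[-2] * shape[-1])


def soft_iou_loss(pred, target) -> Tensor:
    """1 - soft Jaccard index, averaged over the batch; 0 on identity."""
    pred, target = _as_tensor(pred), _as_tensor(target)
    if pred.data.shape != target.data.shape:
        raise ValueError(
            f"shape mismatch {pred.data.shape} vs {target.data.shape}"
        )
    p, y = _flatten_pixels(pred), _flatten_pixels(target)
    inter = (p * y).sum(axis=1)
    union = p.sum(axis=1) + y.sum(axis=1) - inter
    iou = (inter + _EPS) * (union + _EPS) ** -1.0
    return (1.0 - iou).mean()


def _direction_projections(n_directions: int) -> np.ndarray:
    """(D, H*W) pixel-centre projections onto directions theta in [0, pi)."""
    centre = (PATCH_SIZE - 1) / 2.0
    rows, cols = np.mgrid[0:PATCH_SIZE, 0:PATCH_SIZE]
    dy = (rows - centre).ravel()
    dx = (cols - centre).ravel()
    thetas = np.arange(n_directions) * np.pi / n_directions
    return np.cos(thetas)[:, None] * dy[None, :] + np.sin(thetas)[:, None] * dx[None, :]


def soft_longest_diameter(
    pred, spacing_mm=1.0, temperature: float = 4.0, n_directions: int = 24
):
    """Differentiable longest-diameter estimate in mm.

    Per direction, the soft extent is the difference between the
    softmax- and softmin-weighted mean projections of pixel centres,
    with weights ``mask * exp(+/- T * projection)``; the reported
    diameter is the largest directional extent plus a mass-gated pixel
    extent, times the spacing.  On binary masks it agrees with the hard
    extractor to within half a pixel at temperature 8; an empty mask
    measures approximately 0.

    Accepts a (H,W) mask or an (N,1,H,W)/(N,H,W) batch (then
    ``spacing_mm`` may be a length-N vector); returns a Tensor — call
    ``.item()``/``.data`` for values.
    """
    pred = _as_tensor(pred)
    single = pred.data.ndim == 2
    w = _flatten_pixels(pred)  # (N, P)
    n = w.data.shape[0]
    support = w.data > 1e-3  # (N, P); stabilisation shift per sample
    proj = _direction_projections(n_directions)  # (D, P)
    extents = []
    for k in range(n_directions):
        p = proj[k]
        # shift the exponent to the mask's own extremes so the weights
        # neither overflow nor underflow; the exp factors are constants
        # of the graph (gradients flow through the mask values)
        c_hi = np.where(support, p, -np.inf).max(axis=1)
        c_hi = np.where(np.isfinite(c_hi), c_hi, 0.0)
        c_lo = np.where(support, p, np.inf).min(axis=1)
        c_lo = np.where(np.isfinite(c_lo), c_lo, 0.0)
        up = Tensor(np.exp(np.clip(temperature * (p - c_hi[:, None]), -745, 30)))
        dn = Tensor(np.exp(np.clip(-temperature * (p - c_lo[:, None]), -745, 30)))
        wu, wd = w * up, w * dn
        hi = (wu * Tensor(p)).sum(axis=1) * ((wu.sum(axis=1) + _EPS) ** -1.0)
        lo = (wd * Tensor(p)).sum(axis=1) * ((wd.sum(axis=1) + _EPS) ** -1.0)
        extents.append((hi - lo).reshape(n, 1))
    from ._autodiff import concat

    extent = concat(extents, axis=1).max(axis=1)  # (N,)
    mass = w.sum(axis=1)
    gate = mass * ((mass + 0.1) ** -1.0)
    diam = (extent + gate) * _as_tensor(np.broadcast_to(np.asarray(spacing_mm, dtype=np.float64), (n,)).copy())
    return diam.reshape(()) if single else diam


def _bce(pred: Tensor, target: Tensor) -> Tensor:
    p, y = _flatten_pixels(pred), _flatten_pixels(target)
    eps = 1e-7
    return -(y * (p + eps).log() + (1.0 - y) * (1.0 - p + eps).log()).mean()


def reconstruction_loss(
    pred, target_mask, target_d1_mm, spacing_mm, config: TrainingConfig
) -> Tensor:
    """Mode iou_l1: soft IoU + gamma * |soft diameter - D1| (mm);
    iou_only drops the diameter term; bce is per-pixel cross-entropy."""
    pred, target_mask = _as_tensor(pred), _as_tensor(target_mask)
    if config.reconstruction_mode == "bce":
        return _bce(pred, target_mask)
    loss = soft_iou_loss(pred, target_mask)
    if config.reconstruction_mode == "iou_l1" and config.gamma > 0:
        d_true = _as_tensor(np.atleast_1d(np.asarray(target_d1_mm, dtype=np.float64)))
        if config.diameter_mode == "hard":
            from .growth_inference import extract_longest_diameter

            batch = pred.data.reshape(-1, *pred.data.shape[-2:])
            spac = np.broadcast_to(
                np.asarray(spacing_mm, dtype=np.float64), (len(batch),)
            )
            d_pred = _as_tensor(
                np.array(
                    [
                        extract_longest_diameter(m > 0.5, s)
                        for m, s in zip(batch, spac)
                    ]
                )
            )
        else:
            d_pred = soft_longest_diameter(pred, spacing_mm)
        loss = loss + config.gamma * (d_pred - d_true).abs().mean()
    return loss


def kl_hierarchy(posterior: LatentHierarchy, prior: LatentHierarchy) -> Tensor:
    """Closed-form KL(q || p) between diagonal Gaussians, summed over the
    4 levels and all grid cells, averaged over the batch."""
    if len(posterior.levels) != len(prior.levels):
        raise ValueError("hierarchies have different depths")
    total = None
    for q, p in zip(posterior.levels, prior.levels):
        mq, sq = _as_tensor(q.mean), _as_tensor(q.std)
        mp, sp = _as_tensor(p.mean), _as_tensor(p.std)
        if mq.data.shape != mp.data.shape:
            raise ValueError("level structure mismatch between hierarchies")
        ratio = sq * sp ** -1.0
        term = (
            (sp * sq ** -1.0).log()
            + 0.5 * (ratio * ratio + ((mq - mp) * sp ** -1.0) ** 2.0)
            - 0.5
        )
        n = term.data.shape[0] if term.data.ndim == 4 else 1
        level_kl = term.sum() * (1.0 / n)
        total = level_kl if total is None else total + level_kl
    return total


def elbo_loss(record_batch: dict, model: HPNet, config: TrainingConfig, rng):
    """Reconstruction + beta * KL for one batch; returns (total, Lrec, KL)."""
    recon, prior_h, post_h = model.forward_train(
        record_batch["x0"], record_batch["x1"],
        record_batch["t_norm"], record_batch["d_norm"], rng,
    )
    lrec = reconstruction_loss(
        recon, record_batch["y1"], record_batch["d1_mm"],
        record_batch["spacing_mm"], config,
    )
    kl = kl_hierarchy(post_h, prior_h)
    total = lrec + config.beta * kl
    if not np.isfinite(total.data).all():
        raise RuntimeError(
            f"non-finite loss (Lrec={lrec.item():.4g}, KL={kl.item():.4g})"
        )
    return total, lrec, kl


# -- training loop -----------------------------------------------------


def _augment_pair(arrays, rng, config: TrainingConfig):
    """Apply one random rotation + translation to every array in the pair.

    Images are interpolated bilinearly, masks nearest-neighbour; the
    same transform is applied to all arrays of one record.
    """
    angle = rng.uniform(-config.rotation_deg, config.rotation_deg)
    shift = rng.integers(-config.translation_px, config.translation_px + 1, size=2)
    out = []
    for arr, is_mask in arrays:
        order = 0 if is_mask else 1
        a = ndimage.rotate(arr, angle, reshape=False, order=order, mode="constant")
        a = ndimage.shift(a, shift, order=order, mode="constant")
        if is_mask:
            a = (a > 0.5).astype(np.float64)
        else:
            a = np.clip(a, 0.0, 1.0)
        out.append(a)
    return out


def _batch_arrays(records, rng, config: TrainingConfig) -> dict:
    x0, x1, y1, t, d, d1, sp = [], [], [], [], [], [], []
    for r in records:
        img0, img1, m1 = r.image_t0, r.image_t1, r.mask_t1.astype(np.float64)
        if config.augment and rng is not None:
            img0, img1, m1 = _augment_pair(
                [(img0, False), (img1, False), (m1, True)], rng, config
            )
        x0.append(img0)
        x1.append(img1)
        y1.append(m1)
        tn, dn = r.conditioning()
        t.append(tn)
        d.append(dn)
        d1.append(r.d1_mm)
        sp.append(r.spacing_mm)
    return {
        "x0": np.asarray(x0)[:, None],
        "x1": np.asarray(x1)[:, None],
        "y1": np.asarray(y1)[:, None],
        "t_norm": np.asarray(t),
        "d_norm": np.asarray(d),
        "d1_mm": np.asarray(d1),
        "spacing_mm": np.asarray(sp),
    }


def train(
    cohort: Cohort,
    net_config: NetworkConfig | None = None,
    train_config: TrainingConfig | None = None,
    model: HPNet | None = None,
    verbose: bool = False,
):
    """Adam optimisation of the ELBO on a cohort with both time points.

    Returns (model, history) where history is a list of per-epoch dicts
    with keys epoch, lrec, kl, total (mean over batches).
    """
    cfg = train_config or TrainingConfig()
    if len(cohort) == 0:
        raise ValueError("cannot train on an empty cohort")
    for r in cohort:
        if r.image_t1 is None or r.mask_t1 is None or r.d1_mm is None:
            raise ValueError(
                f"record {r.nodule_id}/{r.annotator_id} lacks follow-up data"
            )
    model = model or HPNet(net_config or NetworkConfig())
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.params(), lr=cfg.learning_rate)
    history = []
    records = list(cohort)
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(records))
        sums = np.zeros(3)
        n_batches = 0
        for start in range(0, len(records), cfg.batch_size):
            batch = [records[i] for i in order[start : start + cfg.batch_size]]
            arrays = _batch_arrays(batch, rng, cfg)
            total, lrec, kl = elbo_loss(arrays, model, cfg, rng)
            opt.zero_grad()
            total.backward()
            opt.step()
            sums += (lrec.item(), kl.item(), total.item())
            n_batches += 1
        means = sums / n_batches
        history.append(
            {"epoch": epoch, "lrec": means[0], "kl": means[1], "total": means[2]}
        )
        if verbose:
            print(
                f"epoch {epoch:3d}  Lrec {means[0]:.4f}  KL {means[1]:.4f}  "
                f"total {means[2]:.4f}"
            )
    return model, history
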