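"""Hierarchical probabilistic U-ResNet for future nodule segmentation.

Two structurally identical encoder-decoder subnets: the *prior* sees
only the baseline patch I0 (plus the normalized time-to-predict and
baseline diameter, tiled onto the encoder output), the *posterior*
additionally receives the follow-up patch I1.  Four latent blocks of
flattened dimensions 1, 4, 16 and 64 (one-channel grids of 1x1, 2x2,
4x4, 8x8) are interleaved coarse-to-fine in the decoder; each block
emits diagonal-Gaussian parameters, a latent grid is sampled by
reparameterization and concatenated back into the decoder features, so
finer latent distributions are conditioned on the coarser draws.

During training the prior decoder is run with the posterior's latent
samples injected at every level; at inference the prior samples its own
latents, and repeated forward passes yield the Monte-Carlo segmentation
samples consumed by :mod:`nodugrowth.growth_inference`.  Attention
gates multiplicatively weight each skip connection before concatenation
and can be disabled for ablation, as can the diameter input.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._autodiff import (
    Tensor,
    avg_pool2d,
    concat,
    conv2d,
    no_grad,
    slice_channels,
    upsample2x,
)
from .cohort_io import PATCH_SIZE

__all__ = ["NetworkConfig", "LatentLevel", "LatentHierarchy", "HPNet",
           "sample_latent", "save_checkpoint", "load_checkpoint"]

#: flattened latent dimensions, coarse to fine (grids 1x1, 2x2, 4x4, 8x8)
LATENT_DIMS = (1, 4, 16, 64)
_LATENT_GRIDS = (1, 2, 4, 8)
_STD_FLOOR = 1e-5


@dataclass
class NetworkConfig:
    base_filters: int = 32
    depth: int = 4  # resolution levels of the U-ResNet ladder; fixed
    use_attention: bool = True
    use_d0_input: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.depth != 4:
            raise ValueError("depth is fixed at 4 by the latent-block layout")
        if self.base_filters < 1:
            raise ValueError("base_filters must be positive")


@dataclass
class LatentLevel:
    mean: object  # ndarray or Tensor, shape (N, 1, g, g)
    std: object
    z: object | None = None

    def _np(self, x):
        return x.data if isinstance(x, Tensor) else np.asarray(x)

    @property
    def flat_dim(self) -> int:
        m = self._np(self.mean)
        return int(np.prod(m.shape[-2:]))


@dataclass
class LatentHierarchy:
    """Per-level diagonal-Gaussian parameters and sampled latents."""

    levels: list[LatentLevel] = field(default_factory=list)

    def __post_init__(self):
        self.validate()

    def validate(self):
        if len(self.levels) != 4:
            raise ValueError("latent hierarchy must have exactly 4 levels")
        dims = tuple(lv.flat_dim for lv in self.levels)
        if dims != LATENT_DIMS:
            raise ValueError(f"latent dims {dims}, expected {LATENT_DIMS}")
        for lv in self.levels:
            if (lv._np(lv.std) <= 0).any():
                raise ValueError("latent std must be strictly positive")

    def numpy(self) -> "LatentHierarchy":
        return LatentHierarchy(
            [
                LatentLevel(
                    lv._np(lv.mean),
                    lv._np(lv.std),
                    None if lv.z is None else lv._np(lv.z),
                )
                for lv in self.levels
            ]
        )


def sample_latent(mean, std, rng: np.random.Generator):
    """Reparameterized draw z = mean + std * eps with eps ~ N(0, I)."""
    m = mean.data if isinstance(mean, Tensor) else np.asarray(mean)
    if isinstance(std, Tensor):
        if (std.data < 0).any():
            raise ValueError("latent std must be non-negative")
    elif (np.asarray(std) < 0).any():
        raise ValueError("latent std must be non-negative")
    eps = rng.standard_normal(m.shape)
    if isinstance(mean, Tensor) or isinstance(std, Tensor):
        mean = mean if isinstance(mean, Tensor) else Tensor(mean)
        std = std if isinstance(std, Tensor) else Tensor(std)
        return mean + std * Tensor(eps)
    return m + np.asarray(std) * eps


# -- layers ------------------------------------------------------------


class _Conv:
    def __init__(self, cin, cout, k, rng, bias_init=0.0):
        fan_in = cin * k * k
        w = rng.standard_normal((cout, cin, k, k)) * np.sqrt(2.0 / fan_in)
        self.w = Tensor(w, requires_grad=True)
        self.b = Tensor(np.full(cout, bias_init, dtype=np.float64), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.w, self.b)

    def params(self):
        return [self.w, self.b]


class _ResBlock:
    """Two 3x3 convolutions with a residual (1x1-projected) shortcut."""

    def __init__(self, cin, cout, rng):
        self.c1 = _Conv(cin, cout, 3, rng)
        self.c2 = _Conv(cout, cout, 3, rng)
        self.proj = _Conv(cin, cout, 1, rng) if cin != cout else None

    def __call__(self, x: Tensor) -> Tensor:
        h = self.c2(self.c1(x).relu())
        s = self.proj(x) if self.proj is not None else x
        return (h + s).relu()

    def params(self):
        ps = self.c1.params() + self.c2.params()
        if self.proj is not None:
            ps += self.proj.params()
        return ps


class _AttentionGate:
    """Additive attention gate: alpha = sigmoid(psi(relu(Wg g + Wx x)))."""

    def __init__(self, c_skip, c_gate, rng):
        ci = max(c_skip // 2, 1)
        self.wg = _Conv(c_gate, ci, 1, rng)
        self.wx = _Conv(c_skip, ci, 1, rng)
        self.psi = _Conv(ci, 1, 1, rng)

    def __call__(self, skip: Tensor, gate: Tensor) -> Tensor:
        alpha = self.psi((self.wg(gate) + self.wx(skip)).relu()).sigmoid()
        return skip * alpha

    def coefficients(self, skip: Tensor, gate: Tensor) -> Tensor:
        return self.psi((self.wg(gate) + self.wx(skip)).relu()).sigmoid()

    def params(self):
        return self.wg.params() + self.wx.params() + self.psi.params()


def attention_gate(skip, gate_module: "_AttentionGate | None", gating):
    """Gate skip features; identity when attention is disabled."""
    skip = skip if isinstance(skip, Tensor) else Tensor(skip)
    if gate_module is None:
        return skip
    gating = gating if isinstance(gating, Tensor) else Tensor(gating)
    return gate_module(skip, gating)


# -- subnet ------------------------------------------------------------


class _Subnet:
    """One U-ResNet encoder-decoder with interleaved latent blocks."""

    def __init__(self, in_channels: int, config: NetworkConfig, rng):
        f = config.base_filters
        self.config = config
        n_cond = 2 if config.use_d0_input else 1
        self.enc = [
            _ResBlock(in_channels, f, rng),       # 32x32
            _ResBlock(f, 2 * f, rng),             # 16x16
            _ResBlock(2 * f, 4 * f, rng),         # 8x8
            _ResBlock(4 * f, 8 * f, rng),         # 4x4 (encoder output)
        ]
        self.down = [
            _ResBlock(8 * f + n_cond, 8 * f, rng),  # 2x2
            _ResBlock(8 * f, 8 * f, rng),           # 1x1
        ]
        # latent parameter heads at grids 1,2,4,8 (mean + raw-std
        # channels); initialized near zero so both subnets start from
        # matching N(0, softplus(0)) latents and the KL term starts
        # close to zero
        self.lat_heads = [
            _Conv(8 * f, 2, 1, rng),
            _Conv(8 * f, 2, 1, rng),
            _Conv(8 * f, 2, 1, rng),
            _Conv(4 * f, 2, 1, rng),
        ]
        for head in self.lat_heads:
            head.w.data *= 1e-3
        # decoder blocks; after-latent blocks fold the sampled z back in
        self.dec_in = [
            _ResBlock(16 * f, 8 * f, rng),  # at 2x2 (up(8f) + skip 8f)
            _ResBlock(16 * f, 8 * f, rng),  # at 4x4
            _ResBlock(12 * f, 4 * f, rng),  # at 8x8 (up 8f + skip 4f)
            _ResBlock(6 * f, 2 * f, rng),   # at 16x16 (up 4f + skip 2f)
            _ResBlock(3 * f, f, rng),       # at 32x32 (up 2f + skip f)
        ]
        self.post_z = [
            _ResBlock(8 * f + 1, 8 * f, rng),  # 1x1
            _ResBlock(8 * f + 1, 8 * f, rng),  # 2x2
            _ResBlock(8 * f + 1, 8 * f, rng),  # 4x4
            _ResBlock(4 * f + 1, 4 * f, rng),  # 8x8
        ]
        if config.use_attention:
            self.att = [
                _AttentionGate(8 * f, 8 * f, rng),  # skip @2
                _AttentionGate(8 * f, 8 * f, rng),  # skip @4
                _AttentionGate(4 * f, 8 * f, rng),  # skip @8
                _AttentionGate(2 * f, 4 * f, rng),  # skip @16
                _AttentionGate(f, 2 * f, rng),      # skip @32
            ]
        else:
            self.att = [None] * 5
        self.head = _Conv(f, 1, 1, rng)

    def params(self):
        ps = []
        for blk in self.enc + self.down + self.lat_heads + self.dec_in + self.post_z:
            ps += blk.params()
        for a in self.att:
            if a is not None:
                ps += a.params()
        ps += self.head.params()
        return ps

    def encode(self, x: Tensor, t_norm: np.ndarray, d_norm: np.ndarray):
        """Run the encoder; returns skip features at scales 32..1."""
        feats = []
        h = x
        for i, blk in enumerate(self.enc):
            h = blk(h)
            feats.append(h)
            if i < len(self.enc) - 1:
                h = avg_pool2d(h)
        # conditioning scalars tiled onto the encoder output (4x4)
        n = h.data.shape[0]
        cond = [np.broadcast_to(t_norm.reshape(n, 1, 1, 1), (n, 1, 4, 4))]
        if self.config.use_d0_input:
            cond.append(np.broadcast_to(d_norm.reshape(n, 1, 1, 1), (n, 1, 4, 4)))
        h = concat([h] + [Tensor(np.ascontiguousarray(c)) for c in cond], axis=1)
        h = self.down[0](avg_pool2d(h))
        feats.append(h)  # 2x2
        h = self.down[1](avg_pool2d(h))
        feats.append(h)  # 1x1
        return feats

    def decode(self, feats, rng=None, inject_z=None, mean_z=False):
        """Run the decoder.

        If ``inject_z`` (list of 4 latent grids) is given those latents
        are folded in; with ``mean_z`` the distribution means are used;
        otherwise each level is sampled from this subnet's own latent
        distribution using ``rng``.  Returns (soft mask Tensor, list of
        LatentLevel).
        """
        e32, e16, e8, e4, e2, e1 = feats
        levels: list[LatentLevel] = []
        h = e1
        skips = [e2, e4, e8, e16, e32]

        def latent(idx, h):
            pars = self.lat_heads[idx](h)
            mean = slice_channels(pars, 0, 1)
            std = slice_channels(pars, 1, 2).softplus() + _STD_FLOOR
            if inject_z is not None:
                z = inject_z[idx]
                z = z if isinstance(z, Tensor) else Tensor(z)
            elif mean_z:
                z = mean
            else:
                z = sample_latent(mean, std, rng)
            levels.append(LatentLevel(mean, std, z))
            return self.post_z[idx](concat([h, z], axis=1))

        h = latent(0, h)  # grid 1
        for i in range(5):
            h = upsample2x(h)
            skip = attention_gate(skips[i], self.att[i], h)
            h = self.dec_in[i](concat([h, skip], axis=1))
            if i < 3:
                h = latent(i + 1, h)  # grids 2, 4, 8
        logits = self.head(h)
        return logits.sigmoid(), levels


class HPNet:
    """Prior + posterior subnets with a shared architecture."""

    def __init__(self, config: NetworkConfig | None = None):
        self.config = config or NetworkConfig()
        rng = np.random.default_rng(self.config.seed)
        self.prior = _Subnet(1, self.config, rng)
        self.posterior = _Subnet(2, self.config, rng)

    def params(self):
        return self.prior.params() + self.posterior.params()

    # -- numpy-facing API ------------------------------------------------

    @staticmethod
    def _batchify(image) -> np.ndarray:
        arr = np.asarray(image, dtype=np.float64)
        if arr.ndim == 2:
            arr = arr[None, None]
        elif arr.ndim == 3:
            arr = arr[:, None]
        if arr.shape[-2:] != (PATCH_SIZE, PATCH_SIZE):
            raise ValueError(f"expected {PATCH_SIZE}x{PATCH_SIZE} patches, got {arr.shape}")
        return arr

    def forward_prior(self, image_t0, t_norm, d_norm, seed=None):
        """One stochastic future-segmentation sample from the prior subnet."""
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        x = self._batchify(image_t0)
        n = x.shape[0]
        t = np.full(n, t_norm, dtype=np.float64)
        d = np.full(n, d_norm, dtype=np.float64)
        with no_grad():
            feats = self.prior.encode(Tensor(x), t, d)
            out, levels = self.prior.decode(feats, rng=rng)
        hierarchy = LatentHierarchy(levels).numpy()
        soft = out.data[:, 0]
        return (soft[0] if np.asarray(image_t0).ndim == 2 else soft), hierarchy

    def forward_posterior(self, image_t0, image_t1, t_norm, d_norm):
        """Posterior latent parameters (deterministic; means used as z)."""
        if image_t1 is None:
            raise ValueError("posterior subnet requires the follow-up image I1")
        x = np.concatenate([self._batchify(image_t0), self._batchify(image_t1)], axis=1)
        n = x.shape[0]
        t = np.full(n, t_norm, dtype=np.float64)
        d = np.full(n, d_norm, dtype=np.float64)
        with no_grad():
            feats = self.posterior.encode(Tensor(x), t, d)
            # conditioning of finer levels on coarser ones uses the
            # distribution means, so the parameters are deterministic
            _, levels = self.posterior.decode(feats, mean_z=True)
        return LatentHierarchy(levels).numpy()

    def sample(self, image_t0, t_norm, d_norm, rng) -> np.ndarray:
        soft, _ = self.forward_prior(image_t0, t_norm, d_norm, rng)
        return soft

    def sample_batch(self, image_t0, t_norm, d_norm, rng, K: int) -> np.ndarray:
        """K prior samples of one patch in a single batched forward pass."""
        x = np.repeat(self._batchify(image_t0), K, axis=0)
        t = np.full(K, t_norm, dtype=np.float64)
        d = np.full(K, d_norm, dtype=np.float64)
        with no_grad():
            feats = self.prior.encode(Tensor(x), t, d)
            out, _ = self.prior.decode(feats, rng=rng)
        return out.data[:, 0]

    # -- training-facing API ---------------------------------------------

    def forward_train(self, x0: np.ndarray, x1: np.ndarray, t_norm, d_norm, rng):
        """Reconstruction pass: prior decoder driven by posterior latents.

        Inputs are batched numpy arrays (N,1,32,32); returns
        (reconstruction Tensor (N,1,32,32), prior LatentHierarchy,
        posterior LatentHierarchy) with graph recording enabled.
        """
        t = np.asarray(t_norm, dtype=np.float64)
        d = np.asarray(d_norm, dtype=np.float64)
        post_feats = self.posterior.encode(
            Tensor(np.concatenate([x0, x1], axis=1)), t, d
        )
        _, post_levels = self.posterior.decode(post_feats, rng=rng)
        prior_feats = self.prior.encode(Tensor(x0), t, d)
        recon, prior_levels = self.prior.decode(
            prior_feats, inject_z=[lv.z for lv in post_levels]
        )
        return recon, LatentHierarchy(prior_levels), LatentHierarchy(post_levels)


# -- checkpointing -----------------------------------------------------


def save_checkpoint(model: HPNet, path):
    """Serialize weights plus a NetworkConfig echo to a single .npz file."""
    cfg = json.dumps(
        {
            "base_filters": model.config.base_filters,
            "depth": model.config.depth,
            "use_attention": model.config.use_attention,
            "use_d0_input": model.config.use_d0_input,
            "seed": model.config.seed,
        }
    )
    arrays = {f"p{i}": p.data for i, p in enumerate(model.params())}
    np.savez(path, __config__=np.array(cfg), **arrays)


def load_checkpoint(path) -> HPNet:
    with np.load(Path(path), allow_pickle=False) as data:
        cfg = json.loads(str(data["__config__"]))
        model = HPNet(NetworkConfig(**cfg))
        for i, p in enumerate(model.params()):
            arr = data[f"p{i}"]
            if arr.shape != p.data.shape:
                raise ValueError("checkpoint incompatible with configuration")
            p.data = arr.astype(np.float64)
    return model
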