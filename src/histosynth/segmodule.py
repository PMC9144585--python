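"""Segmentation + reconstruction module with embedding-feature extraction.

Two structurally symmetric U-shaped networks built from residual
down-sampling blocks (RDB) and residual up-sampling blocks (RUB):

* the **segmentation network** S maps an RGB patch (network range [-1, 1])
  through 4 RDBs and 4 RUBs with U-Net skip concatenations to a K-channel
  softmax probability map;
* the **reconstruction network** R maps the grey-scale mask image (argmax
  class / (K-1), in [0, 1]) back to RGB through the same architecture with
  a tanh head.

An RDB sums two paths — (3x3 depthwise-separable conv x2 -> 2x average
pool) and (1x1 conv -> 2x average pool) — halving the spatial size; an RUB
sums (2x nearest upsample -> 3x3 conv x2) and (2x upsample -> 1x1 conv),
doubling it.  Every conv is followed by LeakyReLU (slope 0.2).

Training is joint: L_total = CCE(S(x), guide) + lambda_recon * MSE(R(m), x)
with lambda_recon = 5 by default.  The reconstruction branch consumes the
*soft* expected-value mask sum_k p_k * k/(K-1) so its gradient reaches the
segmentation network; the hard argmax mask is used for visualisation and
feature extraction.

For the generator, three embedding feature grids are tapped from the
reconstruction network: the last RDB output F_enc (input/16, 8*stem
channels) and the first two RUB outputs F_dec1 (input/8, 4*stem) and
F_dec2 (input/4, 2*stem).  At the default stem of 64 and input 256 these
are 16x16x512, 32x32x256 and 64x64x128.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .nn import Adam, Conv2d, Module, SeparableConv2d, Tensor
from .nn import autograd as ag


@dataclass(frozen=True)
class SegModuleConfig:
    input_size: int = 256
    k: int = 4
    stem_channels: int = 64
    lambda_recon: float = 5.0
    leaky_slope: float = 0.2
    learning_rate: float = 1e-3
    adam_beta1: float = 0.9
    adam_beta2: float = 0.99

    def __post_init__(self):
        if self.input_size % 16 != 0:
            raise ValueError("input_size must be divisible by 16 (four 2x poolings)")
        if self.k < 1:
            raise ValueError("k must be >= 1")

    @property
    def encoder_channels(self) -> tuple[int, int, int, int]:
        s = self.stem_channels
        return (s, 2 * s, 4 * s, 8 * s)

    @property
    def feature_shapes(self) -> dict[str, tuple[int, int, int]]:
        s, r = self.stem_channels, self.input_size
        return {"f_enc": (r // 16, r // 16, 8 * s),
                "f_dec1": (r // 8, r // 8, 4 * s),
                "f_dec2": (r // 4, r // 4, 2 * s)}


@dataclass
class EmbeddingSet:
    """Conditioning features for the generator, spatial-major (H, W, C)."""

    f_enc: np.ndarray
    f_dec1: np.ndarray
    f_dec2: np.ndarray

    def as_dict(self) -> dict[str, np.ndarray]:
        return {"f_enc": self.f_enc, "f_dec1": self.f_dec1, "f_dec2": self.f_dec2}


def _scale_init(module: Module, gain: float) -> None:
    """Rescale a block's initial weights; the two-path residual sum doubles
    activation variance, so each path starts at 1/sqrt(2) to keep the deep
    stack's activations in the tanh/softmax operating range."""
    for p in module.parameters():
        p.data = p.data * np.float32(gain)


class RDB(Module):
    """Residual down-sampling block: halves H and W."""

    def __init__(self, in_channels: int, out_channels: int, slope: float,
                 rng: np.random.Generator):
        super().__init__()
        self.slope = slope
        self.sep1 = SeparableConv2d(in_channels, out_channels, 3, rng)
        self.sep2 = SeparableConv2d(out_channels, out_channels, 3, rng)
        self.shortcut = Conv2d(in_channels, out_channels, 1, padding=0, rng=rng)
        _scale_init(self, 1.0 / np.sqrt(2.0))

    def forward(self, x: Tensor) -> Tensor:
        h, w = x.shape[2], x.shape[3]
        if h % 2 or w % 2:
            raise ValueError(f"RDB needs even spatial dims, got {h}x{w}")
        a = ag.leaky_relu(self.sep1(x), self.slope)
        a = ag.leaky_relu(self.sep2(a), self.slope)
        a = ag.avg_pool2(a)
        b = ag.avg_pool2(ag.leaky_relu(self.shortcut(x), self.slope))
        return a + b


class RUB(Module):
    """Residual up-sampling block: doubles H and W (plain 3x3 convs)."""

    def __init__(self, in_channels: int, out_channels: int, slope: float,
                 rng: np.random.Generator):
        super().__init__()
        self.slope = slope
        self.conv1 = Conv2d(in_channels, out_channels, 3, rng=rng)
        self.conv2 = Conv2d(out_channels, out_channels, 3, rng=rng)
        self.shortcut = Conv2d(in_channels, out_channels, 1, padding=0, rng=rng)
        _scale_init(self, 1.0 / np.sqrt(2.0))

    def forward(self, x: Tensor) -> Tensor:
        u = ag.upsample2(x)
        a = ag.leaky_relu(self.conv1(u), self.slope)
        a = ag.leaky_relu(self.conv2(a), self.slope)
        b = ag.leaky_relu(self.shortcut(u), self.slope)
        return a + b


class ResUNet(Module):
    """4-RDB encoder + 4-RUB decoder with skip concatenations.

    ``head`` is a 1x1 conv to ``out_channels``; the caller applies
    softmax/tanh.  ``forward`` can also return the taps needed for
    embedding-feature extraction.
    """

    def __init__(self, in_channels: int, out_channels: int, stem: int,
                 slope: float, rng: np.random.Generator):
        super().__init__()
        c1, c2, c3, c4 = stem, 2 * stem, 4 * stem, 8 * stem
        self.enc1 = RDB(in_channels, c1, slope, rng)
        self.enc2 = RDB(c1, c2, slope, rng)
        self.enc3 = RDB(c2, c3, slope, rng)
        self.enc4 = RDB(c3, c4, slope, rng)
        self.dec1 = RUB(c4, c3, slope, rng)            # bottleneck -> /8
        self.dec2 = RUB(c3 + c3, c2, slope, rng)       # skip from enc3
        self.dec3 = RUB(c2 + c2, c1, slope, rng)       # skip from enc2
        self.dec4 = RUB(c1 + c1, c1, slope, rng)       # skip from enc1
        self.head = Conv2d(c1, out_channels, 1, padding=0, rng=rng)

    def forward(self, x: Tensor, return_taps: bool = False):
        e1 = self.enc1(x)
        e2 = self.enc2(e1)
        e3 = self.enc3(e2)
        e4 = self.enc4(e3)
        d1 = self.dec1(e4)
        d2 = self.dec2(ag.concat([d1, e3], 1))
        d3 = self.dec3(ag.concat([d2, e2], 1))
        d4 = self.dec4(ag.concat([d3, e1], 1))
        out = self.head(d4)
        if return_taps:
            return out, {"f_enc": e4, "f_dec1": d1, "f_dec2": d2}
        return out


def to_network_range(patch: np.ndarray) -> np.ndarray:
    """[0, 1] storage range -> [-1, 1] network range."""
    return patch * 2.0 - 1.0


def from_network_range(x: np.ndarray) -> np.ndarray:
    return np.clip((x + 1.0) / 2.0, 0.0, 1.0)


def _to_nchw(patches: np.ndarray) -> np.ndarray:
    arr = np.asarray(patches, dtype=np.float32)
    if arr.ndim == 3:
        arr = arr[None]
    return arr.transpose(0, 3, 1, 2)


class SegModule(Module):
    """The paired segmentation and reconstruction networks."""

    def __init__(self, cfg: SegModuleConfig, seed: int = 0):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        self.seg_net = ResUNet(3, cfg.k, cfg.stem_channels, cfg.leaky_slope, rng)
        self.recon_net = ResUNet(1, 3, cfg.stem_channels, cfg.leaky_slope, rng)
        self.trained = False

    # -- forward passes ----------------------------------------------------
    def _check_size(self, arr: np.ndarray) -> None:
        r = self.cfg.input_size
        if arr.shape[2] != r or arr.shape[3] != r:
            raise ValueError(
                f"expected input {r}x{r}, got {arr.shape[2]}x{arr.shape[3]}")

    def segment_logits(self, x: Tensor) -> Tensor:
        return self.seg_net(x)

    def segment(self, patch: np.ndarray) -> np.ndarray:
        """Softmax probability map, (H, W, K), rows summing to 1."""
        x = _to_nchw(to_network_range(patch))
        self._check_size(x)
        with ag.no_grad():
            logits = self.seg_net(Tensor(x))
            probs = ag.softmax(logits, axis=1).data[0]
        return probs.transpose(1, 2, 0).astype(np.float64)

    def reconstruct(self, mask: np.ndarray) -> np.ndarray:
        """Reconstruct RGB (network range [-1, 1]) from a mask image in [0, 1]."""
        m = np.asarray(mask, dtype=np.float32)[None, None]
        self._check_size(m)
        with ag.no_grad():
            out = ag.tanh(self.recon_net(Tensor(m)))
        return out.data[0].transpose(1, 2, 0).astype(np.float64)

    def extract_features(self, patch: np.ndarray) -> EmbeddingSet:
        """Run segment -> hard mask -> reconstruction, tapping F_enc/F_dec1/F_dec2."""
        if not self.trained:
            warnings.warn("extracting features from an untrained module",
                          stacklevel=2)
        probs = self.segment(patch)
        mask = mask_from_probs(probs, mode="hard")
        m = Tensor(np.asarray(mask, dtype=np.float32)[None, None])
        with ag.no_grad():
            _, taps = self.recon_net(m, return_taps=True)
        return EmbeddingSet(
            f_enc=taps["f_enc"].data[0].transpose(1, 2, 0).astype(np.float64),
            f_dec1=taps["f_dec1"].data[0].transpose(1, 2, 0).astype(np.float64),
            f_dec2=taps["f_dec2"].data[0].transpose(1, 2, 0).astype(np.float64))


# ---------------------------------------------------------------------------
# mask construction and losses
# ---------------------------------------------------------------------------

def mask_from_probs(probs: np.ndarray, mode: str = "hard") -> np.ndarray:
    """Grey-scale mask image in [0, 1] from an (H, W, K) probability map.

    ``hard``: argmax class k mapped to k/(K-1).  ``soft``: expected value
    sum_k p_k * k/(K-1), the differentiable surrogate.  K=1 yields zeros.
    """
    probs = np.asarray(probs)
    k = probs.shape[-1]
    if k == 1:
        return np.zeros(probs.shape[:-1], dtype=np.float64)
    levels = np.arange(k, dtype=np.float64) / (k - 1)
    if mode == "hard":
        return levels[probs.argmax(axis=-1)]
    if mode == "soft":
        return probs @ levels
    raise ValueError(f"unknown mask mode {mode!r}")


def seg_loss(probs: np.ndarray, classes: np.ndarray) -> float:
    """Categorical cross-entropy: mean over pixels of -ln p[true class].

    Probabilities exactly zero at a true class are clamped at 1e-12 (and a
    warning is emitted) to keep the loss finite.
    """
    probs = np.asarray(probs, dtype=np.float64)
    classes = np.asarray(classes)
    if probs.shape[:-1] != classes.shape:
        raise ValueError("probability map and class map shapes disagree")
    p_true = np.take_along_axis(probs, classes[..., None].astype(np.int64),
                                axis=-1)[..., 0]
    if np.any(p_true <= 0):
        warnings.warn("zero probability at a true class; clamping at 1e-12",
                      stacklevel=2)
        p_true = np.maximum(p_true, 1e-12)
    return float(-np.log(p_true).mean())


def recon_loss(x_hat: np.ndarray, x: np.ndarray) -> float:
    """Mean squared error over all pixels and channels (network range)."""
    x_hat, x = np.asarray(x_hat, dtype=np.float64), np.asarray(x, dtype=np.float64)
    if x_hat.shape != x.shape:
        raise ValueError("shape mismatch")
    return float(((x_hat - x) ** 2).mean())


def total_loss(l_seg: float, l_recon: float, lambda_recon: float = 5.0) -> float:
    return float(l_seg + lambda_recon * l_recon)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _cce_tensor(logits: Tensor, classes: np.ndarray, k: int) -> Tensor:
    """Differentiable CCE from logits, mean over batch and pixels."""
    onehot = np.eye(k, dtype=np.float32)[classes].transpose(0, 3, 1, 2)
    logp = ag.log_softmax(logits, axis=1)
    return ag.neg(ag.tmean(ag.tsum(ag.mul(logp, Tensor(onehot)), axis=1)))


def _soft_mask_tensor(logits: Tensor, k: int) -> Tensor:
    probs = ag.softmax(logits, axis=1)
    levels = (np.arange(k, dtype=np.float32) / max(1, k - 1)).reshape(1, k, 1, 1)
    return ag.tsum(ag.mul(probs, Tensor(levels)), axis=1, keepdims=True)


def train_seg_module(patches: list[np.ndarray], guides: list[np.ndarray],
                     cfg: SegModuleConfig, epochs: int, batch_size: int,
                     seed: int, module: SegModule | None = None,
                     ) -> tuple[SegModule, list[dict]]:
    """Jointly optimise both networks on L_seg + lambda_recon * L_recon.

    ``guides`` are per-patch (H, W) integer class maps from the clustering
    guide.  Returns the trained module and a per-epoch history of the mean
    L_seg, L_recon and L_total (epochs=0 returns initial weights and an
    empty history).
    """
    if len(patches) == 0:
        raise ValueError("empty training set")
    if len(patches) != len(guides):
        raise ValueError("patches and guides must align")
    rng = np.random.default_rng(seed)
    module = module or SegModule(cfg, seed=int(rng.integers(2 ** 31)))
    opt = Adam(module.parameters(), lr=cfg.learning_rate,
               beta1=cfg.adam_beta1, beta2=cfg.adam_beta2)
    x_all = _to_nchw(to_network_range(np.stack(patches)))
    c_all = np.stack(guides).astype(np.int64)
    n = x_all.shape[0]
    history: list[dict] = []
    for epoch in range(epochs):
        order = rng.permutation(n)
        seg_sum = rec_sum = 0.0
        n_batches = 0
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            xb = Tensor(x_all[idx])
            logits = module.seg_net(xb)
            l_seg = _cce_tensor(logits, c_all[idx], cfg.k)
            mask = _soft_mask_tensor(logits, cfg.k)
            x_hat = ag.tanh(module.recon_net(mask))
            l_rec = ag.tmean((x_hat - xb) ** 2)
            loss = l_seg + Tensor(np.float32(cfg.lambda_recon)) * l_rec
            opt.zero_grad()
            loss.backward()
            opt.step()
            seg_sum += l_seg.item()
            rec_sum += l_rec.item()
            n_batches += 1
        l_seg_m, l_rec_m = seg_sum / n_batches, rec_sum / n_batches
        history.append({"epoch": epoch, "l_seg": l_seg_m, "l_recon": l_rec_m,
                        "l_total": total_loss(l_seg_m, l_rec_m, cfg.lambda_recon)})
    module.trained = True
    return module, history
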