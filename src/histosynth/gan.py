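"""Progressive GAN with embedding-feature concatenation, trained via WGAN-GP.

The generator starts from a 4x4 block fed by a 512-dimensional standard
normal latent vector and grows by resolution-doubling stages (nearest
upsample + two 3x3 convs + LeakyReLU per stage, 1x1 conv + tanh to-RGB
head).  New stages fade in: the output is
``(1 - alpha) * upsample(previous-stage RGB) + alpha * new-stage RGB``,
with alpha ramping linearly over the first half of each stage's steps.

The conditioning mechanism: at stage resolutions named in ``concat_plan``
(by default 16 -> F_enc, 32 -> F_dec1, 64 -> F_dec2), the corresponding
embedding feature grid from a frozen, pre-trained reconstruction network is
concatenated channel-wise to the stage input before its convs.  Feature
grids whose native spatial size differs from the stage resolution are
average-pooled down (or nearest-upsampled, for aggressively scaled-down
configurations) by the power-of-two factor.

The discriminator mirrors the generator (1x1 from-RGB, two 3x3 convs and a
2x average pool per stage, final 4x4 conv + dense) and is an unbounded
Wasserstein critic; it never sees the embedding features.  Training uses
the WGAN-GP objective: critic loss ``E[D(fake)] - E[D(real)] + gp`` with
``gp = lambda_gp * E[(||grad_xhat D(xhat)||_2 - 1)^2]`` on uniform
interpolates ``xhat = eps * real + (1 - eps) * fake``, lambda_gp = 10,
and generator loss ``-E[D(fake)]``.  Adam(lr 1e-4, beta1 0.9, beta2 0.99)
for both networks.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .nn import Adam, Conv2d, Linear, Module, Tensor
from .nn import autograd as ag
from .segmodule import EmbeddingSet, SegModule, from_network_range

log = logging.getLogger(__name__)

DEFAULT_CONCAT_PLAN = {16: "f_enc", 32: "f_dec1", 64: "f_dec2"}


def stage_resolutions(final_resolution: int) -> list[int]:
    """Consecutive powers of two from 4 up to ``final_resolution``."""
    if final_resolution < 4 or final_resolution & (final_resolution - 1):
        raise ValueError("final_resolution must be a power of 2, >= 4")
    res, out = 4, []
    while res <= final_resolution:
        out.append(res)
        res *= 2
    return out


@dataclass(frozen=True)
class GanConfig:
    latent_dim: int = 512
    final_resolution: int = 256
    generator_channels: tuple[int, ...] = (512, 512, 512, 256, 128, 64, 32)
    concat_plan: dict[int, str] = field(
        default_factory=lambda: dict(DEFAULT_CONCAT_PLAN))
    lambda_gp: float = 10.0
    leaky_slope: float = 0.2
    learning_rate: float = 1e-4
    adam_beta1: float = 0.9
    adam_beta2: float = 0.99
    n_critic: int = 1

    def __post_init__(self):
        resolutions = stage_resolutions(self.final_resolution)
        if len(self.generator_channels) != len(resolutions):
            raise ValueError(
                f"generator_channels must list one width per stage "
                f"({len(resolutions)} stages for {self.final_resolution})")

    @property
    def resolutions(self) -> list[int]:
        return stage_resolutions(self.final_resolution)


@dataclass
class StageState:
    stage_index: int
    resolution: int
    alpha: float = 1.0

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")


def fade_blend(prev_up: np.ndarray, new: np.ndarray, alpha: float) -> np.ndarray:
    """(1 - alpha) * prev_up + alpha * new; inputs must share a shape."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    prev_up, new = np.asarray(prev_up), np.asarray(new)
    if prev_up.shape != new.shape:
        raise ValueError("fade_blend requires matching shapes")
    return (1.0 - alpha) * prev_up + alpha * new


def _fade_blend_t(prev_up: Tensor, new: Tensor, alpha: float) -> Tensor:
    a = Tensor(np.float32(alpha))
    one = Tensor(np.float32(1.0))
    return (one - a) * prev_up + a * new


def _resize_feature(f: np.ndarray, target: int) -> np.ndarray:
    """Average-pool (or nearest-upsample) an (H, W, C) grid to target size."""
    h = f.shape[0]
    if h == target:
        return f
    if h > target:
        factor = h // target
        if factor * target != h:
            raise ValueError(f"feature size {h} not a multiple of {target}")
        return f.reshape(target, factor, target, factor, -1).mean(axis=(1, 3))
    factor = target // h
    if factor * h != target:
        raise ValueError(f"target {target} not a multiple of feature size {h}")
    return np.repeat(np.repeat(f, factor, axis=0), factor, axis=1)


class Generator(Module):
    """Progressively grown conditional generator."""

    def __init__(self, cfg: GanConfig, feature_channels: dict[str, int], seed: int = 0):
        super().__init__()
        self.cfg = cfg
        self.feature_channels = dict(feature_channels)
        rng = np.random.default_rng(seed)
        chans = cfg.generator_channels
        self.initial = Linear(cfg.latent_dim, chans[0] * 16, rng=rng)
        self.initial_conv = Conv2d(chans[0], chans[0], 3, rng=rng)
        blocks, to_rgb, conv_in = [], [], {}
        to_rgb.append(Conv2d(chans[0], 3, 1, padding=0, rng=rng))
        for s, res in enumerate(cfg.resolutions[1:], start=1):
            cin = chans[s - 1]
            if res in cfg.concat_plan:
                fname = cfg.concat_plan[res]
                if fname not in self.feature_channels:
                    raise ValueError(
                        f"concat plan names {fname!r} at {res}, but the "
                        f"embedding set provides {sorted(self.feature_channels)}")
                cin += self.feature_channels[fname]
            conv_in[res] = cin
            blocks.append(_GenBlock(cin, chans[s], cfg.leaky_slope, rng))
            to_rgb.append(Conv2d(chans[s], 3, 1, padding=0, rng=rng))
        self.blocks = blocks
        self.to_rgb = to_rgb
        #: conv-input channel count per grown resolution (for bookkeeping)
        self.conv_input_channels = conv_in

    def _check_features(self, features: dict[str, np.ndarray] | None, top_res: int):
        needed = [n for r, n in self.cfg.concat_plan.items() if r <= top_res]
        if needed and features is None:
            raise ValueError("this stage requires embedding features")
        for name in needed:
            c = features[name].shape[-1]
            want = self.feature_channels[name]
            if c != want:
                raise ValueError(
                    f"feature {name!r}: expected {want} channels, got {c}")

    def forward(self, z: Tensor, features: dict[str, np.ndarray] | None,
                state: StageState) -> Tensor:
        cfg = self.cfg
        res_list = cfg.resolutions
        stage = state.stage_index
        if not 0 <= stage < len(res_list):
            raise ValueError("stage index out of range")
        self._check_features(features, res_list[stage])
        n = z.shape[0]
        x = ag.reshape(self.initial(z), (n, cfg.generator_channels[0], 4, 4))
        x = ag.leaky_relu(x, cfg.leaky_slope)
        x = ag.leaky_relu(self.initial_conv(x), cfg.leaky_slope)
        prev_x = x
        for s in range(1, stage + 1):
            res = res_list[s]
            prev_x = x
            h = ag.upsample2(x)
            if res in cfg.concat_plan:
                f = features[cfg.concat_plan[res]]
                f = _resize_feature(f, res)
                fb = np.broadcast_to(f.transpose(2, 0, 1)[None],
                                     (n, f.shape[2], res, res))
                h = ag.concat([h, Tensor(np.ascontiguousarray(fb, dtype=np.float32))], 1)
            x = self.blocks[s - 1](h)
        rgb = ag.tanh(self.to_rgb[stage](x))
        if stage > 0 and state.alpha < 1.0:
            prev_rgb = ag.tanh(self.to_rgb[stage - 1](prev_x))
            rgb = _fade_blend_t(ag.upsample2(prev_rgb), rgb, state.alpha)
        return rgb

    def generate(self, z: np.ndarray, features: EmbeddingSet | dict | None,
                 state: StageState) -> np.ndarray:
        """Inference-mode batch generation -> (N, H, W, 3) in [-1, 1]."""
        if isinstance(features, EmbeddingSet):
            features = features.as_dict()
        zt = Tensor(np.asarray(z, dtype=np.float32))
        if res_below_first_concat(self.cfg, state.resolution) and features:
            log.debug("resolution %d is below the first concat scale; "
                      "ignoring supplied features", state.resolution)
            features = None
        with ag.no_grad():
            out = self.forward(zt, features, state)
        return out.data.transpose(0, 2, 3, 1).astype(np.float64)


def res_below_first_concat(cfg: GanConfig, resolution: int) -> bool:
    plan_res = sorted(cfg.concat_plan)
    return bool(plan_res) and resolution < plan_res[0]


class _GenBlock(Module):
    def __init__(self, cin: int, cout: int, slope: float, rng):
        super().__init__()
        self.slope = slope
        self.conv1 = Conv2d(cin, cout, 3, rng=rng)
        self.conv2 = Conv2d(cout, cout, 3, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        x = ag.leaky_relu(self.conv1(x), self.slope)
        return ag.leaky_relu(self.conv2(x), self.slope)


class Discriminator(Module):
    """WGAN critic mirroring the generator's stages; unbounded scalar output."""

    def __init__(self, cfg: GanConfig, seed: int = 0):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        chans = cfg.generator_channels
        from_rgb, blocks = [], []
        for s, res in enumerate(cfg.resolutions):
            from_rgb.append(Conv2d(3, chans[s], 1, padding=0, rng=rng))
            if s > 0:
                blocks.append(_DiscBlock(chans[s], chans[s - 1], cfg.leaky_slope, rng))
        self.from_rgb = from_rgb
        self.blocks = blocks
        self.final_conv = Conv2d(chans[0], chans[0], 4, padding=0, rng=rng)
        self.final_dense = Linear(chans[0], 1, rng=rng)

    def forward(self, x: Tensor, state: StageState) -> Tensor:
        cfg = self.cfg
        stage = state.stage_index
        slope = cfg.leaky_slope
        h = ag.leaky_relu(self.from_rgb[stage](x), slope)
        for s in range(stage, 0, -1):
            h = self.blocks[s - 1](h)
            if s == stage and state.alpha < 1.0:
                h_old = ag.leaky_relu(self.from_rgb[stage - 1](ag.avg_pool2(x)), slope)
                h = _fade_blend_t(h_old, h, state.alpha)
        h = ag.leaky_relu(self.final_conv(h), slope)        # 4x4 -> 1x1
        n, c = h.shape[0], h.shape[1]
        return self.final_dense(ag.reshape(h, (n, c)))

    def score(self, images: np.ndarray, state: StageState) -> np.ndarray:
        with ag.no_grad():
            out = self.forward(Tensor(np.asarray(images, dtype=np.float32)), state)
        return out.data[:, 0].astype(np.float64)


class _DiscBlock(Module):
    def __init__(self, cin: int, cout: int, slope: float, rng):
        super().__init__()
        self.slope = slope
        self.conv1 = Conv2d(cin, cin, 3, rng=rng)
        self.conv2 = Conv2d(cin, cout, 3, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        x = ag.leaky_relu(self.conv1(x), self.slope)
        x = ag.leaky_relu(self.conv2(x), self.slope)
        return ag.avg_pool2(x)


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def gradient_penalty(critic, x_real: np.ndarray, x_fake: np.ndarray,
                     lambda_gp: float, rng: np.random.Generator) -> Tensor:
    """lambda_gp * E[(||grad_xhat critic(xhat)||_2 - 1)^2].

    ``critic`` maps a Tensor batch to per-sample scores; interpolates use
    per-sample eps ~ U[0, 1]: ``xhat = eps * real + (1 - eps) * fake``.
    Returns a Tensor connected to the critic's parameters, so the penalty
    is trainable (double backprop through the critic).
    """
    x_real = np.asarray(x_real, dtype=np.float32)
    x_fake = np.asarray(x_fake, dtype=np.float32)
    if x_real.shape != x_fake.shape:
        raise ValueError("real and fake batches must share a shape")
    n = x_real.shape[0]
    eps = rng.uniform(size=(n,) + (1,) * (x_real.ndim - 1)).astype(np.float32)
    x_hat = Tensor(eps * x_real + (1.0 - eps) * x_fake, requires_grad=True)
    scores = critic(x_hat)
    total = ag.tsum(scores)
    (g,) = ag.grad(total, [x_hat], create_graph=True)
    g2 = ag.reshape(g * g, (n, int(np.prod(x_real.shape[1:]))))
    norms = ag.sqrt(ag.tsum(g2, axis=1) + Tensor(np.float32(1e-16)))
    one = Tensor(np.float32(1.0))
    return Tensor(np.float32(lambda_gp)) * ag.tmean((norms - one) ** 2)


def gan_losses(d_real: np.ndarray, d_fake: np.ndarray,
               gp_term: float) -> tuple[float, float]:
    """(critic_loss, generator_loss) from per-sample critic scores."""
    d_real = np.asarray(d_real, dtype=np.float64)
    d_fake = np.asarray(d_fake, dtype=np.float64)
    critic_loss = float(d_fake.mean() - d_real.mean() + gp_term)
    generator_loss = float(-d_fake.mean())
    return critic_loss, generator_loss


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _downscale_batch(images: np.ndarray, target: int) -> np.ndarray:
    """Average-pool an (N, H, W, 3) batch down to ``target`` resolution."""
    h = images.shape[1]
    if h == target:
        return images
    factor = h // target
    if factor * target != h:
        raise ValueError("resolutions must be power-of-two multiples")
    n, _, _, c = images.shape
    return images.reshape(n, target, factor, target, factor, c).mean(axis=(2, 4))


def _alpha_schedule(step: int, steps_in_stage: int, first_stage: bool) -> float:
    """Linear fade-in over the first half of a stage; 1 afterwards."""
    if first_stage or steps_in_stage <= 1:
        return 1.0
    half = max(1, steps_in_stage // 2)
    return min(1.0, (step + 1) / half)


def train_gan(patches: list[np.ndarray], seg_module: SegModule, cfg: GanConfig,
              schedule: list[int] | dict[int, int], seed: int,
              out_dir: Path | None = None, batch_size: int = 4,
              ) -> tuple[Generator, Discriminator, dict[int, list[dict]]]:
    """Progressive WGAN-GP training conditioned on frozen seg-module features.

    ``schedule`` gives the number of steps per stage (list aligned with the
    stage resolutions, or a {resolution: steps} mapping).  Per generator
    batch a reference patch is drawn uniformly from the dataset and its
    pre-extracted embedding features are concatenated at the plan scales.
    Returns the networks plus per-stage loss logs; if ``out_dir`` is given
    each stage's log is also written as ``losses_res{r}.csv``.
    """
    if not seg_module.trained:
        raise RuntimeError("seg module must be pre-trained (and is kept frozen)")
    resolutions = cfg.resolutions
    if isinstance(schedule, dict):
        steps_per_stage = [int(schedule.get(r, 0)) for r in resolutions]
    else:
        steps_per_stage = [int(s) for s in schedule]
        if len(steps_per_stage) != len(resolutions):
            raise ValueError("schedule length must match the stage count")
    rng = np.random.default_rng(seed)
    feat_shapes = seg_module.cfg.feature_shapes
    feature_channels = {k: v[2] for k, v in feat_shapes.items()}
    gen = Generator(cfg, feature_channels, seed=int(rng.integers(2 ** 31)))
    disc = Discriminator(cfg, seed=int(rng.integers(2 ** 31)))
    g_opt = Adam(gen.parameters(), cfg.learning_rate, cfg.adam_beta1, cfg.adam_beta2)
    d_opt = Adam(disc.parameters(), cfg.learning_rate, cfg.adam_beta1, cfg.adam_beta2)

    # the seg module is frozen: features can be extracted once per patch
    data = np.stack(patches).astype(np.float64)
    feats = [seg_module.extract_features(p).as_dict() for p in patches]
    data_net = data * 2.0 - 1.0                      # network range
    n_data = data_net.shape[0]

    logs: dict[int, list[dict]] = {}
    for stage, (res, n_steps) in enumerate(zip(resolutions, steps_per_stage)):
        stage_log: list[dict] = []
        real_all = _downscale_batch(data_net, res)
        for step in range(n_steps):
            alpha = _alpha_schedule(step, n_steps, first_stage=stage == 0)
            state = StageState(stage, res, alpha)
            use_feats = not res_below_first_concat(cfg, res)

            def sample_fake(batch_rng):
                idx = batch_rng.integers(0, n_data, size=batch_size)
                z = batch_rng.standard_normal((batch_size, cfg.latent_dim)).astype(np.float32)
                f = feats[idx[0]] if use_feats else None
                return gen.forward(Tensor(z), f, state)

            # -- critic update(s) --------------------------------------
            for _ in range(cfg.n_critic):
                idx_r = rng.integers(0, n_data, size=batch_size)
                x_real = np.ascontiguousarray(
                    real_all[idx_r].transpose(0, 3, 1, 2), dtype=np.float32)
                with ag.no_grad():
                    x_fake = sample_fake(rng).data
                d_real = disc.forward(Tensor(x_real), state)
                d_fake = disc.forward(Tensor(x_fake), state)
                gp = gradient_penalty(lambda t: disc.forward(t, state),
                                      x_real, x_fake, cfg.lambda_gp, rng)
                d_loss = ag.tmean(d_fake) - ag.tmean(d_real) + gp
                d_opt.zero_grad()
                d_loss.backward()
                d_opt.step()
                d_loss_val = d_loss.item()

            # -- generator update --------------------------------------
            fake = sample_fake(rng)
            g_loss = ag.neg(ag.tmean(disc.forward(fake, state)))
            g_opt.zero_grad()
            g_loss.backward()
            g_opt.step()
            stage_log.append({"step": step, "alpha": alpha,
                              "critic_loss": d_loss_val,
                              "generator_loss": g_loss.item()})
        logs[res] = stage_log
        if out_dir is not None:
            out_dir = Path(out_dir)
            out_dir.mkdir(parents=True, exist_ok=True)
            with open(out_dir / f"losses_res{res}.csv", "w", newline="") as f:
                w = csv.DictWriter(f, fieldnames=["step", "alpha", "critic_loss",
                                                  "generator_loss"])
                w.writeheader()
                w.writerows(stage_log)
    return gen, disc, logs


def sample(gen: Generator, seg_module: SegModule,
           reference_patches: list[np.ndarray], n: int, seed: int,
           ) -> tuple[np.ndarray, list[dict]]:
    """Draw ``n`` images from the trained generator at its final stage.

    Each image is conditioned on the embedding features of one reference
    patch (chosen round-robin from a seeded shuffle); provenance records
    the reference index and the latent seed.  Returns images in [0, 1]
    storage range, (n, H, W, 3).
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if not reference_patches:
        raise ValueError(
            "generation is reference-conditioned: supply at least one patch "
            "whose embedding features condition the generator")
    cfg = gen.cfg
    stage = len(cfg.resolutions) - 1
    state = StageState(stage, cfg.final_resolution, alpha=1.0)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(reference_patches))
    feats = {}
    images, provenance = [], []
    for i in range(n):
        ref = int(order[i % len(order)])
        if ref not in feats:
            feats[ref] = seg_module.extract_features(reference_patches[ref]).as_dict()
        z_seed = int(rng.integers(2 ** 31))
        z = np.random.default_rng(z_seed).standard_normal((1, cfg.latent_dim))
        img = gen.generate(z, feats[ref], state)[0]
        images.append(from_network_range(img))
        provenance.append({"index": i, "reference": ref, "z_seed": z_seed})
    out = np.stack(images) if images else np.zeros((0, cfg.final_resolution,
                                                    cfg.final_resolution, 3))
    return out, provenance


def save_checkpoint(path: Path, gen: Generator, disc: Discriminator,
                    cfg: GanConfig) -> None:
    path = Path(path)
    np.savez_compressed(
        path,
        config=json.dumps({"latent_dim": cfg.latent_dim,
                           "final_resolution": cfg.final_resolution,
                           "generator_channels": list(cfg.generator_channels),
                           "concat_plan": {str(k): v for k, v in cfg.concat_plan.items()},
                           "lambda_gp": cfg.lambda_gp,
                           "feature_channels": gen.feature_channels}),
        **{"gen." + k: v for k, v in gen.state_dict().items()},
        **{"disc." + k: v for k, v in disc.state_dict().items()})


def load_checkpoint(path: Path) -> tuple[Generator, Discriminator, GanConfig]:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["config"]))
        cfg = GanConfig(latent_dim=meta["latent_dim"],
                        final_resolution=meta["final_resolution"],
                        generator_channels=tuple(meta["generator_channels"]),
                        concat_plan={int(k): v for k, v in meta["concat_plan"].items()},
                        lambda_gp=meta["lambda_gp"])
        gen = Generator(cfg, meta["feature_channels"], seed=0)
        disc = Discriminator(cfg, seed=0)
        gen.load_state_dict({k[4:]: z[k] for k in z.files if k.startswith("gen.")})
        disc.load_state_dict({k[5:]: z[k] for k in z.files if k.startswith("disc.")})
    return gen, disc, cfg
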