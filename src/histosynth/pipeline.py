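"""Pipeline orchestration: validated config, staged execution, manifests.

The canonical stage order mirrors the workflow: synthesize (or ingest)
slides -> tile/filter patches -> fit the k-means clustering guide -> train
the segmentation module -> train the progressive GAN on frozen embedding
features -> sample -> evaluate (FID, and IS against the guide-histogram
classifier).

Every stage derives its own seed from the single global seed by hashing
the stage name, so adding stages never perturbs existing random streams.
Each stage writes a ``_stage.json`` receipt with a config hash, the hash
of its upstream inputs, and content hashes of its outputs; rerunning a
completed stage with unchanged config and inputs is a no-op.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, field_validator

from . import clustering, gan, metrics, prep, segmodule, synthetic

log = logging.getLogger(__name__)

STAGES = ["make-synthetic", "prep", "cluster", "train-seg", "train-gan",
          "sample", "evaluate"]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PatchSpecSection(_Section):
    height: int = 64
    width: int = 64
    nucleus_count: int = 8
    nucleus_radius_range: tuple[int, int] = (4, 7)
    halo_width: int = 2
    vessel_probability: float = 0.3
    noise_sigma: float = 0.02

    def to_spec(self) -> synthetic.PatchSpec:
        return synthetic.PatchSpec(**self.model_dump())


class SyntheticSection(_Section):
    n_slides: int = 2
    slide_height: int = 1024
    slide_width: int = 1024
    tissue_fraction: float = 0.7
    patch: PatchSpecSection = PatchSpecSection()


class PrepSection(_Section):
    patch_size: int = 512
    stride: Optional[int] = None
    output_size: int = 256
    tissue_threshold: float = 0.2
    white_luminance_cutoff: float = 0.9

    def to_config(self) -> prep.PrepConfig:
        return prep.PrepConfig(**self.model_dump())


class ClusterSection(_Section):
    k: int = 4
    sample_per_patch: int = 2000
    max_iter: int = 300
    tol: float = 1e-6


class SegSection(_Section):
    input_size: int = 256
    stem_channels: int = 64
    lambda_recon: float = 5.0
    leaky_slope: float = 0.2
    learning_rate: float = 1e-3
    epochs: int = 5
    batch_size: int = 8

    def to_config(self, k: int) -> segmodule.SegModuleConfig:
        return segmodule.SegModuleConfig(
            input_size=self.input_size, k=k, stem_channels=self.stem_channels,
            lambda_recon=self.lambda_recon, leaky_slope=self.leaky_slope,
            learning_rate=self.learning_rate)


def default_generator_channels(final_resolution: int) -> tuple[int, ...]:
    full = (512, 512, 512, 256, 128, 64, 32)
    n = len(gan.stage_resolutions(final_resolution))
    return full[:n]


class GanSection(_Section):
    latent_dim: int = 512
    final_resolution: int = 256
    generator_channels: Optional[tuple[int, ...]] = None
    lambda_gp: float = 10.0
    leaky_slope: float = 0.2
    learning_rate: float = 1e-4
    adam_beta1: float = 0.9
    adam_beta2: float = 0.99
    n_critic: int = 1
    steps_per_stage: int = 500
    batch_size: int = 4

    @field_validator("final_resolution")
    @classmethod
    def _power_of_two(cls, v):
        if v < 4 or v & (v - 1):
            raise ValueError("final_resolution must be a power of 2, >= 4")
        return v

    def to_config(self) -> gan.GanConfig:
        chans = self.generator_channels or default_generator_channels(self.final_resolution)
        return gan.GanConfig(
            latent_dim=self.latent_dim, final_resolution=self.final_resolution,
            generator_channels=tuple(chans), lambda_gp=self.lambda_gp,
            leaky_slope=self.leaky_slope, learning_rate=self.learning_rate,
            adam_beta1=self.adam_beta1, adam_beta2=self.adam_beta2,
            n_critic=self.n_critic)


class SampleSection(_Section):
    n: int = 16


class EvaluateSection(_Section):
    embed_dim: int = 32
    n_splits: int = 4


class RunConfig(_Section):
    seed: int = 0
    out_root: str = "runs/histosynth"
    synthetic: SyntheticSection = SyntheticSection()
    prep: PrepSection = PrepSection()
    cluster: ClusterSection = ClusterSection()
    seg: SegSection = SegSection()
    gan: GanSection = GanSection()
    sample: SampleSection = SampleSection()
    evaluate: EvaluateSection = EvaluateSection()

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def validate_config(path: Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Load and validate a YAML config; an empty/missing file means defaults.

    Unknown keys are rejected with their field paths (pydantic).  Flag
    overrides are applied dotted, e.g. ``{"gan.final_resolution": 32}``.
    """
    raw: dict = {}
    if path is not None:
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        if not isinstance(raw, dict):
            raise ValueError("config root must be a mapping")
    for key, value in (overrides or {}).items():
        parts = key.split(".")
        d = raw
        for p in parts[:-1]:
            d = d.setdefault(p, {})
        d[parts[-1]] = value
    cfg = RunConfig(**raw)
    log.info("normalized config: %s", json.dumps(cfg.model_dump(), default=str))
    return cfg


def stage_seed(global_seed: int, stage: str) -> int:
    """Named fan-out: independent per-stage seed from the global seed."""
    digest = hashlib.blake2b(f"{stage}:{global_seed}".encode(), digest_size=4).digest()
    return int.from_bytes(digest, "big") % (2 ** 31)


# ---------------------------------------------------------------------------
# hashing / receipts
# ---------------------------------------------------------------------------

def _file_hash(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def _state_hash(state: dict[str, np.ndarray]) -> str:
    h = hashlib.sha256()
    for name in sorted(state):
        h.update(name.encode())
        h.update(np.ascontiguousarray(state[name]).tobytes())
    return h.hexdigest()[:16]


class _StageIO:
    """Receipt bookkeeping for one stage directory."""

    def __init__(self, run_dir: Path, name: str, cfg_hash: str, input_hash: str):
        self.dir = run_dir / name.replace("-", "_")
        self.name = name
        self.cfg_hash = cfg_hash
        self.input_hash = input_hash
        self.receipt = self.dir / "_stage.json"

    def is_done(self) -> bool:
        if not self.receipt.exists():
            return False
        with open(self.receipt) as f:
            r = json.load(f)
        return r.get("config_hash") == self.cfg_hash and r.get("input_hash") == self.input_hash

    def outputs(self) -> dict[str, str]:
        with open(self.receipt) as f:
            return json.load(f)["outputs"]

    def finish(self, outputs: dict[str, str]) -> dict[str, str]:
        with open(self.receipt, "w") as f:
            json.dump({"stage": self.name, "config_hash": self.cfg_hash,
                       "input_hash": self.input_hash, "outputs": outputs}, f, indent=1)
        return outputs

    def hash_files(self, patterns: list[str]) -> dict[str, str]:
        out = {}
        for pat in patterns:
            for p in sorted(self.dir.glob(pat)):
                if p.name != "_stage.json":
                    out[p.name] = _file_hash(p)
        return out


def _inputs_digest(upstream_outputs: dict[str, str]) -> str:
    payload = json.dumps(upstream_outputs, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# stage implementations
# ---------------------------------------------------------------------------

def run_pipeline(cfg: RunConfig, stages: list[str] | None = None) -> dict:
    """Execute the requested stages in canonical order; return the manifest.

    ``stages=None`` runs everything; an empty list returns a manifest with
    the config hash only.  A stage whose upstream artifact is missing
    raises an error naming the stage to run first.
    """
    requested = STAGES if stages is None else [s for s in STAGES if s in stages]
    unknown = set(stages or []) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages {sorted(unknown)}; valid: {STAGES}")
    run_dir = Path(cfg.out_root)
    run_dir.mkdir(parents=True, exist_ok=True)
    cfg_hash = cfg.config_hash()
    manifest: dict = {"config_hash": cfg_hash, "stages": {}}
    chain_outputs: dict[str, str] = {}

    for name in requested:
        io = _StageIO(run_dir, name, cfg_hash, _inputs_digest(chain_outputs))
        skipped = io.is_done()
        if skipped:
            log.info("stage %s up to date; skipping", name)
            outputs = io.outputs()
        else:
            io.dir.mkdir(parents=True, exist_ok=True)
            outputs = _STAGE_FUNCS[name](cfg, run_dir, io)
        manifest["stages"][name] = {"outputs": outputs, "skipped": skipped}
        chain_outputs = dict(outputs)

    with open(run_dir / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=1)
    return manifest


def _require(run_dir: Path, stage: str, filename: str) -> Path:
    p = run_dir / stage.replace("-", "_") / filename
    if not p.exists():
        raise FileNotFoundError(
            f"missing artifact {p}; run the {stage!r} stage first")
    return p


def _stage_make_synthetic(cfg: RunConfig, run_dir: Path, io: _StageIO) -> dict:
    s = cfg.synthetic
    spec = s.patch.to_spec()
    seed = stage_seed(cfg.seed, "make-synthetic")
    for i in range(s.n_slides):
        slide, cmap = synthetic.generate_slide(
            spec, s.slide_height, s.slide_width, s.tissue_fraction, seed + i)
        synthetic.save_patch_png(io.dir / f"slide_{i:03d}.png", slide)
        synthetic.save_component_png(io.dir / f"slide_{i:03d}_components.png", cmap)
    return io.finish(io.hash_files(["slide_*.png"]))


def _stage_prep(cfg: RunConfig, run_dir: Path, io: _StageIO) -> dict:
    slides = sorted((run_dir / "make_synthetic").glob("slide_[0-9]*.png"))
    slides = [p for p in slides if "components" not in p.name]
    if not slides:
        _require(run_dir, "make-synthetic", "slide_000.png")
    prep.prepare_dataset(slides, cfg.prep.to_config(), io.dir)
    return io.finish(io.hash_files(["*.png", "prep_manifest.json"]))


def _load_prepped(run_dir: Path) -> list[np.ndarray]:
    manifest = _require(run_dir, "prep", "prep_manifest.json")
    with open(manifest) as f:
        records = json.load(f)["records"]
    patches = []
    for rec in records:
        if rec["kept"]:
            patches.append(synthetic.load_patch_png(run_dir / "prep" / rec["output_file"]))
    if not patches:
        raise RuntimeError("prep produced no kept patches; loosen the tissue filter")
    return patches


def _stage_cluster(cfg: RunConfig, run_dir: Path, io: _StageIO) -> dict:
    patches = _load_prepped(run_dir)
    guide = clustering.fit_pixel_clusters(
        patches, k=cfg.cluster.k, seed=stage_seed(cfg.seed, "cluster"),
        max_iter=cfg.cluster.max_iter, tol=cfg.cluster.tol,
        sample_per_patch=cfg.cluster.sample_per_patch)
    guide.save(io.dir / "guide.json")
    import imageio.v3 as iio
    for i, p in enumerate(patches[:4]):      # example guide masks
        iio.imwrite(io.dir / f"classmap_{i:03d}.png",
                    clustering.assign_guide(p, guide).astype(np.uint8))
    return io.finish(io.hash_files(["guide.json", "classmap_*.png"]))


def _stage_train_seg(cfg: RunConfig, run_dir: Path, io: _StageIO) -> dict:
    patches = _load_prepped(run_dir)
    guide = clustering.ClusterGuide.load(_require(run_dir, "cluster", "guide.json"))
    guides = [clustering.assign_guide(p, guide) for p in patches]
    scfg = cfg.seg.to_config(cfg.cluster.k)
    module, history = segmodule.train_seg_module(
        patches, guides, scfg, epochs=cfg.seg.epochs,
        batch_size=cfg.seg.batch_size, seed=stage_seed(cfg.seed, "train-seg"))
    state = module.state_dict()
    np.savez_compressed(io.dir / "seg_module.npz",
                        config=json.dumps(scfg.__dict__), **state)
    with open(io.dir / "loss_history.csv", "w") as f:
        f.write("epoch,l_seg,l_recon,l_total\n")
        for h in history:
            f.write(f"{h['epoch']},{h['l_seg']:.6f},{h['l_recon']:.6f},{h['l_total']:.6f}\n")
    import imageio.v3 as iio
    for i, p in enumerate(patches[:4]):      # example predicted masks
        mask = segmodule.mask_from_probs(module.segment(p), mode="hard")
        iio.imwrite(io.dir / f"mask_{i:03d}.png",
                    (mask * 255.0 + 0.5).astype(np.uint8))
    outputs = io.hash_files(["loss_history.csv", "mask_*.png"])
    outputs["seg_module.npz"] = _state_hash(state)   # content hash (zip is timestamped)
    return io.finish(outputs)


def load_seg_module(path: Path) -> segmodule.SegModule:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["config"]))
        scfg = segmodule.SegModuleConfig(**meta)
        module = segmodule.SegModule(scfg, seed=0)
        module.load_state_dict({k: z[k] for k in z.files if k != "config"})
    module.trained = True
    return module


def _stage_train_gan(cfg: RunConfig, run_dir: Path, io: _StageIO) -> dict:
    patches = _load_prepped(run_dir)
    module = load_seg_module(_require(run_dir, "train_seg", "seg_module.npz"))
    gcfg = cfg.gan.to_config()
    schedule = [cfg.gan.steps_per_stage] * len(gcfg.resolutions)
    generator, critic, _ = gan.train_gan(
        patches, module, gcfg, schedule, seed=stage_seed(cfg.seed, "train-gan"),
        out_dir=io.dir, batch_size=cfg.gan.batch_size)
    gan.save_checkpoint(io.dir / "gan_checkpoint.npz", generator, critic, gcfg)
    outputs = io.hash_files(["losses_res*.csv"])
    outputs["gan_checkpoint.npz"] = _state_hash(
        {**{"g." + k: v for k, v in generator.state_dict().items()},
         **{"d." + k: v for k, v in critic.state_dict().items()}})
    return io.finish(outputs)


def _stage_sample(cfg: RunConfig, run_dir: Path, io: _StageIO) -> dict:
    patches = _load_prepped(run_dir)
    module = load_seg_module(_require(run_dir, "train_seg", "seg_module.npz"))
    generator, _, _ = gan.load_checkpoint(_require(run_dir, "train_gan", "gan_checkpoint.npz"))
    images, provenance = gan.sample(
        generator, module, patches, cfg.sample.n, seed=stage_seed(cfg.seed, "sample"))
    for i, img in enumerate(images):
        synthetic.save_patch_png(io.dir / f"sample_{i:04d}.png", img)
    with open(io.dir / "provenance.json", "w") as f:
        json.dump(provenance, f, indent=1)
    return io.finish(io.hash_files(["sample_*.png", "provenance.json"]))


def guide_histogram_classifier(guide: clustering.ClusterGuide):
    """Image -> distribution over guide classes (pixel-fraction histogram).

    A deliberately simple offline classifier for the Inception-Score
    formula: class proportions of the k-means guide assignment.
    """
    def classify(images: np.ndarray) -> np.ndarray:
        images = np.asarray(images)
        out = np.empty((images.shape[0], guide.k))
        for i, img in enumerate(images):
            cm = clustering.assign_guide(img, guide)
            out[i] = np.bincount(cm.ravel(), minlength=guide.k) / cm.size
        return out

    return classify


def _stage_evaluate(cfg: RunConfig, run_dir: Path, io: _StageIO) -> dict:
    patches = _load_prepped(run_dir)
    sample_files = sorted((run_dir / "sample").glob("sample_*.png"))
    if not sample_files:
        _require(run_dir, "sample", "sample_0000.png")
    samples = np.stack([synthetic.load_patch_png(p) for p in sample_files])
    real = np.stack(patches)
    if real.shape[1] != samples.shape[1]:   # compare at the generated scale
        real = gan._downscale_batch(real, samples.shape[1])
    embedder = metrics.RandomProjectionEmbedder(
        int(np.prod(real.shape[1:])), dim=cfg.evaluate.embed_dim,
        seed=stage_seed(cfg.seed, "evaluate"))
    fid_value = metrics.fid(samples, real, embedder)
    guide = clustering.ClusterGuide.load(_require(run_dir, "cluster", "guide.json"))
    n_splits = min(cfg.evaluate.n_splits, len(samples))
    is_mean, is_std = metrics.inception_score(
        samples, guide_histogram_classifier(guide), n_splits=n_splits)
    report = [metrics.score_report("fid", fid_value, None,
                                   f"random_projection({cfg.evaluate.embed_dim})",
                                   len(samples), len(real)),
              metrics.score_report("inception_score", is_mean, is_std,
                                   "guide_histogram", len(samples))]
    with open(io.dir / "scores.json", "w") as f:
        json.dump(report, f, indent=1)
    return io.finish(io.hash_files(["scores.json"]))


_STAGE_FUNCS = {
    "make-synthetic": _stage_make_synthetic,
    "prep": _stage_prep,
    "cluster": _stage_cluster,
    "train-seg": _stage_train_seg,
    "train-gan": _stage_train_gan,
    "sample": _stage_sample,
    "evaluate": _stage_evaluate,
}
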