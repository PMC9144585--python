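"""Training-set construction from large images: tile, filter, resize.

The pipeline is fixed as crop -> tissue filter -> resize.  Large images are
tiled into ``patch_size`` windows on a stride grid (partial windows at the
right/bottom edges are dropped), each window is kept or discarded by a
luminance-based tissue fraction computed at full window resolution, and
surviving windows are bilinearly resized to ``output_size``.

"Tissue" is defined photometrically: a pixel counts as tissue when its
luminance 0.299R + 0.587G + 0.114B falls below ``white_luminance_cutoff``;
H&E background is near-white so this is a robust, deterministic criterion.
A window is kept when its tissue fraction is >= ``tissue_threshold``
(inclusive).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage.transform import resize as _sk_resize

from .synthetic import load_patch_png, save_patch_png

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PrepConfig:
    patch_size: int = 512
    stride: int | None = None          # None -> patch_size (non-overlapping grid)
    output_size: int = 256
    tissue_threshold: float = 0.2
    white_luminance_cutoff: float = 0.9

    def __post_init__(self):
        stride = self.stride if self.stride is not None else self.patch_size
        if self.patch_size < self.output_size:
            raise ValueError("patch_size must be >= output_size")
        if stride <= 0:
            raise ValueError("stride must be positive")
        if not 0.0 <= self.tissue_threshold <= 1.0:
            raise ValueError("tissue_threshold must be in [0, 1]")

    @property
    def effective_stride(self) -> int:
        return self.stride if self.stride is not None else self.patch_size


def luminance(patch: np.ndarray) -> np.ndarray:
    return 0.299 * patch[..., 0] + 0.587 * patch[..., 1] + 0.114 * patch[..., 2]


def crop_patches(slide: np.ndarray, cfg: PrepConfig) -> list[tuple[np.ndarray, tuple[int, int]]]:
    """Tile ``slide`` into ``patch_size`` windows at ``stride`` spacing.

    Origins are 0-based (row, col) of each window's top-left pixel; windows
    are half-open ``[y, y+P) x [x, x+P)``.  Returns an empty list when the
    slide is smaller than one window.
    """
    h, w = slide.shape[:2]
    p, s = cfg.patch_size, cfg.effective_stride
    if h < p or w < p:
        log.warning("slide %dx%d smaller than window %d; no patches", h, w, p)
        return []
    out = []
    for y in range(0, h - p + 1, s):
        for x in range(0, w - p + 1, s):
            out.append((slide[y:y + p, x:x + p], (y, x)))
    return out


def resize_patch(patch: np.ndarray, output_size: int) -> np.ndarray:
    """Bilinear resize of a square patch; output values stay in [0, 1]."""
    h, w = patch.shape[:2]
    if h != w:
        raise ValueError(f"resize_patch expects a square patch, got {h}x{w}")
    if h == output_size:
        return patch.copy()
    out = _sk_resize(patch, (output_size, output_size), order=1,
                     anti_aliasing=False, preserve_range=True, clip=True)
    return np.clip(out, 0.0, 1.0)


def tissue_filter(patch: np.ndarray, cfg: PrepConfig) -> tuple[bool, float]:
    """Keep/drop decision with the measured tissue fraction attached."""
    frac = float(np.mean(luminance(patch) < cfg.white_luminance_cutoff))
    return frac >= cfg.tissue_threshold, frac


def prepare_dataset(slide_paths: list[Path], cfg: PrepConfig, out_dir: Path) -> dict:
    """Tile every slide, filter, resize, write PNGs plus a JSON manifest.

    The manifest has one record per window (kept or dropped) with fields
    ``source, origin_y, origin_x, kept, tissue_fraction, output_file``;
    unreadable source files are recorded under ``errors`` and skipped.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records, errors = [], []
    n_kept = 0
    for path in slide_paths:
        path = Path(path)
        try:
            slide = load_patch_png(path)
        except Exception as e:  # unreadable input is recorded, not fatal
            log.warning("skipping unreadable slide %s: %s", path, e)
            errors.append({"source": path.name, "error": str(e)})
            continue
        for window, (y, x) in crop_patches(slide, cfg):
            keep, frac = tissue_filter(window, cfg)
            rec = {"source": path.name, "origin_y": y, "origin_x": x,
                   "kept": keep, "tissue_fraction": round(frac, 6),
                   "output_file": None}
            if keep:
                fname = f"{path.stem}_y{y:06d}_x{x:06d}.png"
                save_patch_png(out_dir / fname, resize_patch(window, cfg.output_size))
                rec["output_file"] = fname
                n_kept += 1
            records.append(rec)
    manifest = {"config": {"patch_size": cfg.patch_size, "stride": cfg.effective_stride,
                           "output_size": cfg.output_size,
                           "tissue_threshold": cfg.tissue_threshold,
                           "white_luminance_cutoff": cfg.white_luminance_cutoff},
                "n_windows": len(records), "n_kept": n_kept,
                "records": records, "errors": errors}
    with open(out_dir / "prep_manifest.json", "w") as f:
        json.dump(manifest, f, indent=1)
    return manifest
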