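"""Synthetic H&E-like histology patches with exact ground-truth component maps.

Oligodendroglioma under H&E shows rounded, fairly uniform nuclei surrounded
by a cleared perinuclear halo (the "fried egg" appearance) set in a pink
eosinophilic matrix, with occasional vessel lumina and near-white slide
background.  The generator here renders a stylised version of that
morphology: a pink cytoplasm field, dark-purple nuclear discs each ringed by
a lightened-cytoplasm halo, optionally one vessel (a red-walled ring with a
near-white lumen), plus i.i.d. Gaussian pixel noise.

Every patch comes with a per-pixel ``ComponentMap`` (0=background,
1=cytoplasm, 2=nucleus, 3=vessel) recorded *before* noise, which makes the
k-means pseudo-label stage and the segmentation module testable against
known truth.  Halo pixels are labelled cytoplasm in the map but also
returned as a boolean ``halo`` mask, since their colour is a blend.

Everything is deterministic in ``(spec, seed)``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

BACKGROUND, CYTOPLASM, NUCLEUS, VESSEL = 0, 1, 2, 3

COMPONENT_NAMES = {BACKGROUND: "background", CYTOPLASM: "cytoplasm",
                   NUCLEUS: "nucleus", VESSEL: "vessel"}

#: Default palette, RGB in [0, 1].  Components are pairwise >= 0.2 apart in
#: Euclidean RGB distance so that K=4 k-means is well posed.
DEFAULT_PALETTE: dict[str, tuple[float, float, float]] = {
    "background": (0.97, 0.96, 0.97),
    "cytoplasm": (0.91, 0.65, 0.77),
    "nucleus": (0.29, 0.15, 0.42),
    "vessel": (0.78, 0.24, 0.26),
}

#: Halo colour = cytoplasm lightened toward white by this fixed factor.
HALO_LIGHTEN = 0.55


def halo_color(palette: dict[str, tuple[float, float, float]]) -> np.ndarray:
    c = np.asarray(palette["cytoplasm"], dtype=np.float64)
    return c + HALO_LIGHTEN * (1.0 - c)


@dataclass(frozen=True)
class PatchSpec:
    """Parameters of one synthetic patch."""

    height: int = 64
    width: int = 64
    nucleus_count: int = 8
    nucleus_radius_range: tuple[int, int] = (4, 7)
    halo_width: int = 2
    vessel_probability: float = 0.3
    noise_sigma: float = 0.02
    palette: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_PALETTE))

    def __post_init__(self):
        if self.height <= 0 or self.width <= 0:
            raise ValueError("height and width must be positive")
        if self.nucleus_count < 0:
            raise ValueError("nucleus_count must be >= 0")
        rmin, rmax = self.nucleus_radius_range
        if rmin > rmax or rmin <= 0:
            raise ValueError("nucleus_radius_range must satisfy 0 < min <= max")
        if not 0.0 <= self.vessel_probability <= 1.0:
            raise ValueError("vessel_probability must be in [0, 1]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        for name in ("background", "cytoplasm", "nucleus", "vessel"):
            if name not in self.palette:
                raise ValueError(f"palette missing component {name!r}")

    def content_hash(self) -> str:
        payload = json.dumps(
            {"height": self.height, "width": self.width,
             "nucleus_count": self.nucleus_count,
             "nucleus_radius_range": list(self.nucleus_radius_range),
             "halo_width": self.halo_width,
             "vessel_probability": self.vessel_probability,
             "noise_sigma": self.noise_sigma,
             "palette": {k: list(v) for k, v in sorted(self.palette.items())}},
            sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class ComponentMap:
    """Per-pixel component codes paired with a rendered patch."""

    grid: np.ndarray                      # (H, W) uint8 in {0..3}
    halo: np.ndarray | None = None        # (H, W) bool, halo-ring pixels

    def __post_init__(self):
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 2:
            raise ValueError("ComponentMap grid must be 2-D")
        if self.grid.min() < 0 or self.grid.max() > 3:
            raise ValueError("component codes must lie in {0..3}")


def _disc_mask(h: int, w: int, cy: float, cx: float, r: float) -> np.ndarray:
    yy, xx = np.ogrid[:h, :w]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r


def generate_patch(spec: PatchSpec, seed: int) -> tuple[np.ndarray, ComponentMap, dict]:
    """Render one patch.

    Returns ``(patch, component_map, meta)`` where ``patch`` is (H, W, 3)
    float64 in [0, 1].  ``meta`` records nucleus centres/radii, whether a
    vessel was drawn, and how many requested nuclei could not be placed
    without overlap after 100 retries each.
    """
    rng = np.random.default_rng(seed)
    h, w = spec.height, spec.width
    comp = np.full((h, w), CYTOPLASM, dtype=np.uint8)
    halo = np.zeros((h, w), dtype=bool)

    # optional vessel: red wall ring with near-white (background-coded) lumen
    vessel_drawn = bool(rng.random() < spec.vessel_probability)
    if vessel_drawn:
        r_out = max(4, min(h, w) // 6)
        r_in = max(2, r_out - 2)
        cy = rng.uniform(r_out, h - r_out)
        cx = rng.uniform(r_out, w - r_out)
        comp[_disc_mask(h, w, cy, cx, r_out)] = VESSEL
        comp[_disc_mask(h, w, cy, cx, r_in)] = BACKGROUND

    # nuclei: rejection-sampled non-overlapping discs with halo rings
    rmin, rmax = spec.nucleus_radius_range
    placed: list[tuple[float, float, int]] = []
    dropped = 0
    for _ in range(spec.nucleus_count):
        ok = False
        for _ in range(100):
            r = int(rng.integers(rmin, rmax + 1))
            cy = rng.uniform(r + spec.halo_width, h - r - spec.halo_width)
            cx = rng.uniform(r + spec.halo_width, w - r - spec.halo_width)
            margin = spec.halo_width + 1
            if all((cy - py) ** 2 + (cx - px) ** 2 > (r + pr + margin) ** 2
                   for py, px, pr in placed):
                placed.append((cy, cx, r))
                ok = True
                break
        if not ok:
            dropped += 1
    for cy, cx, r in placed:
        ring = _disc_mask(h, w, cy, cx, r + spec.halo_width) & ~_disc_mask(h, w, cy, cx, r)
        ring &= comp == CYTOPLASM          # halo never overwrites vessel/background
        halo |= ring
        comp[_disc_mask(h, w, cy, cx, r)] = NUCLEUS

    # paint colours from the palette; halo pixels get the lightened blend
    lut = np.array([spec.palette["background"], spec.palette["cytoplasm"],
                    spec.palette["nucleus"], spec.palette["vessel"]], dtype=np.float64)
    patch = lut[comp]
    patch[halo] = halo_color(spec.palette)

    if spec.noise_sigma > 0:
        patch = patch + rng.normal(0.0, spec.noise_sigma, size=patch.shape)
        patch = np.clip(patch, 0.0, 1.0)

    meta = {"nuclei": [(float(cy), float(cx), int(r)) for cy, cx, r in placed],
            "nuclei_dropped": dropped, "vessel": vessel_drawn, "seed": int(seed)}
    return patch, ComponentMap(comp, halo), meta


def generate_slide(spec: PatchSpec, slide_height: int, slide_width: int,
                   tissue_fraction: float, seed: int) -> tuple[np.ndarray, ComponentMap]:
    """A pseudo-whole-slide: tissue fills the top rows, background the rest.

    The tissue region is tiled from ``spec``-sized patches (deterministic
    per-tile seeds derived from ``seed``) and occupies ``tissue_fraction``
    of the slide area as a band of full-width rows at the top; the
    remainder is noisy near-white background.
    """
    if not 0.0 <= tissue_fraction <= 1.0:
        raise ValueError("tissue_fraction must be in [0, 1]")
    if slide_height < spec.height or slide_width < spec.width:
        raise ValueError("slide dimensions must be >= patch dimensions")
    rng = np.random.default_rng(seed)
    bg = np.asarray(spec.palette["background"], dtype=np.float64)
    slide = np.broadcast_to(bg, (slide_height, slide_width, 3)).copy()
    comp = np.full((slide_height, slide_width), BACKGROUND, dtype=np.uint8)
    halo = np.zeros((slide_height, slide_width), dtype=bool)

    tissue_rows = int(round(tissue_fraction * slide_height))
    ty = 0
    tile_idx = 0
    while ty < tissue_rows:
        tx = 0
        while tx < slide_width:
            sub_seed = int(rng.integers(0, 2 ** 31))
            patch, cmap, _ = generate_patch(spec, sub_seed)
            hh = min(spec.height, tissue_rows - ty)
            ww = min(spec.width, slide_width - tx)
            slide[ty:ty + hh, tx:tx + ww] = patch[:hh, :ww]
            comp[ty:ty + hh, tx:tx + ww] = cmap.grid[:hh, :ww]
            halo[ty:ty + hh, tx:tx + ww] = cmap.halo[:hh, :ww]
            tx += spec.width
            tile_idx += 1
        ty += spec.height

    if spec.noise_sigma > 0:
        noise_region = np.zeros((slide_height, slide_width), dtype=bool)
        noise_region[tissue_rows:] = True
        slide[noise_region] = np.clip(
            slide[noise_region] + rng.normal(0, spec.noise_sigma,
                                             size=slide[noise_region].shape), 0, 1)
    return slide, ComponentMap(comp, halo)


def save_patch_png(path: Path, patch: np.ndarray) -> None:
    iio.imwrite(path, (np.clip(patch, 0, 1) * 255.0 + 0.5).astype(np.uint8))


def load_patch_png(path: Path) -> np.ndarray:
    arr = iio.imread(path)
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    return arr.astype(np.float64) / 255.0


def save_component_png(path: Path, cmap: ComponentMap) -> None:
    iio.imwrite(path, cmap.grid.astype(np.uint8))


def load_component_png(path: Path) -> ComponentMap:
    return ComponentMap(iio.imread(path).astype(np.uint8))


def generate_dataset(n: int, spec: PatchSpec, seed: int, out_dir: Path) -> dict:
    """Write ``n`` patch/component PNG pairs plus a JSON manifest.

    Per-item seeds are ``seed + i`` so any subset can be regenerated
    byte-identically.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    items = []
    for i in range(n):
        item_seed = seed + i
        patch, cmap, meta = generate_patch(spec, item_seed)
        patch_file = f"patch_{i:05d}.png"
        comp_file = f"comp_{i:05d}.png"
        save_patch_png(out_dir / patch_file, patch)
        save_component_png(out_dir / comp_file, cmap)
        items.append({"index": i, "seed": item_seed, "patch": patch_file,
                      "component_map": comp_file,
                      "nuclei_dropped": meta["nuclei_dropped"],
                      "vessel": meta["vessel"]})
    manifest = {"n": n, "base_seed": int(seed), "spec_hash": spec.content_hash(),
                "items": items}
    with open(out_dir / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=1)
    return manifest


def generate_patches(n: int, spec: PatchSpec, seed: int) -> tuple[list[np.ndarray], list[ComponentMap]]:
    """In-memory convenience: ``n`` patches with per-item seeds ``seed + i``."""
    patches, cmaps = [], []
    for i in range(n):
        p, c, _ = generate_patch(spec, seed + i)
        patches.append(p)
        cmaps.append(c)
    return patches, cmaps
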