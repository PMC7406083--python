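"""Synthetic object/background/scene generation with exact figure-ground masks.

The generator emulates the statistical structure of an object-on-background
congruency design: K object categories, each with class-diagnostic features
confined to a masked object region (a shape family plus an oriented-grating
object texture), and per-category background families whose colour and texture
statistics co-vary with the category.  A scene places one object exemplar on a
3x3 location grid over a white ("segmented"), category-matched ("congruent"),
or category-mismatched ("incongruent") background.

All randomness flows through :func:`numpy.random.SeedSequence` keyed by
(dataset seed, role, indices), so every sprite, background, and scene is a
deterministic function of its identifiers and the configuration seed.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml
from matplotlib.colors import hsv_to_rgb

CONDITIONS = ("segmented", "congruent", "incongruent")
N_LOCATIONS = 9  # 3x3 placement grid
_N_SHAPE_FAMILIES = 6

# role tags for the per-entity random streams
_ROLE_OBJECT = 11
_ROLE_BACKGROUND = 23
_ROLE_SCENE = 37
_ROLE_SPLIT = 53


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GenConfig:
    """Design parameters of the synthetic stimulus family.

    Parameters
    ----------
    K : number of object categories (>= 2 for an incongruent condition).
    E : exemplars per category in a stimulus set.
    B : backgrounds per category family.
    image_size : side of the square scene in pixels.
    object_scale : sprite canvas side as a fraction of ``image_size``; the
        sprite must fit at every cell of the 3x3 grid, so this is <= 1.
    rho : object-background correlation in [0, 1]: the probability that a
        *training* scene's background is drawn from its object's own family
        rather than a foreign one.  Natural scene statistics make context an
        informative but imperfect cue; rho < 1 emulates that.  Evaluation
        stimulus sets are unaffected (their congruent condition is matched by
        definition).
    seed : dataset seed; all entity-level randomness derives from it.
    """

    K: int = 6
    E: int = 12
    B: int = 3
    image_size: int = 32
    object_scale: float = 0.5
    rho: float = 0.8
    seed: int = 0

    @property
    def sprite_size(self) -> int:
        return max(4, int(round(self.image_size * self.object_scale)))

    def validate(self) -> None:
        if self.K < 2:
            raise ValueError(f"K must be >= 2 (got {self.K}); the incongruent "
                             "condition needs a foreign category")
        if self.E < 1 or self.B < 1:
            raise ValueError("E and B must be >= 1")
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError(f"rho must lie in [0, 1], got {self.rho}")
        if self.sprite_size > self.image_size:
            raise ValueError("object_scale too large: sprite exceeds image")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GenConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__ | {}, fh, sort_keys=True)


def _rng(cfg_seed: int, role: int, *keys: int) -> np.random.Generator:
    """Deterministic per-entity generator."""
    ss = np.random.SeedSequence((int(cfg_seed) & 0x7FFFFFFF, role) + tuple(int(k) for k in keys))
    return np.random.Generator(np.random.PCG64(ss))


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass
class ObjectSprite:
    """Cut-out object on a small canvas with its exact boolean mask."""

    pixels: np.ndarray  # (s, s, 3) float in [0, 1]
    mask: np.ndarray    # (s, s) bool, True = object
    category: int
    exemplar_id: int


@dataclass
class Background:
    """Full-scene textured colour field from one category's family."""

    pixels: np.ndarray  # (H, W, 3) float in [0, 1]
    source_category: int
    background_id: int


@dataclass
class Scene:
    """Composited stimulus: one object exemplar on one background."""

    pixels: np.ndarray  # (H, W, 3)
    mask: np.ndarray    # (H, W) bool
    category: int
    condition: str      # segmented | congruent | incongruent
    location: int       # 0..8, row-major over the 3x3 grid
    exemplar_id: int
    background_id: int  # -1 for segmented


@dataclass
class StimulusSet:
    """Manifest-backed scene collection with balance invariants."""

    scenes: list[Scene]
    manifest: pd.DataFrame
    design: dict

    def __len__(self) -> int:
        return len(self.scenes)

    def condition_counts(self) -> dict[str, int]:
        vc = self.manifest["condition"].value_counts()
        return {c: int(vc.get(c, 0)) for c in CONDITIONS}

    def save(self, outdir: str | Path, write_masks: bool = True) -> Path:
        """Write 8-bit PNG scenes (+ masks) and the manifest CSV."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for scene, fname in zip(self.scenes, self.manifest["filename"]):
            iio.imwrite(outdir / fname, np.round(scene.pixels * 255).astype(np.uint8))
            if write_masks:
                iio.imwrite(outdir / fname.replace(".png", "_mask.png"),
                            np.where(scene.mask, 255, 0).astype(np.uint8))
        path = outdir / "manifest.csv"
        self.manifest.to_csv(path, index=False)
        return path


@dataclass
class ImageDataset:
    """Training/validation image collection with per-image exact masks."""

    images: np.ndarray   # (N, H, W, 3) float32
    labels: np.ndarray   # (N,) int
    masks: np.ndarray    # (N, H, W) bool
    train_idx: np.ndarray
    val_idx: np.ndarray
    diet: str            # segmented | unsegmented

    @property
    def train(self) -> tuple[np.ndarray, np.ndarray]:
        return self.images[self.train_idx], self.labels[self.train_idx]

    @property
    def val(self) -> tuple[np.ndarray, np.ndarray]:
        return self.images[self.val_idx], self.labels[self.val_idx]


# --------------------------------------------------------------------------
# objects
# --------------------------------------------------------------------------

def _shape_mask(family: int, size: int, scale: float, angle: float) -> np.ndarray:
    """Binary mask of one of the parametric shape families, rotated by angle."""
    half = (size - 1) / 2.0
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    yy -= half
    xx -= half
    ca, sa = np.cos(angle), np.sin(angle)
    x = ca * xx + sa * yy
    y = -sa * xx + ca * yy
    t = scale * size
    if family == 0:      # ellipse
        m = (x / (0.45 * t)) ** 2 + (y / (0.30 * t)) ** 2 <= 1.0
    elif family == 1:    # rectangle
        m = (np.abs(x) <= 0.42 * t) & (np.abs(y) <= 0.26 * t)
    elif family == 2:    # triangle
        m = (y >= -0.33 * t) & (np.abs(x) <= 0.45 * t * (0.33 * t - y) / (0.66 * t + 1e-9)) & (y <= 0.33 * t)
    elif family == 3:    # annulus
        r = np.sqrt(x ** 2 + y ** 2)
        m = (r <= 0.42 * t) & (r >= 0.24 * t)
    elif family == 4:    # cross
        m = ((np.abs(x) <= 0.14 * t) & (np.abs(y) <= 0.45 * t)) | \
            ((np.abs(y) <= 0.14 * t) & (np.abs(x) <= 0.45 * t))
    else:                # diamond
        m = np.abs(x) / (0.48 * t) + np.abs(y) / (0.32 * t) <= 1.0
    return m


def make_object(category: int, exemplar_id: int, config: GenConfig) -> ObjectSprite:
    """Render one object exemplar.

    Category determines the class-diagnostic parameters (shape family and the
    orientation/wavelength band of the object grating); the exemplar index
    draws the nuisance parameters (size jitter, rotation, grating phase,
    slight colour tint) within those bands.
    """
    config.validate()
    K = config.K
    if not 0 <= category < K:
        raise ValueError(f"category {category} out of range [0, {K})")
    if not 0 <= exemplar_id < 10 ** 9:
        raise ValueError(f"exemplar_id {exemplar_id} must be non-negative")
    rng = _rng(config.seed, _ROLE_OBJECT, category, exemplar_id)
    s = config.sprite_size

    family = category % _N_SHAPE_FAMILIES
    # class-diagnostic grating orientation band, disjoint across categories
    band = np.pi / K
    theta = band * (category + 0.5) + (rng.uniform(-0.3, 0.3)) * band
    # class-linked wavelength (px), three coarse bands with exemplar jitter
    wavelength = (4.0 + (category % 3)) * rng.uniform(0.92, 1.08)

    scale = rng.uniform(0.78, 1.0)
    angle = rng.uniform(-0.35, 0.35)
    phase = rng.uniform(0, 2 * np.pi)
    mask = _shape_mask(family, s, scale, angle)
    if not mask.any():  # degenerate jitter draw; fall back to unjittered shape
        mask = _shape_mask(family, s, 1.0, 0.0)
    assert mask.sum() <= 0.5 * s * s, "object mask exceeds half the canvas"

    yy, xx = np.mgrid[0:s, 0:s].astype(float)
    grating = np.sin(2 * np.pi / wavelength * (np.cos(theta) * xx + np.sin(theta) * yy) + phase)
    lum = np.clip(0.5 + 0.38 * grating, 0.0, 1.0)
    # class hue tint from the category's own hue arc (the arc its congruent
    # background family also draws from), moderately saturated so the spatial
    # cues stay necessary for fine discrimination
    hue = (category + 0.1 + 0.8 * rng.uniform()) / K
    sat = 0.45 + 0.10 * rng.uniform()
    hsv = np.stack([np.full((s, s), hue), np.full((s, s), sat), lum], axis=-1)
    pixels = hsv_to_rgb(hsv)
    pixels = np.where(mask[..., None], pixels, 0.5)  # neutral placeholder outside
    return ObjectSprite(pixels=pixels, mask=mask, category=category, exemplar_id=exemplar_id)


# --------------------------------------------------------------------------
# backgrounds
# --------------------------------------------------------------------------

def make_background(source_category: int, background_id: int, config: GenConfig) -> Background:
    """Render one background from a category's appearance family.

    Each category owns a disjoint hue arc (width 0.8/K of the hue circle) and
    a disjoint luminance-texture frequency band; a background draws its base
    hue, saturation, and texture parameters within its category's bands.
    """
    config.validate()
    K = config.K
    if not 0 <= source_category < K:
        raise ValueError(f"source_category {source_category} out of range [0, {K})")
    if background_id < 0:
        raise ValueError(f"background_id {background_id} must be non-negative")
    rng = _rng(config.seed, _ROLE_BACKGROUND, source_category, background_id)
    H = config.image_size

    hue = (source_category + 0.1 + 0.8 * rng.uniform()) / K
    sat = 0.55 + 0.3 * rng.uniform()
    # disjoint per-category texture-frequency band (cycles per image)
    f_lo, f_width = 1.0, 2.5
    freq = f_lo + (source_category + 0.1 + 0.8 * rng.uniform()) * f_width / K
    orient = rng.uniform(0, np.pi)
    phase = rng.uniform(0, 2 * np.pi)

    # object-scale clutter: a second grating at the wavelengths the object
    # textures occupy, with nuisance orientation, so backgrounds compete with
    # objects in texture statistics and not just in colour
    hf_wavelength = rng.uniform(3.5, 7.5)
    hf_orient = rng.uniform(0, np.pi)
    hf_phase = rng.uniform(0, 2 * np.pi)

    yy, xx = np.mgrid[0:H, 0:H].astype(float) / H
    wave = np.sin(2 * np.pi * freq * (np.cos(orient) * xx + np.sin(orient) * yy) + phase)
    yyp, xxp = np.mgrid[0:H, 0:H].astype(float)
    hf = np.sin(2 * np.pi / hf_wavelength * (np.cos(hf_orient) * xxp + np.sin(hf_orient) * yyp)
                + hf_phase)
    value = 0.60 + 0.14 * wave + 0.18 * hf + 0.05 * rng.standard_normal((H, H))
    hsv = np.stack([np.full((H, H), hue), np.full((H, H), sat),
                    np.clip(value, 0.05, 1.0)], axis=-1)
    return Background(pixels=hsv_to_rgb(hsv), source_category=source_category,
                      background_id=background_id)


def background_params(bg: Background) -> dict:
    """Mean appearance statistics of a rendered background (for diagnostics)."""
    px = bg.pixels
    v = px.max(axis=-1)
    return {"mean_rgb": px.mean(axis=(0, 1)), "mean_value": float(v.mean())}


# --------------------------------------------------------------------------
# compositing
# --------------------------------------------------------------------------

def _location_offsets(image_size: int, sprite_size: int, location: int) -> tuple[int, int]:
    if not 0 <= location < N_LOCATIONS:
        raise ValueError(f"location {location} out of range [0, {N_LOCATIONS})")
    row, col = divmod(location, 3)
    step = (image_size - sprite_size) // 2
    return row * step, col * step


def compose_scene(sprite: ObjectSprite, background: Background | None,
                  location: int, image_size: int | None = None) -> Scene:
    """Paste a sprite onto a background (or white) at one 3x3 grid cell.

    Outside the translated mask the scene equals the background exactly;
    inside it equals the sprite's masked pixels exactly.
    """
    if background is not None:
        canvas = background.pixels.copy()
        H = canvas.shape[0]
        condition = "congruent" if background.source_category == sprite.category else "incongruent"
        background_id = background.background_id
    else:
        if image_size is None:
            raise ValueError("image_size is required for a white (segmented) scene")
        H = image_size
        canvas = np.ones((H, H, 3))
        condition = "segmented"
        background_id = -1
    s = sprite.mask.shape[0]
    r0, c0 = _location_offsets(H, s, location)
    if r0 + s > H or c0 + s > H:
        raise ValueError(f"sprite of size {s} overflows image of size {H} at location {location}")
    mask = np.zeros((H, H), dtype=bool)
    mask[r0:r0 + s, c0:c0 + s] = sprite.mask
    canvas[r0:r0 + s, c0:c0 + s][sprite.mask] = sprite.pixels[sprite.mask]
    return Scene(pixels=canvas, mask=mask, category=sprite.category,
                 condition=condition, location=location,
                 exemplar_id=sprite.exemplar_id, background_id=background_id)


# --------------------------------------------------------------------------
# stimulus sets
# --------------------------------------------------------------------------

def _scene_filename(scene: Scene) -> str:
    return (f"scene_c{scene.category:02d}_e{scene.exemplar_id:03d}_"
            f"{scene.condition}_b{scene.background_id:+03d}_l{scene.location}.png")


def _manifest(scenes: Iterable[Scene], seed: int) -> pd.DataFrame:
    rows = [{"filename": _scene_filename(sc), "category": sc.category,
             "condition": sc.condition, "location": sc.location,
             "exemplar_id": sc.exemplar_id, "background_id": sc.background_id,
             "seed": seed} for sc in scenes]
    return pd.DataFrame(rows, columns=["filename", "category", "condition",
                                       "location", "exemplar_id", "background_id", "seed"])


def build_stimulus_set(K: int, E: int, B: int, config: GenConfig | None = None,
                       **overrides) -> StimulusSet:
    """Enumerate the full balanced design.

    Every (category, exemplar) pair yields one segmented scene, B congruent
    scenes (one per family background), and B incongruent scenes whose
    backgrounds come from a seeded cyclically shifted category, guaranteeing a
    category mismatch.  Locations are seeded draws from the 3x3 grid.
    Counts: K*E*B congruent, K*E*B incongruent, K*E segmented.
    """
    config = replace(config or GenConfig(), K=K, E=E, B=B, **overrides)
    config.validate()
    loc_rng = _rng(config.seed, _ROLE_SCENE, 0)
    # seeded cyclic shift in [1, K-1]: a derangement of the category labels
    shift = 1 + int(loc_rng.integers(K - 1))

    backgrounds = {(c, b): make_background(c, b, config)
                   for c in range(K) for b in range(B)}
    scenes: list[Scene] = []
    for c in range(K):
        for e in range(E):
            sprite = make_object(c, e, config)
            scenes.append(compose_scene(sprite, None, int(loc_rng.integers(N_LOCATIONS)),
                                        config.image_size))
            for b in range(B):
                scenes.append(compose_scene(sprite, backgrounds[(c, b)],
                                            int(loc_rng.integers(N_LOCATIONS))))
            for b in range(B):
                scenes.append(compose_scene(sprite, backgrounds[((c + shift) % K, b)],
                                            int(loc_rng.integers(N_LOCATIONS))))
    design = {"K": K, "E": E, "B": B, "image_size": config.image_size,
              "seed": config.seed, "incongruent_shift": shift, "rho": config.rho}
    return StimulusSet(scenes=scenes, manifest=_manifest(scenes, config.seed), design=design)


def sample_balanced_subset(sset: StimulusSet, per_cat_per_cond: int, seed: int) -> StimulusSet:
    """Draw a balanced subset: the same number of scenes per category and
    condition, with no exemplar repeated within a category.

    Mirrors the human-matched subsets of the original design (81 per
    condition, 3 per category for K=27): each category contributes
    ``per_cat_per_cond`` exemplars to each of the three conditions, and an
    exemplar appears at most once in the subset.
    """
    K, E, B = sset.design["K"], sset.design["E"], sset.design["B"]
    need = per_cat_per_cond * len(CONDITIONS)
    if need > E:
        raise ValueError(
            f"infeasible subset: {per_cat_per_cond} per condition x {len(CONDITIONS)} "
            f"conditions needs {need} distinct exemplars but E={E}")
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence((sset.design["seed"] & 0x7FFFFFFF,
                                                                      _ROLE_SPLIT, int(seed)))))
    m = sset.manifest
    chosen: list[int] = []
    for c in range(K):
        exemplars = rng.permutation(E)[:need]
        for i, cond in enumerate(CONDITIONS):
            for e in exemplars[i * per_cat_per_cond:(i + 1) * per_cat_per_cond]:
                rows = m.index[(m.category == c) & (m.condition == cond) & (m.exemplar_id == e)]
                chosen.append(int(rows[int(rng.integers(len(rows)))]))
    scenes = [sset.scenes[i] for i in chosen]
    design = dict(sset.design, subset_seed=int(seed), per_cat_per_cond=per_cat_per_cond)
    return StimulusSet(scenes=scenes, manifest=m.loc[chosen].reset_index(drop=True), design=design)


def latin_square_locations(K: int, E: int, B: int) -> np.ndarray:
    """Optional fully counterbalanced exemplar-background-location assignment:
    location = (exemplar + background) mod 9 folded over the grid."""
    out = np.empty((K, E, B), dtype=int)
    for c in range(K):
        for e in range(E):
            for b in range(B):
                out[c, e, b] = (c + e + b) % N_LOCATIONS
    return out


# --------------------------------------------------------------------------
# training datasets (segmented vs unsegmented diets)
# --------------------------------------------------------------------------

def make_training_datasets(K: int, n_per_class: int | Sequence[int],
                           config: GenConfig | None = None, seed: int | None = None,
                           val_fraction: float = 0.2,
                           **overrides) -> tuple[ImageDataset, ImageDataset]:
    """Build the segmented and unsegmented training diets.

    Both datasets contain the same object exemplars in the same order and at
    the same locations; they differ only in what lies outside the mask (white
    vs an in-scene background).  Scene backgrounds come from the object's own
    family with probability ``rho`` and from a foreign family otherwise,
    emulating context that is an informative but imperfect category cue.  The
    seeded train/validation split is computed once and shared, so diet is the
    only difference between the two returned datasets.  ``n_per_class`` may
    be a sequence to emulate class-imbalanced designs.
    """
    config = replace(config or GenConfig(), K=K, **overrides)
    if seed is not None:
        config = replace(config, seed=seed)
    config.validate()
    counts = ([int(n_per_class)] * K if np.isscalar(n_per_class) else list(n_per_class))
    if len(counts) != K:
        raise ValueError(f"n_per_class sequence length {len(counts)} != K={K}")
    rng = _rng(config.seed, _ROLE_SCENE, 1)
    H = config.image_size

    seg_imgs, unseg_imgs, labels, masks = [], [], [], []
    for c in range(K):
        for e in range(counts[c]):
            sprite = make_object(c, e, config)
            loc = int(rng.integers(N_LOCATIONS))
            if rng.uniform() < config.rho:
                bg_cat = c
            else:
                bg_cat = (c + 1 + int(rng.integers(K - 1))) % K
            bg = make_background(bg_cat, int(rng.integers(config.B)), config)
            seg = compose_scene(sprite, None, loc, H)
            unseg = compose_scene(sprite, bg, loc)
            seg_imgs.append(seg.pixels)
            unseg_imgs.append(unseg.pixels)
            labels.append(c)
            masks.append(seg.mask)
    N = len(labels)
    order = _rng(config.seed, _ROLE_SPLIT, 0).permutation(N)
    n_train = int(round((1.0 - val_fraction) * N))
    train_idx, val_idx = np.sort(order[:n_train]), np.sort(order[n_train:])
    if len(train_idx) == 0 or len(val_idx) == 0:
        raise ValueError("empty train or validation split; increase n_per_class")

    def _mk(images, diet):
        return ImageDataset(images=np.asarray(images, dtype=np.float32),
                            labels=np.asarray(labels, dtype=np.int64),
                            masks=np.asarray(masks), train_idx=train_idx,
                            val_idx=val_idx, diet=diet)

    return _mk(seg_imgs, "segmented"), _mk(unseg_imgs, "unsegmented")


def dataset_digest(ds: ImageDataset) -> str:
    """Stable content hash of a dataset (images + labels + split)."""
    h = hashlib.sha256()
    for arr in (ds.images, ds.labels, ds.masks, ds.train_idx, ds.val_idx):
        h.update(np.ascontiguousarray(arr).tobytes())
    return h.hexdigest()[:16]
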