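"""Feature-reliance probes: region-wise noise, occlusion importance maps,
and layer-wise filter-activation heatmaps.

Occlusion importance follows the sliding-gray-patch protocol: a patch of side
``patch`` slides over the image in ``stride``-pixel steps, and the importance
of each position is the relative change of the true class's pre-softmax score,

    importance = (original_score - occluded_score) / original_score.

Positive values mean the occluded pixels were helping classification.  The
grid of per-position importances is projected to pixels by averaging over all
occluder placements covering each pixel, and region summaries average the
pixel map over the object mask and its complement.  Because the per-position
values are already normalized by the original score, the region means are the
"importance ratios" directly; no second normalization is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .scenegen import Scene

__all__ = ["ImportanceMap", "RegionImportance", "add_region_noise",
           "occlusion_sweep", "region_importance", "filter_correct",
           "layer_heatmap", "GRAY_FILL"]

GRAY_FILL = (0.5, 0.5, 0.5)
_REGIONS = ("object", "background", "both")


# --------------------------------------------------------------------------
# region-wise Gaussian noise
# --------------------------------------------------------------------------

def add_region_noise(scene: Scene, region: str, sigma: float, seed: int) -> Scene:
    """Add i.i.d. Gaussian pixel noise (std ``sigma``) to one region only.

    The noise field is drawn once for the whole image from ``seed`` and then
    masked, so noising "both" equals noising object and background separately
    with the same seed, composed on their disjoint regions.  Pixels are
    clipped to [0, 1]; mask and metadata are unchanged.
    """
    if region not in _REGIONS:
        raise ValueError(f"unknown region {region!r}; expected one of {_REGIONS}")
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    if sigma == 0:
        return replace(scene, pixels=scene.pixels.copy(), mask=scene.mask.copy())
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence((int(seed) & 0x7FFFFFFF, 177))))
    noise = rng.normal(0.0, sigma, size=scene.pixels.shape)
    if region == "object":
        sel = scene.mask[..., None]
    elif region == "background":
        sel = ~scene.mask[..., None]
    else:
        sel = np.ones_like(scene.mask)[..., None]
    pixels = np.clip(scene.pixels + np.where(sel, noise, 0.0), 0.0, 1.0)
    return replace(scene, pixels=pixels, mask=scene.mask.copy())


# --------------------------------------------------------------------------
# occlusion sweep
# --------------------------------------------------------------------------

@dataclass
class ImportanceMap:
    """Occlusion-sweep attribution for one scene and one model."""

    grid: np.ndarray          # (gh, gw) importance per occluder position
    patch: int
    stride: int
    fill: tuple
    original_score: float     # pre-softmax true-class score, unoccluded
    pixel_map: np.ndarray     # (H, W) mean importance over covering placements
    defined: bool             # False when original_score == 0

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.grid.shape


def grid_positions(H: int, W: int, patch: int, stride: int) -> tuple[list[tuple[int, int]], tuple[int, int]]:
    """Top-left corners of all fully-inside occluder placements and the grid
    shape floor((H-patch)/stride)+1 per axis."""
    if patch > H or patch > W:
        raise ValueError(f"patch {patch} exceeds image size {H}x{W}")
    if stride < 1:
        raise ValueError(f"stride must be >= 1, got {stride}")
    rows = range(0, H - patch + 1, stride)
    cols = range(0, W - patch + 1, stride)
    return [(r, c) for r in rows for c in cols], (len(rows), len(cols))


def occlusion_sweep(model, scene: Scene, patch: int, stride: int,
                    fill: Sequence[float] = GRAY_FILL) -> ImportanceMap:
    """Slide a ``patch`` x ``patch`` fill-colored square over the scene and
    measure the relative drop of the true class's pre-softmax score.

    When the unoccluded score is exactly zero the ratio is undefined; the map
    is returned with ``defined=False`` and NaN values rather than divided.
    """
    H, W = scene.mask.shape
    positions, (gh, gw) = grid_positions(H, W, patch, stride)
    fill_arr = np.asarray(fill, dtype=float)

    original_score = float(model.class_scores(scene.pixels)[scene.category])
    batch = np.repeat(scene.pixels[None].astype(np.float32), len(positions), axis=0)
    for i, (r, c) in enumerate(positions):
        batch[i, r:r + patch, c:c + patch, :] = fill_arr
    occluded = model.class_scores_batch(batch)[:, scene.category].astype(float)

    if original_score == 0.0:
        grid = np.full((gh, gw), np.nan)
        pixel_map = np.full((H, W), np.nan)
        return ImportanceMap(grid, patch, stride, tuple(fill), 0.0, pixel_map, False)

    grid = ((original_score - occluded) / original_score).reshape(gh, gw)
    acc = np.zeros((H, W))
    cnt = np.zeros((H, W))
    for val, (r, c) in zip(grid.ravel(), positions):
        acc[r:r + patch, c:c + patch] += val
        cnt[r:r + patch, c:c + patch] += 1.0
    with np.errstate(invalid="ignore"):
        pixel_map = np.where(cnt > 0, acc / np.maximum(cnt, 1.0), np.nan)
    return ImportanceMap(grid, patch, stride, tuple(fill), original_score, pixel_map, True)


@dataclass
class RegionImportance:
    """Object/background means of a pixel importance map (importance ratios)."""

    object_importance: float
    background_importance: float
    object_defined: bool
    background_defined: bool
    n_object_pixels: int
    n_background_pixels: int


def region_importance(imap: ImportanceMap, mask: np.ndarray) -> RegionImportance:
    """Average the pixel importance map over the object mask and its
    complement.  Empty regions (all-true or all-false masks) are flagged
    undefined instead of averaged."""
    if not imap.defined:
        raise ValueError("importance map is undefined (original score was 0)")
    if mask.shape != imap.pixel_map.shape:
        raise ValueError(f"mask shape {mask.shape} does not match map {imap.pixel_map.shape}")
    n_obj = int(mask.sum())
    n_bg = int((~mask).sum())
    # drop pixels never covered by any occluder placement (NaN in the map)
    def _mean(sel: np.ndarray) -> float:
        vals = imap.pixel_map[sel]
        vals = vals[np.isfinite(vals)]
        return float(vals.mean()) if len(vals) else float("nan")
    obj = _mean(mask) if n_obj else float("nan")
    bg = _mean(~mask) if n_bg else float("nan")
    return RegionImportance(object_importance=obj, background_importance=bg,
                            object_defined=n_obj > 0 and np.isfinite(obj),
                            background_defined=n_bg > 0 and np.isfinite(bg),
                            n_object_pixels=n_obj, n_background_pixels=n_bg)


def importance_frame(rows: Iterable[dict]) -> pd.DataFrame:
    """Results-CSV schema for region importance summaries."""
    return pd.DataFrame(list(rows), columns=["scene", "condition", "model", "patch",
                                             "object_importance", "background_importance"])


def save_importance_map(imap: ImportanceMap, scene: Scene, path_prefix) -> None:
    """Write an importance map as a CSV grid plus a rendered PNG overlay
    (scene image blended with the pixel map under a diverging colormap)."""
    import matplotlib
    matplotlib.use("Agg")
    from matplotlib import cm, image as mpimg
    from pathlib import Path

    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(f"{prefix}_grid.csv", imap.grid, delimiter=",", fmt="%.6g")
    pm = np.nan_to_num(imap.pixel_map, nan=0.0)
    scale = np.abs(pm).max() or 1.0
    heat = cm.coolwarm(0.5 + 0.5 * pm / scale)[..., :3]
    overlay = np.clip(0.45 * scene.pixels + 0.55 * heat, 0.0, 1.0)
    mpimg.imsave(f"{prefix}_overlay.png", overlay)


# --------------------------------------------------------------------------
# correct-trial filtering
# --------------------------------------------------------------------------

def filter_correct(scenes: Sequence[Scene], model, top_k: int = 1):
    """Keep only scenes whose true class is within the model's top-k scores.

    Returns (subset, per-condition counts).  Attribution averages are computed
    on correct trials only, because relative score changes are uninterpretable
    when the unoccluded score is already near zero.
    """
    if not len(scenes):
        return [], {}
    images = np.asarray([sc.pixels for sc in scenes], dtype=np.float32)
    scores = model.class_scores_batch(images)
    cats = np.array([sc.category for sc in scenes])
    topk_idx = np.argsort(-scores, axis=1, kind="stable")[:, :top_k]
    keep = (topk_idx == cats[:, None]).any(axis=1)
    subset = [sc for sc, k in zip(scenes, keep) if k]
    counts: dict[str, int] = {}
    for sc, k in zip(scenes, keep):
        if k:
            counts[sc.condition] = counts.get(sc.condition, 0) + 1
    if not subset:
        warnings.warn("no correctly classified scenes; downstream averaging will be skipped",
                      stacklevel=2)
    return subset, counts


# --------------------------------------------------------------------------
# filter-activation heatmaps
# --------------------------------------------------------------------------

def layer_heatmap(model, scene: Scene, layer: str) -> np.ndarray:
    """Sum of absolute per-filter activations of one layer: a non-negative
    H' x W' map whose bright parts carry the features the layer responds to."""
    acts = model.layer_activations(scene.pixels, layer)  # (filters, H', W')
    return np.abs(acts).sum(axis=0)
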