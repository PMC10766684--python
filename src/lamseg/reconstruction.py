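"""Sparse-to-dense annotation reconstruction.

Scattered one-hot patch predictions are deposited at their center pixels in
a c-channel sparse map; a w x w windowed sum per channel turns vote counts
into a per-pixel class confidence (the signal density); the per-pixel
argmax over channels gives the rough per-slice labeling; and a
connected-component pass reassigns each structure's small satellite
components to the neighboring structure with the longest shared boundary.
The final volume interleaves the manual annotations (training slices,
verbatim) with the reconstructed slices.

The density window defaults to 51 x 51 — an odd side so the window has a
unique center pixel — and window *sums* are used directly as confidence:
dividing by the constant window area cannot change the argmax.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Sequence

import numpy as np
from skimage.measure import label as cc_label

from .classifier import PatchClassifier, predict_batch
from .localization import SliceSplit
from .sampling import sample_prediction_patches
from .stack_io import LabelScheme, LabelVolume

__all__ = [
    "SparseMap",
    "ConfidenceMaps",
    "build_sparse_map",
    "density_scan",
    "assign_labels",
    "reassign_small_components",
    "reconstruct_slice",
    "assemble_volume",
]


@dataclasses.dataclass
class SparseMap:
    """c-channel accumulation of one-hot votes at sampled patch centers."""

    counts: np.ndarray  # (c, H, W) non-negative ints
    n_filled: int

    @property
    def c(self) -> int:
        return self.counts.shape[0]


@dataclasses.dataclass
class ConfidenceMaps:
    """Windowed vote density per channel (the per-pixel class confidence)."""

    density: np.ndarray  # (c, H, W)
    window_w: int


def build_sparse_map(predictions: Sequence[tuple[tuple[int, int], np.ndarray]],
                     shape: tuple[int, int], c: int) -> SparseMap:
    """Deposit one-hot votes at their centers; repeated centers accumulate."""
    counts = np.zeros((c, *shape), dtype=np.int64)
    for center, one_hot in predictions:
        y, x = center
        if not (0 <= y < shape[0] and 0 <= x < shape[1]):
            raise ValueError(f"center {center} outside slice of shape {shape}")
        k = int(np.argmax(one_hot))
        counts[k, y, x] += 1
    return SparseMap(counts, len(predictions))


def _windowed_sum(channel: np.ndarray, w: int) -> np.ndarray:
    """Exact w x w box sum centered per pixel, zero-padded at borders.

    Computed with an integral image, so it matches the naive double loop
    bit-exactly on integer counts.
    """
    h, wd = channel.shape
    half = w // 2
    ii = np.zeros((h + 1, wd + 1), dtype=np.int64)
    np.cumsum(channel, axis=0, out=ii[1:, 1:])
    np.cumsum(ii[1:, 1:], axis=1, out=ii[1:, 1:])
    y0 = np.clip(np.arange(h) - half, 0, h)
    y1 = np.clip(np.arange(h) + half + 1, 0, h)
    x0 = np.clip(np.arange(wd) - half, 0, wd)
    x1 = np.clip(np.arange(wd) + half + 1, 0, wd)
    return (ii[y1[:, None], x1[None, :]] - ii[y0[:, None], x1[None, :]]
            - ii[y1[:, None], x0[None, :]] + ii[y0[:, None], x0[None, :]])


def density_scan(sm: SparseMap, w: int) -> ConfidenceMaps:
    """Signal density: per channel, the sum of votes in the w x w window
    centered at each pixel (zero padding beyond the slice)."""
    if w < 1:
        raise ValueError("window size must be >= 1")
    if w % 2 == 0:
        raise ValueError("window size must be odd so the window has a center")
    density = np.stack([_windowed_sum(sm.counts[k].astype(np.int64), w)
                        for k in range(sm.c)])
    return ConfidenceMaps(density, w)


def assign_labels(conf: ConfidenceMaps, foreground: np.ndarray) -> np.ndarray:
    """Per-pixel argmax labeling inside the foreground.

    Ties break toward the lowest channel; pixels with zero confidence in
    every channel, or outside the foreground, become background.
    """
    foreground = np.asarray(foreground, dtype=bool)
    if foreground.shape != conf.density.shape[1:]:
        raise ValueError("foreground shape does not match confidence maps")
    winner = np.argmax(conf.density, axis=0).astype(np.int64) + 1
    total = conf.density.sum(axis=0)
    labels = np.where(foreground & (total > 0), winner, 0)
    return labels.astype(np.uint8 if conf.density.shape[0] <= 255 else np.int32)


def reassign_small_components(rr: np.ndarray, min_fraction: float) -> np.ndarray:
    """Relabel each structure's small satellite components.

    For every structure, 8-connected components with area below
    ``min_fraction`` x (that structure's largest component area) are handed
    to the neighboring structure sharing the longest boundary with them
    (ties to the lowest structure id); background wins only when it is the
    only neighbor. Single pass: all reassignments are decided on the input
    labeling, then applied together.
    """
    if not 0 <= min_fraction < 1:
        raise ValueError("min_fraction must be in [0, 1)")
    rr = np.asarray(rr)
    out = rr.copy()
    structures = [int(s) for s in np.unique(rr) if s != 0]
    for s in structures:
        comps = cc_label(rr == s, connectivity=2)
        n_comp = comps.max()
        if n_comp <= 1:
            continue
        areas = np.bincount(comps.ravel())[1:]
        threshold = min_fraction * areas.max()
        for ci in np.flatnonzero(areas < threshold):
            comp_mask = comps == ci + 1
            target = _longest_boundary_neighbor(rr, comp_mask)
            out[comp_mask] = target
    return out


def _longest_boundary_neighbor(rr: np.ndarray, comp_mask: np.ndarray) -> int:
    """Label (possibly 0) of the 8-connected neighbor with the longest
    shared boundary; structures beat background, ties to lowest id."""
    ys, xs = np.nonzero(comp_mask)
    h, w = rr.shape
    y0, y1 = max(0, ys.min() - 1), min(h, ys.max() + 2)
    x0, x1 = max(0, xs.min() - 1), min(w, xs.max() + 2)
    sub = comp_mask[y0:y1, x0:x1]
    ring = np.zeros_like(sub)
    # 8-connected dilation by one pixel via shifts
    for dy in (-1, 0, 1):
        for dx in (-1, 0, 1):
            if dy == 0 and dx == 0:
                continue
            src = sub[max(0, -dy):sub.shape[0] - max(0, dy),
                      max(0, -dx):sub.shape[1] - max(0, dx)]
            ring[max(0, dy):ring.shape[0] - max(0, -dy),
                 max(0, dx):ring.shape[1] - max(0, -dx)] |= src
    ring &= ~sub
    neighbor_labels = rr[y0:y1, x0:x1][ring]
    if neighbor_labels.size == 0:
        return 0
    counts = np.bincount(neighbor_labels)
    if counts.size > 1 and counts[1:].max() > 0:
        return int(np.argmax(counts[1:]) + 1)  # longest boundary, lowest id wins ties
    return 0


def reconstruct_slice(slice_img: np.ndarray, foreground: np.ndarray,
                      model: PatchClassifier, m: int, p: int, w: int,
                      rng: np.random.Generator,
                      min_component_fraction: float = 0.05,
                      slice_index: int = 0) -> np.ndarray:
    """Full per-slice reconstruction: sample, classify, densify, relabel."""
    if m == 0:
        warnings.warn(f"slice {slice_index}: m=0 patches, returning background",
                      stacklevel=2)
        return np.zeros_like(np.asarray(foreground), dtype=np.uint8)
    patches = sample_prediction_patches(slice_img, foreground, m, p, rng,
                                        slice_index)
    preds = predict_batch(model, patches)
    sm = build_sparse_map([(center, oh) for center, _, oh in preds],
                          np.asarray(slice_img).shape, model.c)
    conf = density_scan(sm, w)
    rough = assign_labels(conf, foreground)
    return reassign_small_components(rough, min_component_fraction)


def assemble_volume(split: SliceSplit,
                    training_annotations: Mapping[int, np.ndarray],
                    predicted: Mapping[int, np.ndarray],
                    scheme: LabelScheme | None = None) -> LabelVolume:
    """Interleave manual and reconstructed slices in z order.

    Training slices carry their manual annotations bit-identically.
    """
    scheme = scheme or LabelScheme()
    all_idx = sorted(set(split.training_indices) | set(split.predicting_indices))
    dup = set(training_annotations) & set(predicted)
    if dup:
        raise ValueError(f"slices covered by both maps: {sorted(dup)}")
    missing = [i for i in all_idx
               if i not in training_annotations and i not in predicted]
    if missing:
        raise ValueError(f"slices covered by neither map: {missing}")
    no_annot = [i for i in split.training_indices if i not in training_annotations]
    if no_annot:
        raise ValueError(f"training slices without annotations: {no_annot}")
    first = training_annotations.get(split.training_indices[0])
    shape = np.asarray(first).shape
    labels = np.zeros((split.n_slices, *shape), dtype=np.uint8)
    for i in split.training_indices:
        labels[i] = training_annotations[i]
    for i in split.predicting_indices:
        labels[i] = predicted[i]
    return LabelVolume(labels, scheme=scheme)
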