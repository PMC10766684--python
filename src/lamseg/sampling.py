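"""Patch extraction and random patch sampling.

Training patches are drawn uniformly (with replacement) from the *undilated*
labeled pixels of an annotated slice, each carrying the structure label of
its center pixel. Prediction patches are drawn uniformly from a slice's
initial foreground mask and carry no label. Patches whose window crosses the
image border are completed by reflect padding, so every eligible center is
sampled without bias against thin peripheral layers.

The center-pixel convention for a p x p patch (p even or odd) is
``(p // 2, p // 2)``.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

__all__ = [
    "PatchSample",
    "extract_patch",
    "extract_patches_batch",
    "sample_training_patches",
    "sample_prediction_patches",
    "split_train_val",
]


@dataclasses.dataclass
class PatchSample:
    """One p x p grayscale window with its provenance."""

    pixels: np.ndarray
    center_yx: tuple[int, int]
    slice_index: int = 0
    label: int | None = None


def _check_center(slice_shape: tuple[int, int], center_yx: tuple[int, int]) -> None:
    y, x = center_yx
    h, w = slice_shape
    if not (0 <= y < h and 0 <= x < w):
        raise ValueError(f"center {center_yx} outside slice of shape {slice_shape}")


def extract_patch(slice_img: np.ndarray, center_yx: tuple[int, int],
                  p: int) -> np.ndarray:
    """Window of side ``p`` centered at ``center_yx``, reflect-padded at borders."""
    if p < 1:
        raise ValueError("patch size must be >= 1")
    slice_img = np.asarray(slice_img)
    _check_center(slice_img.shape, center_yx)
    half = p // 2
    y, x = center_yx
    y0, x0 = y - half, x - half
    pad = max(0, -min(y0, x0),
              y0 + p - slice_img.shape[0], x0 + p - slice_img.shape[1])
    if pad > 0:
        padded = np.pad(slice_img, pad, mode="reflect")
        return padded[y0 + pad:y0 + pad + p, x0 + pad:x0 + pad + p].copy()
    return slice_img[y0:y0 + p, x0:x0 + p].copy()


def extract_patches_batch(slice_img: np.ndarray, centers_yx: np.ndarray,
                          p: int) -> np.ndarray:
    """Vectorized extraction of many patches from one slice.

    Returns an array of shape ``(m, p, p)``; equivalent to calling
    :func:`extract_patch` per center.
    """
    slice_img = np.asarray(slice_img)
    centers_yx = np.asarray(centers_yx)
    if centers_yx.size == 0:
        return np.empty((0, p, p), dtype=slice_img.dtype)
    half = p // 2
    pad = p  # generous: covers any center inside the slice
    padded = np.pad(slice_img, pad, mode="reflect")
    windows = np.lib.stride_tricks.sliding_window_view(padded, (p, p))
    ys = centers_yx[:, 0] - half + pad
    xs = centers_yx[:, 1] - half + pad
    return windows[ys, xs]


def sample_training_patches(slice_img: np.ndarray, annotation: np.ndarray,
                            m: int, p: int, rng: np.random.Generator,
                            slice_index: int = 0) -> list[PatchSample]:
    """Draw ``m`` labeled patches with centers uniform over labeled pixels."""
    annotation = np.asarray(annotation)
    eligible = np.flatnonzero(annotation > 0)
    if eligible.size == 0:
        raise ValueError(
            f"slice {slice_index}: annotation has no labeled pixels to sample")
    w = annotation.shape[1]
    chosen = eligible[rng.integers(0, eligible.size, size=m)]
    centers = np.stack(np.divmod(chosen, w), axis=1)
    patches = extract_patches_batch(slice_img, centers, p)
    labels = annotation.ravel()[chosen]
    return [
        PatchSample(patches[i], (int(centers[i, 0]), int(centers[i, 1])),
                    slice_index, int(labels[i]))
        for i in range(m)
    ]


def sample_prediction_patches(slice_img: np.ndarray, foreground: np.ndarray,
                              m: int, p: int, rng: np.random.Generator,
                              slice_index: int = 0) -> list[PatchSample]:
    """Draw ``m`` unlabeled patches with centers uniform over the foreground."""
    foreground = np.asarray(foreground, dtype=bool)
    eligible = np.flatnonzero(foreground)
    if eligible.size == 0:
        raise ValueError(f"slice {slice_index}: initial foreground is empty")
    w = foreground.shape[1]
    chosen = eligible[rng.integers(0, eligible.size, size=m)]
    centers = np.stack(np.divmod(chosen, w), axis=1)
    patches = extract_patches_batch(slice_img, centers, p)
    return [
        PatchSample(patches[i], (int(centers[i, 0]), int(centers[i, 1])),
                    slice_index, None)
        for i in range(m)
    ]


def split_train_val(samples: Sequence[PatchSample], train_fraction: float,
                    rng: np.random.Generator) -> tuple[list[PatchSample], list[PatchSample]]:
    """Random disjoint train/validation split (default protocol: 70/30)."""
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    if len(samples) < 2:
        raise ValueError("need at least 2 samples to split")
    order = rng.permutation(len(samples))
    n_train = int(round(train_fraction * len(samples)))
    n_train = min(max(n_train, 1), len(samples) - 1)
    train = [samples[i] for i in order[:n_train]]
    val = [samples[i] for i in order[n_train:]]
    return train, val
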