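"""Initial localization: slice splitting and foreground interpolation.

Manual annotation on every n-th slice both trains the classifier and tells
the predictor *where* to look. The annotated slices' binarized, dilated
label maps form their foreground; un-annotated slices borrow the foreground
of the nearest annotated slice (nearest-neighbor interpolation along z —
never a blend, always a copy).
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping

import numpy as np
from scipy import ndimage

__all__ = [
    "SliceSplit",
    "split_slices",
    "disc_structuring_element",
    "annotation_foreground",
    "interpolate_foreground",
    "build_initial_foreground",
]


@dataclasses.dataclass(frozen=True)
class SliceSplit:
    """Partition of slice indices into training (annotated) and predicting."""

    training_indices: tuple[int, ...]
    predicting_indices: tuple[int, ...]
    interval_n: int

    @property
    def n_slices(self) -> int:
        return len(self.training_indices) + len(self.predicting_indices)


def split_slices(n_slices: int, interval_n: int) -> SliceSplit:
    """Every ``interval_n``-th slice (starting at 0) becomes a training slice.

    Following the reference protocol at full scale: 2900 slices at interval
    100 yields 29 annotated training slices. More than 100 training slices
    triggers a warning (the method was designed for sparse annotation).
    """
    if interval_n < 1:
        raise ValueError("interval_n must be >= 1")
    if interval_n >= n_slices:
        raise ValueError(
            f"interval_n={interval_n} must be smaller than n_slices={n_slices}"
        )
    training = tuple(range(0, n_slices, interval_n))
    predicting = tuple(i for i in range(n_slices) if i % interval_n != 0)
    if len(training) > 100:
        warnings.warn(
            f"{len(training)} training slices exceeds the intended sparse-"
            "annotation regime (<= 100)", stacklevel=2)
    return SliceSplit(training, predicting, interval_n)


def disc_structuring_element(radius: int) -> np.ndarray:
    """Binary disc: pixels within Euclidean distance ``radius`` of the center."""
    if radius < 0:
        raise ValueError("radius must be >= 0")
    yy, xx = np.mgrid[-radius:radius + 1, -radius:radius + 1]
    return (yy * yy + xx * xx) <= radius * radius


def annotation_foreground(annotation: np.ndarray, dilation_radius: int) -> np.ndarray:
    """Binarize a label slice and dilate it with a disc of the given radius."""
    fg = np.asarray(annotation) > 0
    if dilation_radius == 0:
        return fg
    return ndimage.binary_dilation(
        fg, structure=disc_structuring_element(dilation_radius))


def interpolate_foreground(fg_a: np.ndarray, fg_b: np.ndarray,
                           interval_n: int) -> list[np.ndarray]:
    """Nearest-neighbor masks for the ``interval_n - 1`` slices between two
    annotated slices at offsets 0 and ``interval_n``.

    Offset k gets a copy of ``fg_a`` if k <= n/2 else ``fg_b``; the midpoint
    tie for even n goes to the earlier slice (``fg_a``).
    """
    fg_a = np.asarray(fg_a, dtype=bool)
    fg_b = np.asarray(fg_b, dtype=bool)
    if fg_a.shape != fg_b.shape:
        raise ValueError(f"mask shapes differ: {fg_a.shape} vs {fg_b.shape}")
    if interval_n < 1:
        raise ValueError("interval_n must be >= 1")
    return [
        fg_a.copy() if 2 * k <= interval_n else fg_b.copy()
        for k in range(1, interval_n)
    ]


def build_initial_foreground(split: SliceSplit,
                             annotations: Mapping[int, np.ndarray],
                             dilation_radius: int) -> np.ndarray:
    """Per-slice initial foreground for the whole stack.

    Training slices use their own dilated annotation; predicting slices copy
    the nearest training slice's foreground (midpoint ties to the earlier
    slice, slices past the last annotated one reuse its foreground).
    """
    missing = [i for i in split.training_indices if i not in annotations]
    if missing:
        raise ValueError(f"missing annotation for training slices {missing}")
    tc = np.asarray(split.training_indices)
    fgs = {i: annotation_foreground(annotations[i], dilation_radius) for i in tc}
    shape = next(iter(fgs.values())).shape
    out = np.zeros((split.n_slices, *shape), dtype=bool)
    for i in tc:
        out[i] = fgs[i]
    for i in split.predicting_indices:
        below = tc[tc < i]
        above = tc[tc > i]
        if below.size == 0:
            nearest = int(above[0])
        elif above.size == 0:
            nearest = int(below[-1])
        else:
            lo, hi = int(below[-1]), int(above[0])
            # tie at the exact midpoint goes to the earlier (lower-z) slice
            nearest = lo if 2 * (i - lo) <= (hi - lo) else hi
        out[i] = fgs[nearest]
    return out
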