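"""Slice-stack and label-volume I/O plus run configuration.

Single source of truth for the package's conventions:

* arrays are indexed ``(z, y, x)``, 0-based, pixel centers at integer
  coordinates;
* label maps are integer images, 0 = background, 1..c = structures;
* grayscale only — RGB inputs are rejected rather than silently converted.
"""

from __future__ import annotations

import dataclasses
import os
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import tifffile
import yaml
from imageio.v3 import imread as _imread, imwrite as _imwrite

__all__ = [
    "SliceStack",
    "LabelScheme",
    "LabelVolume",
    "PipelineConfig",
    "DEFAULT_MOB_NAMES",
    "read_slice_stack",
    "write_slice_stack",
    "read_label_volume",
    "write_label_volume",
    "load_config",
]

#: The ten olfactory-area structures of the default label scheme: the five
#: concentric MOB laminae followed by the non-laminar structures.
DEFAULT_MOB_NAMES = (
    "GL", "EPL", "ML", "IPL", "GCL", "AOB", "AON", "SEZ", "aco", "lotg",
)

_IMAGE_SUFFIXES = (".tif", ".tiff", ".png")


@dataclasses.dataclass
class SliceStack:
    """A z-ordered stack of 2D grayscale slices.

    Parameters
    ----------
    voxels
        3D array indexed ``(z, y, x)``; integer intensities in [0, 255] /
        [0, 65535] or floats in [0, 1].
    pixel_size_um
        In-plane pixel size in micrometres (isotropic).
    """

    voxels: np.ndarray
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(
                f"voxels must be 3D (z, y, x), got shape {self.voxels.shape}"
            )
        if self.voxels.shape[0] < 1:
            raise ValueError("a SliceStack needs at least one slice")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    @property
    def slice_shape(self) -> tuple[int, int]:
        return self.voxels.shape[1], self.voxels.shape[2]

    def __getitem__(self, z: int) -> np.ndarray:
        return self.voxels[z]


@dataclasses.dataclass(frozen=True)
class LabelScheme:
    """Names the c structures; label value i maps to ``names[i - 1]``."""

    names: tuple[str, ...] = DEFAULT_MOB_NAMES

    def __post_init__(self) -> None:
        object.__setattr__(self, "names", tuple(self.names))
        if len(self.names) < 1:
            raise ValueError("a LabelScheme needs at least one structure")
        if any(not n for n in self.names):
            raise ValueError("structure names must be non-empty")
        if len(set(self.names)) != len(self.names):
            raise ValueError("structure names must be unique")

    @property
    def c(self) -> int:
        return len(self.names)

    def name_of(self, label: int) -> str:
        if not 1 <= label <= self.c:
            raise ValueError(f"label {label} outside 1..{self.c}")
        return self.names[label - 1]


@dataclasses.dataclass
class LabelVolume:
    """Integer segmentation volume aligned with a :class:`SliceStack`."""

    labels: np.ndarray
    scheme: LabelScheme = dataclasses.field(default_factory=LabelScheme)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be 3D (z, y, x)")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integer-valued")
        _validate_label_range(self.labels, self.scheme.c)

    @property
    def n_slices(self) -> int:
        return self.labels.shape[0]

    def __getitem__(self, z: int) -> np.ndarray:
        return self.labels[z]


def _validate_label_range(labels: np.ndarray, c: int) -> None:
    if labels.size == 0:
        return
    if labels.min() < 0:
        raise ValueError("negative label values present")
    if labels.max() > c:
        bad = np.argwhere(labels > c)[0]
        raise ValueError(
            f"label value {int(labels[tuple(bad)])} at slice {int(bad[0])} "
            f"exceeds the scheme's {c} structures"
        )


# ---------------------------------------------------------------------------
# image stack I/O


def _read_any_image(path: Path) -> np.ndarray:
    """Read one TIFF (possibly multi-page) or PNG; reject multi-channel."""
    if path.suffix.lower() in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tif:
            if tif.pages[0].samplesperpixel != 1:
                raise ValueError(
                    f"{path}: RGB(A) images are not supported; convert to "
                    "single-channel grayscale first")
            return tif.asarray()
    arr = _imread(path)
    if arr.ndim == 3:
        raise ValueError(f"{path}: RGB(A) images are not supported; convert "
                         "to single-channel grayscale first")
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a 2D grayscale image, "
                         f"got shape {arr.shape}")
    return arr


def read_slice_stack(path: str | os.PathLike, pixel_size_um: float = 1.0) -> SliceStack:
    """Read a multi-page TIFF or a directory of single-page TIFF/PNG files.

    Slices are ordered by TIFF page or by lexicographic filename.
    8/16-bit integer intensities are preserved bit-exactly.
    """
    arr = _read_stack_array(Path(path))
    return SliceStack(arr, pixel_size_um=pixel_size_um)


def _read_stack_array(path: Path) -> np.ndarray:
    if not path.exists():
        raise FileNotFoundError(f"no such file or directory: {path}")
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in _IMAGE_SUFFIXES
        )
        if not files:
            raise ValueError(f"{path}: no TIFF/PNG slices found")
        slices = []
        shape = None
        for f in files:
            img = _read_any_image(f)
            if img.ndim != 2:
                raise ValueError(f"{f}: expected one 2D image per file")
            if shape is None:
                shape = img.shape
            elif img.shape != shape:
                raise ValueError(
                    f"{f}: slice shape {img.shape} differs from first slice {shape}"
                )
            slices.append(img)
        return np.stack(slices, axis=0)
    arr = _read_any_image(path)
    if arr.ndim == 2:  # single-page file: one-slice stack
        arr = arr[None]
    return arr


def write_slice_stack(stack: SliceStack, path: str | os.PathLike) -> None:
    """Write a stack so that :func:`read_slice_stack` round-trips bit-exactly.

    ``path`` ending in .tif/.tiff writes one multi-page TIFF; otherwise a
    directory of zero-padded PNG (8/16-bit) or TIFF slices is created.
    """
    _write_stack_array(stack.voxels, Path(path))


def _write_stack_array(arr: np.ndarray, path: Path) -> None:
    if arr.shape[0] < 1:
        raise ValueError("refusing to write an empty stack")
    if path.suffix.lower() in (".tif", ".tiff"):
        path.parent.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(path, arr, photometric="minisblack")
        return
    path.mkdir(parents=True, exist_ok=True)
    width = max(4, len(str(arr.shape[0] - 1)))
    suffix = ".png" if arr.dtype in (np.uint8, np.uint16) else ".tif"
    for z in range(arr.shape[0]):
        f = path / f"s{z:0{width}d}{suffix}"
        if suffix == ".png":
            _imwrite(f, arr[z])
        else:
            tifffile.imwrite(f, arr[z])


def read_label_volume(path: str | os.PathLike,
                      scheme: LabelScheme | None = None) -> LabelVolume:
    """Read an integer label stack and validate it against ``scheme``."""
    scheme = scheme or LabelScheme()
    arr = _read_stack_array(Path(path))
    if not np.issubdtype(arr.dtype, np.integer):
        raise ValueError(f"{path}: label images must be integer-valued, "
                         f"got dtype {arr.dtype}")
    return LabelVolume(arr, scheme=scheme)


def write_label_volume(volume: LabelVolume, path: str | os.PathLike) -> None:
    labels = volume.labels
    if volume.scheme.c <= 255 and labels.dtype != np.uint8:
        labels = labels.astype(np.uint8)
    _write_stack_array(labels, Path(path))


# ---------------------------------------------------------------------------
# pipeline configuration


@dataclasses.dataclass
class PipelineConfig:
    """All tunables of the train/predict workflow.

    Defaults are the full-scale operating point (1 um/px coronal slices):
    annotate every 100th slice, 800 px receptive field downsampled to
    100x100 classifier input, 220,000 training patches, 100,000 prediction
    patches per slice, 51x51 density window, 50 px foreground dilation.
    """

    slice_interval_n: int = 100
    patch_size_p: int = 800
    input_downsample_d: int = 100
    train_patches_total: int = 220_000
    predict_patches_per_slice: int = 100_000
    density_window_w: int = 51
    dilation_radius: int = 50
    min_component_fraction: float = 0.05
    seed: int = 0
    label_names: tuple[str, ...] = DEFAULT_MOB_NAMES
    classifier: Mapping[str, object] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        errors = []
        for key in ("slice_interval_n", "patch_size_p", "input_downsample_d",
                    "train_patches_total", "predict_patches_per_slice",
                    "density_window_w"):
            if getattr(self, key) < 1:
                errors.append(f"{key} must be positive")
        if self.density_window_w % 2 == 0:
            errors.append("density_window_w must be odd")
        if self.dilation_radius < 0:
            errors.append("dilation_radius must be >= 0")
        if not 0 <= self.min_component_fraction < 1:
            errors.append("min_component_fraction must be in [0, 1)")
        if errors:
            raise ValueError("invalid configuration: " + "; ".join(errors))
        self.label_names = tuple(self.label_names)

    @property
    def scheme(self) -> LabelScheme:
        return LabelScheme(self.label_names)


def load_config(path: str | os.PathLike) -> PipelineConfig:
    """Load a YAML config; missing keys take defaults, unknown keys error."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ValueError(f"{path}: unknown config keys: {', '.join(unknown)}")
    return PipelineConfig(**raw)
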