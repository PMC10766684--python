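"""Synthetic layered-cytoarchitecture phantoms with ground-truth labels.

Nissl staining marks neuronal somata, so in micron-resolution images the
concentric laminae of the main olfactory bulb differ mainly in *texture* —
the density and size of dark soma-like dots — not in mean tissue intensity.
The phantom emulates exactly that: concentric elliptical annuli whose
cross-section morphs smoothly along z, each annulus filled with a Poisson
point process of dots with layer-specific density, radius and contrast, on
a shared tissue background, plus clipped additive Gaussian noise.

Two presets mirror the regimes downstream code is tested in: ``easy``
(well-separated dot densities, comfortably thick layers) and ``hard``
(closer densities and one thin lamina, the analogue of the mitral-cell
layer whose narrowest extent is only a few micrometres).
"""

from __future__ import annotations

import dataclasses
import json
import os
from typing import Sequence

import numpy as np

from .stack_io import LabelScheme, LabelVolume, SliceStack

__all__ = [
    "LayerSpec",
    "PhantomSpec",
    "layer_masks",
    "render_slice",
    "generate_phantom",
    "easy_spec",
    "hard_spec",
    "save_spec_json",
]


@dataclasses.dataclass(frozen=True)
class LayerSpec:
    """One concentric layer.

    ``radius_profile`` is the layer's *outer* boundary, expressed per slice
    as a fraction of the largest inscribable ellipse; it must be smooth in z
    and strictly ordered across layers (outermost first). ``dot_density`` is
    the expected number of dots per 100x100 px patch of this layer.
    """

    label: int
    radius_profile: Sequence[float]
    dot_density: float
    dot_radius_px: float = 2.0
    dot_intensity: float = 0.2
    background_intensity: float = 0.8
    noise_sd: float = 0.02

    def __post_init__(self) -> None:
        object.__setattr__(self, "radius_profile",
                           tuple(float(r) for r in self.radius_profile))
        if self.label < 1:
            raise ValueError("layer label must be >= 1")
        if self.dot_density < 0:
            raise ValueError("dot_density must be >= 0")
        if not (0 <= self.dot_intensity <= 1 and 0 <= self.background_intensity <= 1):
            raise ValueError("intensities must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if any(not 0 < r <= 1 for r in self.radius_profile):
            raise ValueError("radius fractions must lie in (0, 1]")


@dataclasses.dataclass(frozen=True)
class PhantomSpec:
    height: int
    width: int
    n_slices: int
    layers: tuple[LayerSpec, ...]
    seed: int = 0
    outside_intensity: float = 0.95
    outside_noise_sd: float = 0.01

    def __post_init__(self) -> None:
        object.__setattr__(self, "layers", tuple(self.layers))
        if self.height < 1 or self.width < 1 or self.n_slices < 1:
            raise ValueError("height, width and n_slices must be positive")
        if len(self.layers) < 2:
            raise ValueError("need at least 2 layers")
        for layer in self.layers:
            if len(layer.radius_profile) != self.n_slices:
                raise ValueError(
                    f"layer {layer.label}: radius_profile has "
                    f"{len(layer.radius_profile)} entries, expected {self.n_slices}"
                )
        for z in range(self.n_slices):
            radii = [layer.radius_profile[z] for layer in self.layers]
            if any(a <= b for a, b in zip(radii, radii[1:])):
                raise ValueError(
                    f"radius profiles cross at slice {z}: {radii} "
                    "(must be strictly decreasing outermost-first)"
                )

    @property
    def c(self) -> int:
        return max(layer.label for layer in self.layers)

    def scheme(self) -> LabelScheme:
        names = [f"L{i}" for i in range(1, self.c + 1)]
        for layer in self.layers:
            names[layer.label - 1] = f"L{layer.label}"
        return LabelScheme(tuple(names))


def _normalized_radius(spec: PhantomSpec) -> np.ndarray:
    """Per-pixel radius, 1.0 on the largest centered inscribed ellipse."""
    cy, cx = (spec.height - 1) / 2.0, (spec.width - 1) / 2.0
    yy = (np.arange(spec.height) - cy) / (spec.height / 2.0)
    xx = (np.arange(spec.width) - cx) / (spec.width / 2.0)
    return np.sqrt(yy[:, None] ** 2 + xx[None, :] ** 2)


def layer_masks(spec: PhantomSpec, z: int) -> np.ndarray:
    """Ground-truth label slice at index ``z``.

    Layer j occupies the elliptical annulus between its own outer radius and
    the next (inner) layer's outer radius; the innermost layer is a full
    ellipse. Every pixel receives exactly one label in {0..c}.
    """
    if not 0 <= z < spec.n_slices:
        raise ValueError(f"slice index {z} outside 0..{spec.n_slices - 1}")
    r = _normalized_radius(spec)
    labels = np.zeros((spec.height, spec.width), dtype=np.uint8)
    # paint outermost-first so inner layers overwrite their enclosed region
    for layer in spec.layers:
        labels[r <= layer.radius_profile[z]] = layer.label
    return labels


def sample_dot_centers(layer: LayerSpec, inside: np.ndarray,
                       rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Poisson point process of dot centers over a layer's pixels.

    The realized dot count is Poisson with mean ``dot_density x area / 1e4``;
    centers are uniform over the layer mask. Returns (rows, cols).
    """
    area = int(inside.sum())
    if area == 0 or layer.dot_density == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    n_dots = rng.poisson(layer.dot_density * area / 1e4)
    if n_dots == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    flat = np.flatnonzero(inside)
    centers = flat[rng.integers(0, flat.size, size=n_dots)]
    return np.divmod(centers, inside.shape[1])


def render_slice(mask: np.ndarray, spec: PhantomSpec,
                 rng: np.random.Generator) -> np.ndarray:
    """Render one grayscale slice from its label mask.

    Each layer contributes a Poisson number of dots (mean density x area /
    10^4) at uniformly chosen pixels of the layer; dots are painted as discs
    and may cross layer boundaries, as real somata do. Gaussian noise is
    added per-pixel and the result clipped to [0, 1].
    """
    h, w = mask.shape
    img = np.full((h, w), spec.outside_intensity, dtype=np.float64)
    noise_sd = np.full((h, w), spec.outside_noise_sd, dtype=np.float64)
    for layer in spec.layers:
        inside = mask == layer.label
        img[inside] = layer.background_intensity
        noise_sd[inside] = layer.noise_sd
    yy, xx = np.mgrid[0:h, 0:w]
    for layer in spec.layers:
        inside = mask == layer.label
        cys, cxs = sample_dot_centers(layer, inside, rng)
        if cys.size == 0:
            continue
        rad = layer.dot_radius_px
        ri = int(np.ceil(rad))
        for cy, cx in zip(cys, cxs):
            y0, y1 = max(0, cy - ri), min(h, cy + ri + 1)
            x0, x1 = max(0, cx - ri), min(w, cx + ri + 1)
            disc = ((yy[y0:y1, x0:x1] - cy) ** 2
                    + (xx[y0:y1, x0:x1] - cx) ** 2) <= rad * rad
            img[y0:y1, x0:x1][disc] = layer.dot_intensity
    img += rng.normal(0.0, 1.0, size=(h, w)) * noise_sd
    return np.clip(img, 0.0, 1.0)


def generate_phantom(spec: PhantomSpec) -> tuple[SliceStack, LabelVolume]:
    """Generate the full (stack, ground-truth labels) pair.

    Each slice uses an RNG stream derived from ``(spec.seed, z)``, so the
    output is fully determined by the spec and independent of render order.
    """
    stacks = np.empty((spec.n_slices, spec.height, spec.width), dtype=np.float64)
    labels = np.empty((spec.n_slices, spec.height, spec.width), dtype=np.uint8)
    for z in range(spec.n_slices):
        mask = layer_masks(spec, z)
        rng = np.random.default_rng([spec.seed, z])
        stacks[z] = render_slice(mask, spec, rng)
        labels[z] = mask
    return SliceStack(stacks), LabelVolume(labels, scheme=spec.scheme())


def _bulge_profile(n_slices: int, base: float, amplitude: float = 0.25) -> tuple[float, ...]:
    """Smooth axial morphing: the cross-section bulges mid-stack."""
    z = np.arange(n_slices)
    scale = (1 - amplitude) + amplitude * np.sin(np.pi * (z + 0.5) / n_slices)
    return tuple(base * scale)


def easy_spec(height: int = 512, width: int = 512, n_slices: int = 30,
              seed: int = 0) -> PhantomSpec:
    """Five thick concentric layers with widely separated soma coverage.

    Densities and dot radii are chosen so the fraction of tissue covered by
    dots is well separated between every pair of adjacent layers
    (roughly 2 / 30 / 12 / 55 / 80 percent going inward), and the radii so
    that every layer — including the innermost disc — spans the default
    51 px density window comfortably; windowed majority voting erodes
    convex structures whose radius is comparable to the window side.
    """
    fracs = (0.92, 0.75, 0.60, 0.44, 0.28)
    densities = (22.0, 275.0, 60.0, 890.0, 550.0)
    radii = (1.5, 2.0, 2.5, 1.5, 3.0)
    layers = tuple(
        LayerSpec(
            label=i + 1,
            radius_profile=_bulge_profile(n_slices, fracs[i], amplitude=0.15),
            dot_density=densities[i],
            dot_radius_px=radii[i],
        )
        for i in range(5)
    )
    return PhantomSpec(height, width, n_slices, layers, seed=seed)


def hard_spec(height: int = 512, width: int = 512, n_slices: int = 30,
              seed: int = 0) -> PhantomSpec:
    """Closer soma coverages and one thin lamina (mitral-layer analogue).

    Layer 2 is a ~20 px annulus — thin relative to the 51 px density
    window — and adjacent coverages differ far less than in ``easy``.
    """
    fracs = (0.92, 0.74, 0.66, 0.45, 0.20)
    densities = (64.0, 664.0, 172.0, 436.0, 331.0)
    radii = (2.0, 1.5, 2.0, 2.5, 2.0)
    layers = tuple(
        LayerSpec(
            label=i + 1,
            radius_profile=_bulge_profile(n_slices, fracs[i], amplitude=0.15),
            dot_density=densities[i],
            dot_radius_px=radii[i],
            noise_sd=0.04,
        )
        for i in range(5)
    )
    return PhantomSpec(height, width, n_slices, layers, seed=seed)


PRESETS = {"easy": easy_spec, "hard": hard_spec}


def save_spec_json(spec: PhantomSpec, path: str | os.PathLike) -> None:
    """Write the spec as a JSON sidecar next to generated image stacks."""
    payload = dataclasses.asdict(spec)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
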