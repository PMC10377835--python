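"""Seeded generators of lesion-like images and labeled feature tables.

Every module of the pipeline is testable without any download: the image
generator emits a textured background with an embedded elliptical lesion
whose *texture statistics* differ by class (cancer-like lesions carry a
higher-amplitude, finer-grained texture and an irregular boundary;
benign-like lesions a smoother, lower-amplitude one), corrupted by impulse
and Gaussian noise.  The class signal lives in texture, not in mean
intensity, so segmentation and the co-occurrence/run-length features —
rather than a trivial intensity threshold — must carry it.  The table
generator emits two-class Gaussian feature tables with a known informative
subset.  Both generators are pure functions of their spec (seed included).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .selection import LabeledFeatureTable

CANCER_LABEL = 1
BENIGN_LABEL = -1


@dataclass(frozen=True)
class SyntheticImageSpec:
    """Recipe for one synthetic lesion photograph.

    Geometry fields left as None are drawn (seeded) from ranges that keep
    the ellipse fully inside the frame.  Texture amplitudes are gray
    levels; texture scale is the Gaussian smoothing sigma of the underlying
    white noise (larger = coarser blobs, chosen to survive a 7x7 median
    filter).  ``boundary_wobble`` perturbs the lesion radius with low-order
    harmonics, making cancer-like boundaries irregular.
    """

    kind: str = "cancer"  # "cancer" or "benign"
    side: int = 256
    seed: int = 0
    center: tuple[float, float] | None = None
    axes: tuple[float, float] | None = None
    angle: float | None = None
    background_level: float = 110.0
    background_amplitude: float = 6.0
    background_scale: float = 4.0
    lesion_level: float = 135.0
    lesion_amplitude: float | None = None  # per-class default when None
    lesion_scale: float | None = None
    boundary_wobble: float | None = None
    impulse_fraction: float = 0.02
    gaussian_sigma: float = 3.0

    def __post_init__(self) -> None:
        if self.kind not in ("cancer", "benign"):
            raise ValueError(f"kind must be 'cancer' or 'benign', got {self.kind!r}")
        if not (0.0 <= self.impulse_fraction <= 0.2):
            raise ValueError("impulse_fraction must lie in [0, 0.2]")

    @property
    def label(self) -> int:
        return CANCER_LABEL if self.kind == "cancer" else BENIGN_LABEL


#: Class-conditional texture defaults: (amplitude, scale, boundary wobble).
_CLASS_TEXTURE = {
    "cancer": (55.0, 2.5, 0.10),
    "benign": (25.0, 4.0, 0.0),
}


def _smooth_noise(rng: np.random.Generator, side: int, scale: float) -> np.ndarray:
    """Zero-mean, unit-std spatially correlated noise field."""
    raw = ndimage.gaussian_filter(rng.standard_normal((side, side)), scale)
    sd = raw.std()
    return raw / sd if sd > 0 else raw


def generate_image(
    spec: SyntheticImageSpec,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Render one synthetic lesion image.

    Returns (8-bit grayscale image, exact boolean lesion mask, class
    label +1 cancer-like / -1 benign-like).
    """
    rng = np.random.default_rng(spec.seed)
    side = spec.side
    amp, scale, wobble = _CLASS_TEXTURE[spec.kind]
    amp = spec.lesion_amplitude if spec.lesion_amplitude is not None else amp
    scale = spec.lesion_scale if spec.lesion_scale is not None else scale
    wobble = spec.boundary_wobble if spec.boundary_wobble is not None else wobble

    # geometry (drawn before any texture so mask generation is stable)
    if spec.center is None:
        cy, cx = rng.uniform(0.45 * side, 0.55 * side, size=2)
    else:
        cy, cx = spec.center
    if spec.axes is None:
        a = rng.uniform(0.20 * side, 0.26 * side)
        b = rng.uniform(0.13 * side, 0.18 * side)
    else:
        a, b = spec.axes
    theta = rng.uniform(0, np.pi) if spec.angle is None else spec.angle

    ys, xs = np.indices((side, side), dtype=np.float64)
    dy, dx = ys - cy, xs - cx
    u = dx * np.cos(theta) + dy * np.sin(theta)
    v = -dx * np.sin(theta) + dy * np.cos(theta)
    rho = np.sqrt((u / a) ** 2 + (v / b) ** 2)  # 1 on the ellipse boundary
    if wobble > 0:
        phi = np.arctan2(v, u)
        k1, k2 = rng.integers(3, 7, size=2)
        p1, p2 = rng.uniform(0, 2 * np.pi, size=2)
        limit = 1.0 + wobble * (np.sin(k1 * phi + p1) + 0.5 * np.sin(k2 * phi + p2))
    else:
        limit = 1.0
    mask = rho <= limit

    max_reach = max(a, b) * (1.0 + 1.5 * wobble)
    if (
        cy - max_reach < 0
        or cx - max_reach < 0
        or cy + max_reach > side
        or cx + max_reach > side
    ):
        raise ValueError("ellipse (with wobble) does not fit inside the frame")

    img = np.full((side, side), spec.background_level, dtype=np.float64)
    if spec.background_amplitude > 0:
        img += spec.background_amplitude * _smooth_noise(
            rng, side, spec.background_scale
        )
    lesion = np.full((side, side), spec.lesion_level, dtype=np.float64)
    if amp > 0:
        lesion += amp * _smooth_noise(rng, side, scale)
    img[mask] = lesion[mask]

    if spec.gaussian_sigma > 0:
        img += rng.normal(0.0, spec.gaussian_sigma, size=img.shape)
    if spec.impulse_fraction > 0:
        hits = rng.random(img.shape) < spec.impulse_fraction
        img[hits] = np.where(rng.random(img.shape)[hits] < 0.5, 0.0, 255.0)

    return np.clip(np.rint(img), 0, 255).astype(np.uint8), mask, spec.label


def generate_image_set(
    n_per_class: int,
    side: int = 256,
    seed: int = 0,
    **overrides,
) -> tuple[list[np.ndarray], list[np.ndarray], np.ndarray]:
    """A balanced two-class image set with per-image derived seeds."""
    images, masks, labels = [], [], []
    for i in range(n_per_class):
        for kind in ("cancer", "benign"):
            spec = SyntheticImageSpec(
                kind=kind,
                side=side,
                seed=(seed * 7919 + i * 2 + (kind == "benign")) % (2**31),
                **overrides,
            )
            img, m, lab = generate_image(spec)
            images.append(img)
            masks.append(m)
            labels.append(lab)
    return images, masks, np.array(labels)


@dataclass(frozen=True)
class SyntheticTableSpec:
    """Recipe for a two-class Gaussian feature table.

    Informative columns are class-conditional normals whose means differ by
    ``separation`` (in units of the common noise sigma); the remaining
    columns are a single normal shared by both classes.  Columns are
    shuffled; the informative index set (post-shuffle) is returned.
    """

    n_per_class: int = 40
    n_features: int = 10
    n_informative: int = 3
    separation: float = 2.0
    noise_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 2:
            raise ValueError("need at least 2 samples per class")
        if not (0 <= self.n_informative <= self.n_features):
            raise ValueError("informative count must not exceed total features")
        if self.separation < 0:
            raise ValueError("separation must be non-negative")


def generate_table(
    spec: SyntheticTableSpec,
) -> tuple[LabeledFeatureTable, np.ndarray]:
    """Sample a labeled feature table; returns (table, informative indices)."""
    rng = np.random.default_rng(spec.seed)
    n = 2 * spec.n_per_class
    labels = np.array([1] * spec.n_per_class + [-1] * spec.n_per_class)
    values = rng.normal(0.0, spec.noise_sigma, size=(n, spec.n_features))
    shift = spec.separation * spec.noise_sigma / 2.0
    values[: spec.n_per_class, : spec.n_informative] += shift
    values[spec.n_per_class :, : spec.n_informative] -= shift

    perm = rng.permutation(spec.n_features)
    values = values[:, perm]
    informative = np.flatnonzero(np.isin(perm, np.arange(spec.n_informative)))
    names = tuple(f"f{j}" for j in range(spec.n_features))
    return LabeledFeatureTable(values, labels, names), informative
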