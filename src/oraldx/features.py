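"""Texture, statistical, geometric, and moment features of a segmented lesion.

The feature vector mirrors the classic lesion-description set: five
co-occurrence (GLCM/Haralick) texture statistics, three region intensity
statistics, the first three Hu invariant moments, and ten geometric shape
descriptors.  All features are deterministic functions of the preprocessed
image and its binary segmentation mask.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure, morphology

#: Stable output order of the full feature vector.
FEATURE_ORDER = (
    "correlation",
    "contrast",
    "energy",
    "entropy",
    "homogeneity",
    "mean",
    "variance",
    "std",
    "phi1",
    "phi2",
    "phi3",
    "area",
    "perimeter",
    "solidity",
    "elongation",
    "rectangularity",
    "form_factor",
    "irregularity_index",
    "eccentricity",
    "equivalent_diameter",
    "convex_area",
)


class EmptyRegionError(ValueError):
    """The mask selects no pixels."""


@dataclass(frozen=True)
class GLCMatrix:
    """Normalized gray-level co-occurrence matrix restricted to a region."""

    p: np.ndarray  # (levels, levels), sums to 1
    offset: tuple[int, int]
    levels: int


def glcm(
    image: np.ndarray,
    mask: np.ndarray,
    offset: tuple[int, int] = (0, 1),
    levels: int = 16,
    symmetric: bool = True,
    n_gray: int = 256,
) -> GLCMatrix:
    """Co-occurrence matrix of quantized intensities inside a mask.

    Only pixel pairs with *both* ends inside the mask are counted; the
    matrix is symmetrized (a pair counts in both directions) and normalized
    to sum 1.
    """
    img = np.asarray(image)
    m = np.asarray(mask).astype(bool)
    if img.shape != m.shape:
        raise ValueError("image and mask shapes differ")
    if not m.any():
        raise EmptyRegionError("mask selects no pixels")
    q = (img.astype(np.int64) * levels) // n_gray
    q = np.clip(q, 0, levels - 1)

    dy, dx = offset
    h, w = img.shape
    ys = slice(max(0, -dy), min(h, h - dy))
    xs = slice(max(0, -dx), min(w, w - dx))
    a = q[ys, xs]
    b = q[ys.start + dy : ys.stop + dy, xs.start + dx : xs.stop + dx]
    valid = m[ys, xs] & m[ys.start + dy : ys.stop + dy, xs.start + dx : xs.stop + dx]
    counts = np.bincount(
        (a[valid] * levels + b[valid]).ravel(), minlength=levels * levels
    ).reshape(levels, levels).astype(np.float64)
    if symmetric:
        counts = counts + counts.T
    total = counts.sum()
    if total == 0:
        raise EmptyRegionError("mask admits no co-occurring pixel pairs")
    return GLCMatrix(p=counts / total, offset=offset, levels=levels)


def texture_features(g: GLCMatrix) -> dict[str, float]:
    """Haralick statistics of a co-occurrence matrix.

    contrast = sum (i-j)^2 p, energy = sum p^2, entropy = -sum p ln p
    (0 ln 0 := 0), homogeneity = sum p / (1 + |i-j|), correlation =
    sum (i-mu_r)(j-mu_c) p / (sigma_r sigma_c), defined as 0 for a
    degenerate (constant) region.
    """
    p = g.p
    i = np.arange(g.levels, dtype=np.float64)[:, None]
    j = np.arange(g.levels, dtype=np.float64)[None, :]
    contrast = float(((i - j) ** 2 * p).sum())
    energy = float((p**2).sum())
    nz = p[p > 0]
    entropy = float(-(nz * np.log(nz)).sum())
    homogeneity = float((p / (1.0 + np.abs(i - j))).sum())

    mu_r = float((i * p).sum())
    mu_c = float((j * p).sum())
    var_r = float(((i - mu_r) ** 2 * p).sum())
    var_c = float(((j - mu_c) ** 2 * p).sum())
    if var_r > 0 and var_c > 0:
        correlation = float(
            (((i - mu_r) * (j - mu_c) * p).sum()) / math.sqrt(var_r * var_c)
        )
    else:
        correlation = 0.0
    return {
        "correlation": correlation,
        "contrast": contrast,
        "energy": energy,
        "entropy": entropy,
        "homogeneity": homogeneity,
    }


def region_statistics(image: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    """Mean, variance and standard deviation of the masked pixels."""
    m = np.asarray(mask).astype(bool)
    if not m.any():
        raise EmptyRegionError("mask selects no pixels")
    vals = np.asarray(image, dtype=np.float64)[m]
    var = float(vals.var())
    return {"mean": float(vals.mean()), "variance": var, "std": math.sqrt(var)}


def _largest_component(mask: np.ndarray) -> np.ndarray:
    m = np.asarray(mask).astype(bool)
    if not m.any():
        raise EmptyRegionError("mask selects no pixels")
    labels, n = ndimage.label(m, structure=np.ones((3, 3), dtype=int))
    if n <= 1:
        return m
    sizes = ndimage.sum_labels(m, labels, index=np.arange(1, n + 1))
    return labels == (1 + int(np.argmax(sizes)))


def _axis_lengths(mask: np.ndarray) -> tuple[float, float]:
    """Equivalent-rectangle axis lengths from second-order central moments.

    Eigenvalues of the pixel-coordinate covariance (with the +1/12
    continuous-pixel correction) scaled by sqrt(12), so that a solid
    w x h rectangle yields exactly (max(w,h), min(w,h)).
    """
    ys, xs = np.nonzero(mask)
    y = ys - ys.mean()
    x = xs - xs.mean()
    n = len(xs)
    c20 = (x @ x) / n + 1.0 / 12.0
    c02 = (y @ y) / n + 1.0 / 12.0
    c11 = (x @ y) / n
    common = math.sqrt(max(((c20 - c02) / 2) ** 2 + c11**2, 0.0))
    lam1 = (c20 + c02) / 2 + common
    lam2 = (c20 + c02) / 2 - common
    a = math.sqrt(12.0 * max(lam1, 0.0))
    b = math.sqrt(12.0 * max(lam2, 0.0))
    return a, b


def geometric_features(mask: np.ndarray) -> dict[str, float]:
    """Shape descriptors of the largest foreground region of a mask.

    area is the pixel count; perimeter uses the Crofton estimator (4
    directions), which is close to unbiased for smooth contours, so a
    digital disk scores an irregularity index near 1; a, b are the
    equivalent-rectangle
    axis lengths from the second-order central moments.  The composite
    indices follow the conventions documented in docs/methods.md:
    irregularity = 4*pi*area/perimeter^2, form factor = area/a^2,
    rectangularity = area/(a*b), elongation = 2*sqrt(area/(a*pi)),
    eccentricity = 2*sqrt(a^2-b^2)/a (0 for a=b).
    """
    region = _largest_component(mask)
    area = float(region.sum())
    perimeter = float(measure.perimeter_crofton(region, directions=4))
    convex_area = float(morphology.convex_hull_image(region).sum())
    a, b = _axis_lengths(region)
    ecc_sq = max(a * a - b * b, 0.0)
    return {
        "area": area,
        "perimeter": perimeter,
        "solidity": area / convex_area,
        "elongation": 2.0 * math.sqrt(area / (a * math.pi)),
        "rectangularity": area / (a * b),
        "form_factor": area / a**2,
        "irregularity_index": 4.0 * math.pi * area / perimeter**2,
        "eccentricity": 2.0 * math.sqrt(ecc_sq) / a,
        "equivalent_diameter": math.sqrt(4.0 * area / math.pi),
        "convex_area": convex_area,
    }


def hu_moments(region: np.ndarray) -> tuple[float, float, float]:
    """First three Hu invariant moments of a mask or weighted region.

    Normalized central moments eta_pq = mu_pq / mu_00^(1+(p+q)/2) feed

    * phi1 = eta20 + eta02
    * phi2 = (eta20 - eta02)^2 + 4 eta11^2
    * phi3 = (eta30 - 3 eta12)^2 + (3 eta21 - eta03)^2
    """
    w = np.asarray(region, dtype=np.float64)
    m00 = w.sum()
    if m00 <= 0:
        raise EmptyRegionError("region has zero total mass")
    ys, xs = np.indices(w.shape)
    cy = (ys * w).sum() / m00
    cx = (xs * w).sum() / m00
    y = ys - cy
    x = xs - cx

    def mu(p: int, q: int) -> float:
        return float((x**p * y**q * w).sum())

    def eta(p: int, q: int) -> float:
        return mu(p, q) / m00 ** (1 + (p + q) / 2)

    e20, e02, e11 = eta(2, 0), eta(0, 2), eta(1, 1)
    e30, e12, e21, e03 = eta(3, 0), eta(1, 2), eta(2, 1), eta(0, 3)
    phi1 = e20 + e02
    phi2 = (e20 - e02) ** 2 + 4 * e11**2
    phi3 = (e30 - 3 * e12) ** 2 + (3 * e21 - e03) ** 2
    return phi1, phi2, phi3


def extract_all(image: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    """Full named feature vector of (image, mask), in FEATURE_ORDER."""
    g = glcm(image, mask)
    tex = texture_features(g)
    stats = region_statistics(image, mask)
    phi1, phi2, phi3 = hu_moments(_largest_component(mask))
    geo = geometric_features(mask)
    vec = {**tex, **stats, "phi1": phi1, "phi2": phi2, "phi3": phi3, **geo}
    return {name: vec[name] for name in FEATURE_ORDER}
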