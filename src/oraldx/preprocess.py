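"""Image preprocessing: median-filter noise cancellation and CLAHE.

The preprocessing stage of the diagnosis pipeline takes an 8-bit lesion
photograph, converts it to a single grayscale channel, removes impulse
("salt-and-pepper") noise with a 7x7 median filter, and enhances local
contrast with contrast-limited adaptive histogram equalization (CLAHE):
per-tile histogram equalization with a clip limit and bilinear blending of
the neighbouring tile mappings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from PIL import Image
from scipy import ndimage


class FormatError(ValueError):
    """Unsupported image format (channel count or dtype)."""


@dataclass(frozen=True)
class CLAHEConfig:
    """Parameters of contrast-limited adaptive histogram equalization.

    Attributes
    ----------
    tile_side : int
        Side length ``m`` (pixels) of the square tiles; must divide
        ``resize_side``.
    clip_limit : float
        Normalized contrast limit ``Ncl`` in (0, 1].  The per-tile count
        threshold is ``CL = Ncl * Navg`` with ``Navg = m*m / n_gray``.
    resize_side : int
        The image is resized to ``resize_side x resize_side`` before tiling
        so the tile grid is exact.
    n_gray : int
        Number of gray levels (256 for 8-bit input).
    """

    tile_side: int = 32
    clip_limit: float = 0.002
    resize_side: int = 256
    n_gray: int = 256

    def __post_init__(self) -> None:
        if not (0.0 < self.clip_limit <= 1.0):
            raise ValueError(f"clip_limit must be in (0, 1], got {self.clip_limit}")
        if self.tile_side > self.resize_side:
            raise ValueError("tile_side may not exceed resize_side")
        if self.resize_side % self.tile_side:
            raise ValueError(
                f"tile_side {self.tile_side} must divide resize_side {self.resize_side}"
            )

    @property
    def count_limit(self) -> float:
        """Per-tile clip threshold CL = Ncl * Navg (counts)."""
        navg = self.tile_side * self.tile_side / self.n_gray
        return self.clip_limit * navg


# BT.601 luma weights for RGB -> gray conversion.
_LUMA = np.array([0.299, 0.587, 0.114])


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Convert an 8-bit image to a single gray channel.

    Three-channel inputs are reduced with the ITU-R BT.601 luma weighting
    ``0.299 R + 0.587 G + 0.114 B`` (rounded); single-channel inputs pass
    through unchanged.
    """
    arr = np.asarray(image)
    if arr.dtype != np.uint8:
        raise FormatError(f"expected 8-bit image, got dtype {arr.dtype}")
    if arr.ndim == 2:
        return arr.copy()
    if arr.ndim == 3 and arr.shape[2] == 3:
        gray = np.rint(arr.astype(np.float64) @ _LUMA)
        return np.clip(gray, 0, 255).astype(np.uint8)
    raise FormatError(f"unsupported image shape {arr.shape}")


def median_filter(image: np.ndarray, window: int = 7) -> np.ndarray:
    """Median-filter an image with a square sliding window.

    Each output pixel is the median of its ``window x window``
    neighbourhood; the border is handled by replicate-edge padding of
    radius ``(window - 1) // 2``, which avoids the darkening that
    zero-padding causes at the edges of bright lesions.
    """
    if window % 2 == 0 or window < 3:
        raise ValueError(f"window must be odd and >= 3, got {window}")
    arr = np.asarray(image)
    if arr.ndim != 2:
        raise FormatError("median_filter expects a 2-D grayscale image")
    return ndimage.median_filter(arr, size=window, mode="nearest")


def clip_histogram(hist: np.ndarray, count_limit: float) -> np.ndarray:
    """Clip a histogram at a count threshold and redistribute the excess.

    Bins above the limit are truncated; the clipped total is spread
    uniformly over all bins, with any integer remainder handed out
    one-per-bin from bin 0 upward.  The total count is conserved exactly.
    """
    if count_limit <= 0:
        raise ValueError(f"count_limit must be positive, got {count_limit}")
    h = np.asarray(hist, dtype=np.int64)
    if np.any(h < 0):
        raise ValueError("histogram counts must be non-negative")
    cap = int(math.floor(count_limit))
    clipped = np.minimum(h, cap)
    excess = int((h - clipped).sum())
    n_bins = h.size
    per_bin, remainder = divmod(excess, n_bins)
    out = clipped + per_bin
    out[:remainder] += 1
    return out


def _tile_mapping(tile: np.ndarray, cfg: CLAHEConfig) -> np.ndarray:
    """Equalization lookup table for one tile (clipped-histogram CDF)."""
    hist = np.bincount(tile.ravel(), minlength=cfg.n_gray)
    hist = clip_histogram(hist, cfg.count_limit)
    cdf = np.cumsum(hist)
    total = cdf[-1]
    return np.rint(cdf / total * (cfg.n_gray - 1)).astype(np.float64)


def _resize(image: np.ndarray, side: int) -> np.ndarray:
    if image.shape == (side, side):
        return image
    pil = Image.fromarray(image)
    return np.asarray(pil.resize((side, side), Image.BILINEAR))


def clahe(image: np.ndarray, cfg: CLAHEConfig | None = None) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization.

    The image is resized to ``resize_side`` square, decomposed into
    ``m x m`` tiles, each tile's histogram is clipped at
    ``CL = Ncl * Navg`` and equalized by its cumulative distribution, and
    every pixel is remapped by bilinear interpolation of the four
    surrounding tile mappings (edge and corner pixels use the two / one
    available mappings, implemented by replicating the mapping grid).
    """
    cfg = cfg or CLAHEConfig()
    arr = to_grayscale(np.asarray(image))
    arr = _resize(arr, cfg.resize_side)

    m = cfg.tile_side
    n_tiles = cfg.resize_side // m
    # Lookup tables, one per tile.
    maps = np.empty((n_tiles, n_tiles, cfg.n_gray), dtype=np.float64)
    for ty in range(n_tiles):
        for tx in range(n_tiles):
            tile = arr[ty * m : (ty + 1) * m, tx * m : (tx + 1) * m]
            maps[ty, tx] = _tile_mapping(tile, cfg)

    # Bilinear blend between tile-centre mappings; outside the outermost
    # centres the nearest mapping is replicated (classic CLAHE borders).
    coords = np.arange(cfg.resize_side, dtype=np.float64)
    t = (coords - (m - 1) / 2.0) / m  # tile-centre coordinate
    t0 = np.clip(np.floor(t).astype(int), 0, n_tiles - 1)
    t1 = np.clip(t0 + 1, 0, n_tiles - 1)
    w = np.clip(t - np.floor(t), 0.0, 1.0)
    w[t < 0] = 0.0
    w[t > n_tiles - 1] = 0.0

    y0, y1, wy = t0[:, None], t1[:, None], w[:, None]
    x0, x1, wx = t0[None, :], t1[None, :], w[None, :]
    g = arr.astype(int)
    out = (
        (1 - wy) * (1 - wx) * maps[y0, x0, g]
        + (1 - wy) * wx * maps[y0, x1, g]
        + wy * (1 - wx) * maps[y1, x0, g]
        + wy * wx * maps[y1, x1, g]
    )
    return np.clip(np.rint(out), 0, cfg.n_gray - 1).astype(np.uint8)


def preprocess_image(
    image: np.ndarray,
    median_window: int = 7,
    clahe_cfg: CLAHEConfig | None = None,
) -> np.ndarray:
    """Full preprocessing chain: grayscale -> median filter -> CLAHE."""
    gray = to_grayscale(np.asarray(image))
    filtered = median_filter(gray, window=median_window)
    return clahe(filtered, clahe_cfg)


def load_image(path) -> np.ndarray:
    """Read a PNG/JPEG image as an 8-bit array (gray or RGB)."""
    with Image.open(path) as im:
        if im.mode not in ("L", "RGB"):
            im = im.convert("RGB")
        return np.asarray(im)


def save_image(path, image: np.ndarray) -> None:
    Image.fromarray(np.asarray(image, dtype=np.uint8)).save(path)
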