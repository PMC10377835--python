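"""Rough-set K-means segmentation over windowed run-length texture features.

Lesion/background separation works on texture rather than raw intensity:
the image is divided into non-overlapping 4x4 windows, each window is
described by five classic gray-level run-length (GLRLM) statistics, and the
window vectors are clustered with a rough K-means.  Rough K-means follows
Pawlak's rough-set idea: every cluster carries a *lower* approximation
(windows certainly in the cluster) and an *upper* approximation (windows
possibly in it); windows whose two nearest centers are closer than a
distance margin fall only into upper approximations, and cluster centers
are weighted combinations of lower-member and boundary-member means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Names of the per-window run-length statistics, in feature order.
GLRLM_FEATURES = (
    "short_run_emphasis",
    "long_run_emphasis",
    "gray_level_nonuniformity",
    "run_length_nonuniformity",
    "run_percentage",
)


class EmptyCentersError(RuntimeError):
    """Raised when an assignment is requested with no cluster centers."""


# ---------------------------------------------------------------------------
# Rough approximations
# ---------------------------------------------------------------------------


@dataclass
class RoughApproximation:
    """Lower/upper approximation pair of a rough set.

    ``lower`` holds items certainly in the set, ``upper`` items possibly in
    it; their difference is the boundary region, whose size measures the
    uncertainty of the set.
    """

    lower: set = field(default_factory=set)
    upper: set = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.lower <= self.upper:
            raise ValueError("lower approximation must be a subset of the upper")

    @property
    def boundary(self) -> set:
        return self.upper - self.lower


def rough_limits(approx: RoughApproximation, values: dict) -> tuple[float, float]:
    """Mean of the item values over the lower and upper approximations.

    These are the lower/upper limits of the rough number of the set; their
    difference (the rough boundary distance) quantifies its uncertainty.
    Empty approximations yield ``nan`` limits.
    """
    lo = [values[i] for i in approx.lower]
    up = [values[i] for i in approx.upper]
    lim_lower = float(np.mean(lo)) if lo else float("nan")
    lim_upper = float(np.mean(up)) if up else float("nan")
    return lim_lower, lim_upper


def rough_boundary_distance(approx: RoughApproximation, values: dict) -> float:
    """Difference of the upper and lower rough limits."""
    lim_lower, lim_upper = rough_limits(approx, values)
    return lim_upper - lim_lower


@dataclass
class RoughCluster:
    """A rough K-means cluster: center plus its approximation sets."""

    center: np.ndarray
    approx: RoughApproximation
    w_lower: float = 0.7
    threshold: float = 0.0

    @property
    def w_upper(self) -> float:
        return 1.0 - self.w_lower


# ---------------------------------------------------------------------------
# Windowed GLRLM features
# ---------------------------------------------------------------------------


@dataclass
class WindowFeatureMap:
    """Per-window texture feature vectors over a regular window grid."""

    features: np.ndarray  # (grid_h, grid_w, 5)
    variance: np.ndarray  # (grid_h, grid_w) quantized-intensity variance
    window: int
    levels: int

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.features.shape[:2]

    @property
    def flat(self) -> np.ndarray:
        return self.features.reshape(-1, self.features.shape[-1])


def quantize(image: np.ndarray, levels: int, n_gray: int = 256) -> np.ndarray:
    """Uniformly quantize 8-bit intensities to ``levels`` bins."""
    q = (np.asarray(image, dtype=np.int64) * levels) // n_gray
    return np.clip(q, 0, levels - 1)


def glrlm_matrix(quantized: np.ndarray, levels: int) -> np.ndarray:
    """Gray-level run-length matrix of one window, runs along rows (0 deg).

    Entry ``(g, l-1)`` counts maximal horizontal runs of level ``g`` with
    length ``l``.
    """
    q = np.asarray(quantized)
    max_len = q.shape[1]
    out = np.zeros((levels, max_len), dtype=np.int64)
    for row in q:
        start = 0
        for j in range(1, len(row) + 1):
            if j == len(row) or row[j] != row[start]:
                out[row[start], j - start - 1] += 1
                start = j
    return out


def glrlm_window_features(
    image: np.ndarray, window: int = 4, levels: int = 8
) -> WindowFeatureMap:
    """Five GLRLM statistics for every non-overlapping square window.

    Per window (runs taken along the horizontal direction):

    * short-run emphasis      SRE = (1/Nr) sum R(g,l) / l^2
    * long-run emphasis       LRE = (1/Nr) sum R(g,l) * l^2
    * gray-level non-uniformity  GLN = (1/Nr) sum_g (sum_l R)^2
    * run-length non-uniformity  RLN = (1/Nr) sum_l (sum_g R)^2
    * run percentage          RP  = Nr / (pixels per window)

    where Nr is the number of runs in the window.
    """
    img = np.asarray(image)
    if img.ndim != 2 or img.shape[0] < window or img.shape[1] < window:
        raise ValueError(f"image must be 2-D and at least {window}x{window}")
    q = quantize(img, levels)
    gh, gw = img.shape[0] // window, img.shape[1] // window
    # (n_windows, window, window) view in window-major order
    wins = (
        q[: gh * window, : gw * window]
        .reshape(gh, window, gw, window)
        .transpose(0, 2, 1, 3)
        .reshape(-1, window, window)
    )
    n_win = wins.shape[0]
    rows = wins.reshape(-1, window)  # all window-rows, runs never span rows

    starts = np.ones_like(rows, dtype=bool)
    starts[:, 1:] = rows[:, 1:] != rows[:, :-1]
    flat = starts.ravel()
    pos = np.flatnonzero(flat)
    lengths = np.diff(np.append(pos, flat.size))
    run_levels = rows.ravel()[pos]
    win_id = pos // (window * window)

    n_runs = np.bincount(win_id, minlength=n_win).astype(np.float64)
    sre = np.bincount(win_id, weights=1.0 / lengths**2, minlength=n_win)
    lre = np.bincount(win_id, weights=lengths.astype(np.float64) ** 2, minlength=n_win)

    level_key = win_id * levels + run_levels
    c_level = np.bincount(level_key, minlength=n_win * levels).astype(np.float64)
    gln = np.bincount(
        np.arange(n_win * levels) // levels, weights=c_level**2, minlength=n_win
    )
    length_key = win_id * window + (lengths - 1)
    c_len = np.bincount(length_key, minlength=n_win * window).astype(np.float64)
    rln = np.bincount(
        np.arange(n_win * window) // window, weights=c_len**2, minlength=n_win
    )

    feats = np.stack(
        [
            sre / n_runs,
            lre / n_runs,
            gln / n_runs,
            rln / n_runs,
            n_runs / (window * window),
        ],
        axis=1,
    ).reshape(gh, gw, 5)
    var = wins.reshape(n_win, -1).var(axis=1).reshape(gh, gw)
    return WindowFeatureMap(features=feats, variance=var, window=window, levels=levels)


# ---------------------------------------------------------------------------
# Rough K-means
# ---------------------------------------------------------------------------


@dataclass
class MembershipRecord:
    """Rough assignment of one feature vector against the current centers."""

    nearest: int
    candidates: tuple  # clusters within the distance margin of the nearest
    in_lower: bool

    @property
    def upper_of(self) -> tuple:
        return (self.nearest, *self.candidates)


def assign_rough_memberships(
    v: np.ndarray, centers: np.ndarray, threshold: float
) -> MembershipRecord:
    """Assign one vector to lower/upper approximations.

    The nearest center ``i`` is found by Euclidean distance (ties broken by
    lowest index); every other center within ``threshold`` of the nearest
    distance is a candidate.  With no candidates the vector enters both the
    lower and upper approximation of cluster ``i``; otherwise it enters only
    the upper approximations of ``i`` and all candidates.
    """
    centers = np.atleast_2d(np.asarray(centers, dtype=np.float64))
    if centers.shape[0] == 0:
        raise EmptyCentersError("no cluster centers")
    d = np.linalg.norm(centers - np.asarray(v, dtype=np.float64), axis=1)
    i = int(np.argmin(d))
    cand = tuple(
        j for j in range(len(d)) if j != i and d[j] - d[i] <= threshold
    )
    return MembershipRecord(nearest=i, candidates=cand, in_lower=not cand)


def _assign_all(
    features: np.ndarray, centers: np.ndarray, threshold: float
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized rough assignment of every row of ``features``.

    Returns ``nearest`` (N,) and a boolean ``upper`` matrix (N, k) marking
    upper-approximation membership.  A row is a lower member of its nearest
    cluster iff its upper row has a single True.
    """
    d = np.linalg.norm(features[:, None, :] - centers[None, :, :], axis=2)
    nearest = np.argmin(d, axis=1)
    d_min = d[np.arange(len(d)), nearest]
    upper = d - d_min[:, None] <= threshold
    upper[np.arange(len(d)), nearest] = True
    return nearest, upper


def update_rough_centers(
    clusters: list[RoughCluster],
    features: np.ndarray,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Recompute centers as weighted lower/boundary means.

    With both member sets populated the center is
    ``w_lower * mean(lower) + w_upper * mean(boundary)``; with an empty
    boundary it is the plain lower mean, with an empty lower set the plain
    boundary mean.  A cluster with no members at all is re-seeded from a
    random feature vector (``rng`` required in that case).
    """
    features = np.asarray(features, dtype=np.float64)
    out = np.empty((len(clusters), features.shape[1]))
    for j, cl in enumerate(clusters):
        lower = sorted(cl.approx.lower)
        bound = sorted(cl.approx.boundary)
        if lower and bound:
            out[j] = cl.w_lower * features[lower].mean(axis=0) + cl.w_upper * features[
                bound
            ].mean(axis=0)
        elif lower:
            out[j] = features[lower].mean(axis=0)
        elif bound:
            out[j] = features[bound].mean(axis=0)
        else:
            if rng is None:
                raise ValueError("empty cluster needs an rng to re-seed")
            out[j] = features[rng.integers(len(features))]
    return out


def rough_kmeans(
    features: np.ndarray,
    k: int = 2,
    w_lower: float = 0.7,
    threshold: float | None = None,
    max_iter: int = 100,
    tol: float = 1e-6,
    seed: int | None = None,
) -> list[RoughCluster]:
    """Cluster feature vectors with the rough K-means.

    Centers are initialized from ``k`` distinct random feature vectors.
    When ``threshold`` is None a scale-free margin is used: 0.1 times the
    mean nearest-center distance of the first assignment pass.  Iteration
    stops when the largest center displacement falls below ``tol`` or after
    ``max_iter`` rounds.
    """
    features = np.asarray(features, dtype=np.float64)
    n = features.shape[0]
    if k < 1 or k > n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    if not (0.0 < w_lower <= 1.0):
        raise ValueError(f"w_lower must be in (0, 1], got {w_lower}")
    rng = np.random.default_rng(seed)
    # distinct starting points: sample row indices without replacement
    centers = features[rng.choice(n, size=k, replace=False)].copy()

    if threshold is None:
        d = np.linalg.norm(features[:, None, :] - centers[None, :, :], axis=2)
        threshold = 0.1 * float(d.min(axis=1).mean())

    nearest, upper = _assign_all(features, centers, threshold)
    for _ in range(max_iter):
        clusters = _build_clusters(centers, nearest, upper, w_lower, threshold)
        new_centers = update_rough_centers(clusters, features, rng)
        # Degenerate fixed point: when centers coincide, every item is a
        # boundary member of all of them and the weighted means stay merged
        # forever.  Re-seed duplicates from random feature vectors, the same
        # remedy used for empty clusters.
        reseeded = False
        for j in range(1, k):
            if np.any(
                np.linalg.norm(new_centers[:j] - new_centers[j], axis=1) <= tol
            ):
                new_centers[j] = features[rng.integers(n)]
                reseeded = True
        shift = np.linalg.norm(new_centers - centers, axis=1).max()
        centers = new_centers
        nearest, upper = _assign_all(features, centers, threshold)
        if shift < tol and not reseeded:
            break
    return _build_clusters(centers, nearest, upper, w_lower, threshold)


def _build_clusters(
    centers: np.ndarray,
    nearest: np.ndarray,
    upper: np.ndarray,
    w_lower: float,
    threshold: float,
) -> list[RoughCluster]:
    sole = upper.sum(axis=1) == 1  # lower members have exactly one upper set
    clusters = []
    for j in range(len(centers)):
        up = set(np.flatnonzero(upper[:, j]).tolist())
        lo = set(np.flatnonzero(sole & (nearest == j)).tolist())
        clusters.append(
            RoughCluster(
                center=centers[j].copy(),
                approx=RoughApproximation(lower=lo, upper=up),
                w_lower=w_lower,
                threshold=threshold,
            )
        )
    return clusters


def mask_from_clusters(
    clusters: list[RoughCluster],
    feature_map: WindowFeatureMap,
    image_shape: tuple[int, int],
) -> np.ndarray:
    """Paint a binary lesion mask from a 2-cluster rough K-means result.

    Every window takes the label of the cluster whose lower approximation
    holds it; boundary-only windows take their nearest-center label.  The
    lesion cluster is the one whose member windows have the higher mean
    quantized-intensity variance (lesions are the textured regions), and
    the window-grid labels are upsampled to the full image size.
    """
    if len(clusters) != 2:
        raise ValueError("mask export supports exactly k=2 clusters")
    gh, gw = feature_map.grid_shape
    flat = feature_map.flat
    centers = np.stack([c.center for c in clusters])
    labels = np.full(flat.shape[0], -1, dtype=int)
    for j, cl in enumerate(clusters):
        labels[sorted(cl.approx.lower)] = j
    undecided = labels < 0
    if undecided.any():
        d = np.linalg.norm(flat[undecided, None, :] - centers[None, :, :], axis=2)
        labels[undecided] = np.argmin(d, axis=1)

    var = feature_map.variance.ravel()
    mean_var = [
        var[labels == j].mean() if np.any(labels == j) else -np.inf for j in (0, 1)
    ]
    lesion = int(np.argmax(mean_var))
    grid = (labels == lesion).reshape(gh, gw)

    h, w = image_shape
    wy = np.clip(np.arange(h) // feature_map.window, 0, gh - 1)
    wx = np.clip(np.arange(w) // feature_map.window, 0, gw - 1)
    return grid[np.ix_(wy, wx)].astype(np.uint8)


def segment_image(
    image: np.ndarray,
    k: int = 2,
    w_lower: float = 0.7,
    threshold: float | None = None,
    seed: int | None = None,
    window: int = 4,
    levels: int = 8,
) -> np.ndarray:
    """Segment a preprocessed grayscale image into a binary lesion mask.

    Window features are z-scored before clustering so that no single
    run-length statistic dominates the Euclidean metric.
    """
    fmap = glrlm_window_features(image, window=window, levels=levels)
    flat = fmap.flat
    mu, sd = flat.mean(axis=0), flat.std(axis=0)
    sd[sd == 0] = 1.0
    standardized = (flat - mu) / sd
    clusters = rough_kmeans(
        standardized, k=k, w_lower=w_lower, threshold=threshold, seed=seed
    )
    # mask_from_clusters works in the standardized space too: labels depend
    # only on memberships and centers, which were fit in that space.
    fmap_std = WindowFeatureMap(
        features=standardized.reshape(fmap.features.shape),
        variance=fmap.variance,
        window=fmap.window,
        levels=fmap.levels,
    )
    return mask_from_clusters(clusters, fmap_std, image.shape)
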