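"""Marker tracks to multiaxial strain maps and scalar sensor metrics.

Given marker detections in an initial (no-strain) frame and a current frame,
this module selects the markers of interest (MOIs) nearest the image center,
matches markers across frames by position, robustly fits a homography with
RANSAC, and evaluates paired strain amplitude (px) and direction (rad) maps
over a sampling lattice.  It also computes the residual-deviation map that
encodes the attachment state of the worn sensor, plus the scalar metrics used
to characterize the device (relative pixel change, MAPE).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from skimage.measure import ransac as _sk_ransac
from skimage.transform import ProjectiveTransform

from .imaging import MarkerSet

__all__ = [
    "MOISet",
    "Correspondences",
    "StrainMap",
    "ResidualStressMap",
    "select_mois",
    "match_markers",
    "estimate_homography",
    "compute_strain_map",
    "compute_residual_stress_map",
    "relative_pixel_change",
    "mape",
]


def _centroids(markers) -> np.ndarray:
    if isinstance(markers, MarkerSet):
        return markers.centroids
    arr = np.asarray(markers, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("expected (N, 2) centroid array or MarkerSet")
    return arr


@dataclass
class MOISet:
    """The k markers of interest: ids mapped to initial centroids.

    Ids are assigned in order of increasing distance to the image center
    (ties broken by x then y) and stay stable across frames.
    """

    positions: np.ndarray  # (k, 2) initial centroids, ordered by id
    center: tuple[float, float]

    @property
    def k(self) -> int:
        return len(self.positions)


def select_mois(markers, image_size: tuple[int, int], k: int = 16) -> MOISet:
    """Select the k markers with smallest Euclidean distance to image center.

    The image center is ((w-1)/2, (h-1)/2) in pixel-center coordinates.
    Deterministic ordering by (distance, x, y).

    Raises
    ------
    ValueError
        If fewer than ``k`` markers are available ("insufficient markers in
        FOV").
    """
    pts = _centroids(markers)
    if len(pts) < k:
        raise ValueError(f"insufficient markers in FOV: {len(pts)} < {k}")
    w, h = image_size
    center = ((w - 1) / 2.0, (h - 1) / 2.0)
    d = np.hypot(pts[:, 0] - center[0], pts[:, 1] - center[1])
    order = np.lexsort((pts[:, 1], pts[:, 0], d))
    return MOISet(positions=pts[order[:k]].copy(), center=center)


@dataclass
class Correspondences:
    """One-to-one positional matches between two marker sets."""

    initial_idx: np.ndarray
    current_idx: np.ndarray
    distances: np.ndarray
    unmatched_initial: np.ndarray
    unmatched_current: np.ndarray

    def __len__(self) -> int:
        return len(self.initial_idx)

    @property
    def src(self) -> np.ndarray:
        return self._src

    @property
    def dst(self) -> np.ndarray:
        return self._dst


def match_markers(initial, current, max_disp_px: float) -> Correspondences:
    """Greedy one-to-one nearest-neighbor matching within ``max_disp_px``.

    All markers are visually identical dots, so matching is purely
    positional: candidate pairs are taken in ascending distance order, each
    marker used at most once.  Unmatched markers on either side are reported.
    """
    a = _centroids(initial)
    b = _centroids(current)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both marker sets must be non-empty")
    diff = a[:, None, :] - b[None, :, :]
    dist = np.sqrt((diff**2).sum(-1))
    pairs = np.argwhere(dist <= max_disp_px)
    order = np.argsort(dist[pairs[:, 0], pairs[:, 1]], kind="stable")
    used_a = np.zeros(len(a), dtype=bool)
    used_b = np.zeros(len(b), dtype=bool)
    ia, ib, dd = [], [], []
    for i, j in pairs[order]:
        if used_a[i] or used_b[j]:
            continue
        used_a[i] = used_b[j] = True
        ia.append(i)
        ib.append(j)
        dd.append(dist[i, j])
    corr = Correspondences(
        initial_idx=np.array(ia, dtype=int),
        current_idx=np.array(ib, dtype=int),
        distances=np.array(dd),
        unmatched_initial=np.flatnonzero(~used_a),
        unmatched_current=np.flatnonzero(~used_b),
    )
    corr._src = a[corr.initial_idx]
    corr._dst = b[corr.current_idx]
    return corr


def _fit_homography_lsq(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    t = ProjectiveTransform.from_estimate(src, dst)
    if not t:
        raise ValueError("degenerate correspondences: homography estimation failed")
    H = t.params
    return H / H[2, 2]


def estimate_homography(
    correspondences: Correspondences | tuple[np.ndarray, np.ndarray],
    ransac_threshold_px: float = 1.0,
    seed: int = 0,
    max_trials: int = 1000,
) -> np.ndarray:
    """RANSAC homography from matched points, refit on inliers.

    Maximizes the inlier count at the reprojection threshold, then
    re-estimates by least squares on the inlier set.  Returned matrix is
    normalized to H[2, 2] = 1 and maps initial-frame to current-frame
    coordinates.
    """
    if isinstance(correspondences, Correspondences):
        src, dst = correspondences.src, correspondences.dst
    else:
        src, dst = (np.asarray(x, dtype=float) for x in correspondences)
    if len(src) < 4:
        raise ValueError("underdetermined homography: need >= 4 correspondences")
    if len(src) == 4:
        return _fit_homography_lsq(src, dst)
    model, inliers = _sk_ransac(
        (src, dst),
        ProjectiveTransform,
        min_samples=4,
        residual_threshold=ransac_threshold_px,
        max_trials=max_trials,
        rng=np.random.default_rng(seed),
    )
    if model is None or inliers is None or inliers.sum() < 4:
        raise ValueError("RANSAC failed to find a homography consensus")
    return _fit_homography_lsq(src[inliers], dst[inliers])


@dataclass
class StrainMap:
    """Paired amplitude (px) and direction (rad) grids over a lattice."""

    xs: np.ndarray  # (cols,) lattice x coordinates
    ys: np.ndarray  # (rows,) lattice y coordinates
    amplitude: np.ndarray  # (rows, cols), >= 0
    direction: np.ndarray  # (rows, cols), in (-pi, pi]


def compute_strain_map(
    H: np.ndarray,
    lattice: tuple[int, int] = (12, 16),
    image_size: tuple[int, int] = (320, 240),
) -> StrainMap:
    """Evaluate the multiaxial strain map of a homography on a lattice.

    Each lattice point p maps to p' = H.p (homogeneous, dehomogenized);
    amplitude(p) = ||p' - p||2 in pixels and direction(p) = atan2(dy, dx)
    with y increasing downward (image convention).

    ``lattice`` is (rows, cols) over the frame; default 12 x 16 over
    320 x 240.
    """
    H = np.asarray(H, dtype=float)
    rows, cols = lattice
    w, h = image_size
    xs = np.linspace(0.0, w - 1.0, cols)
    ys = np.linspace(0.0, h - 1.0, rows)
    gx, gy = np.meshgrid(xs, ys)
    pts = np.stack([gx.ravel(), gy.ravel(), np.ones(gx.size)], axis=1)
    mapped = pts @ H.T
    wcoord = mapped[:, 2]
    if np.any(np.abs(wcoord) < 1e-12):
        raise ValueError("lattice point mapped to infinity (vanishing homogeneous denominator)")
    p2 = mapped[:, :2] / wcoord[:, None]
    delta = p2 - pts[:, :2]
    amplitude = np.hypot(delta[:, 0], delta[:, 1]).reshape(rows, cols)
    direction = np.arctan2(delta[:, 1], delta[:, 0]).reshape(rows, cols)
    return StrainMap(xs=xs, ys=ys, amplitude=amplitude, direction=direction)


@dataclass
class ResidualStressMap:
    """Per-marker deviation between designed and captured layouts.

    Captured markers are paired to the designed layout after aligning the two
    centroids by translation, so the map is exactly invariant to any global
    translation of the captured set.
    """

    deviations: np.ndarray  # (N,) px, >= 0
    translation: np.ndarray  # (2,) applied to the designed layout
    pairs: np.ndarray  # (N,) index into designed layout for each captured marker

    def summary_features(self, length: int = 16) -> np.ndarray:
        """Deviation magnitudes resampled to a fixed-length feature vector."""
        d = np.sort(self.deviations)
        if len(d) == 0:
            return np.zeros(length)
        x_old = np.linspace(0.0, 1.0, len(d)) if len(d) > 1 else np.array([0.5])
        return np.interp(np.linspace(0.0, 1.0, length), x_old, d)


def compute_residual_stress_map(designed, captured) -> ResidualStressMap:
    """Positional-deviation field between designed and captured layouts.

    Steps: (1) centroid of the captured markers; (2) designed layout
    translated so the centroids coincide; (3) each captured marker paired
    with its nearest translated designed point; deviation = pair distance.
    """
    des = _centroids(designed)
    cap = _centroids(captured)
    if len(des) == 0 or len(cap) == 0:
        raise ValueError("designed and captured layouts must be non-empty")
    # centered formulation: numerically insensitive to large global offsets
    des_c = des - des.mean(axis=0)
    cap_c = cap - cap.mean(axis=0)
    shift = cap.mean(axis=0) - des.mean(axis=0)
    tree = cKDTree(des_c)
    dist, idx = tree.query(cap_c)
    return ResidualStressMap(deviations=dist, translation=shift, pairs=idx)


def relative_pixel_change(
    moi_initial,
    moi_current,
    image_size: tuple[int, int] | None = (320, 240),
    reference: str = "center",
) -> float:
    """Relative pixel change ||dMOI|| / ||MOI0|| of a tracked MOI.

    With the default ``reference='center'`` convention, coordinates are
    measured from the image center so the sensitivity does not depend on
    where the origin sits in the frame; ``reference='origin'`` uses raw
    pixel coordinates.
    """
    p0 = np.asarray(moi_initial, dtype=float)
    p1 = np.asarray(moi_current, dtype=float)
    if reference == "center":
        if image_size is None:
            raise ValueError("image_size required for center reference")
        w, h = image_size
        c = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
        ref = p0 - c
    elif reference == "origin":
        ref = p0
    else:
        raise ValueError(f"unknown reference convention: {reference!r}")
    denom = np.linalg.norm(ref)
    if denom < 1e-12:
        raise ValueError("undefined ratio: initial MOI at the reference origin")
    return float(np.linalg.norm(p1 - p0) / denom)


def mape(series_s, series_a) -> float:
    """Mean absolute percentage error between two response series.

    100/n * sum_t |1 - A_t / S_t|, with ``series_s`` the reference response.
    """
    s = np.asarray(series_s, dtype=float)
    a = np.asarray(series_a, dtype=float)
    if s.shape != a.shape:
        raise ValueError("series must have equal length")
    if np.any(s == 0):
        raise ValueError("reference series contains zero entries")
    return float(100.0 * np.mean(np.abs(1.0 - a / s)))
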