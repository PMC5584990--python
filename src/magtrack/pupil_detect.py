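"""Pupil and corneal-reflection extraction from eye-camera images.

The eye is illuminated with infrared light, so the pupil appears dark and
each camera's LED produces a compact bright corneal reflection (CR).  The
processing order matters:

1. :func:`detect_crs` -- threshold bright pixels and localize CR candidates
   with a circular Hough transform (centroid-refined to subpixel); the
   reference CR is the candidate nearest the image center, where the rig is
   aligned to place it.  The reflection of the *opposite* camera's LED
   appears as a displaced distractor and is ignored.
2. :func:`mask_crs` -- replace each CR disc with the median of an annular
   neighborhood so the bright spots cannot masquerade as pupil edges.
3. :func:`detect_pupil` -- the Starburst procedure: cast rays from a seed
   point, take the strongest dark-to-light gradient along each ray as a
   candidate pupil edge, re-seed at the candidate centroid and iterate,
   then fit an ellipse to the candidates with random-sample consensus.
4. :func:`detect_sync_flash` -- find the 1 Hz, 30 ms LED sync flashes in a
   per-frame mean-intensity series (median + k*MAD threshold, consecutive
   supra-threshold frames merged into one onset).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates
from skimage.measure import EllipseModel, ransac
from skimage.transform import hough_circle, hough_circle_peaks

__all__ = [
    "CRDetection",
    "EllipseFit",
    "detect_crs",
    "mask_crs",
    "detect_pupil",
    "detect_sync_flash",
    "find_pupil_seed",
]


@dataclass
class CRDetection:
    """Bright-spot (CR) candidates, sorted by Hough score."""

    centers_px: np.ndarray  # (n, 2) as (x, y)
    radii_px: np.ndarray
    scores: np.ndarray
    reference_index: int | None  # candidate nearest the image center

    def __post_init__(self):
        self.centers_px = np.asarray(self.centers_px, dtype=float).reshape(-1, 2)
        self.radii_px = np.asarray(self.radii_px, dtype=float)
        self.scores = np.asarray(self.scores, dtype=float)

    def __len__(self) -> int:
        return self.centers_px.shape[0]

    @property
    def reference_center_px(self) -> np.ndarray:
        if self.reference_index is None:
            raise ValueError("no CR detected")
        return self.centers_px[self.reference_index]


@dataclass
class EllipseFit:
    """Robust ellipse fit of the pupil boundary."""

    center_px: tuple[float, float]
    semi_axes_px: tuple[float, float]
    orientation_deg: float
    inlier_fraction: float
    converged: bool

    def __post_init__(self):
        if self.converged and (self.semi_axes_px[0] <= 0 or self.semi_axes_px[1] <= 0):
            raise ValueError("semi-axes must be positive for a converged fit")
        if not 0.0 <= self.inlier_fraction <= 1.0:
            raise ValueError("inlier fraction must lie in [0, 1]")


def _failed_fit() -> EllipseFit:
    return EllipseFit(center_px=(np.nan, np.nan), semi_axes_px=(np.nan, np.nan),
                      orientation_deg=np.nan, inlier_fraction=0.0, converged=False)


def detect_crs(image, bright_threshold: float = 200.0,
               radius_range_px: tuple[int, int] = (2, 8),
               max_peaks: int = 4) -> CRDetection:
    """Localize corneal reflections by circular Hough accumulation.

    Bright pixels above ``bright_threshold`` form a binary map whose
    boundary votes in a Hough accumulator over ``radius_range_px``.  Peak
    centers (refined to the intensity centroid of the local bright blob)
    are returned sorted by score; the reference CR is the one nearest the
    image center.  An image with no bright pixel yields an empty detection.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a grayscale image")
    bright = img > bright_threshold
    if not bright.any():
        return CRDetection(np.empty((0, 2)), np.empty(0), np.empty(0), None)
    # boundary of the bright mask = circle edges for the Hough votes
    interior = (np.roll(bright, 1, 0) & np.roll(bright, -1, 0)
                & np.roll(bright, 1, 1) & np.roll(bright, -1, 1))
    edges = bright & ~interior
    radii = np.arange(radius_range_px[0], radius_range_px[1] + 1)
    accum = hough_circle(edges, radii)
    scores, cxs, cys, rs = hough_circle_peaks(
        accum, radii, total_num_peaks=max_peaks,
        min_xdistance=int(2 * radii[-1]), min_ydistance=int(2 * radii[-1]))
    if len(scores) == 0:
        return CRDetection(np.empty((0, 2)), np.empty(0), np.empty(0), None)
    centers = []
    for cx, cy, r in zip(cxs, cys, rs):
        centers.append(_centroid_refine(img, float(cx), float(cy), float(r) + 2.0,
                                        bright_threshold))
    centers = np.asarray(centers)
    h, w = img.shape
    dist = np.hypot(centers[:, 0] - w / 2.0, centers[:, 1] - h / 2.0)
    return CRDetection(centers_px=centers, radii_px=np.asarray(rs, float),
                       scores=np.asarray(scores, float),
                       reference_index=int(np.argmin(dist)))


def _centroid_refine(img: np.ndarray, cx: float, cy: float, radius: float,
                     floor: float) -> tuple[float, float]:
    """Subpixel center: intensity-above-floor centroid within a disc."""
    h, w = img.shape
    x0, x1 = max(0, int(cx - radius)), min(w, int(cx + radius) + 1)
    y0, y1 = max(0, int(cy - radius)), min(h, int(cy + radius) + 1)
    patch = img[y0:y1, x0:x1] - floor
    patch[patch < 0] = 0.0
    tot = patch.sum()
    if tot == 0:
        return cx, cy
    yy, xx = np.mgrid[y0:y1, x0:x1]
    return float((xx * patch).sum() / tot), float((yy * patch).sum() / tot)


def mask_crs(image, crs: CRDetection, safety_factor: float = 1.5,
             annulus_px: float = 3.0) -> np.ndarray:
    """Replace each CR disc with the median of its annular neighborhood.

    The disc radius is the Hough radius times ``safety_factor`` plus the
    blob's Gaussian tail allowance; the rest of the image is unchanged.  An
    empty detection returns the image untouched (a copy).
    """
    img = np.asarray(image, dtype=float).copy()
    h, w = img.shape
    yy, xx = np.mgrid[0:h, 0:w]
    for (cx, cy), r in zip(crs.centers_px, crs.radii_px):
        rm = r * safety_factor + 2.0
        d2 = (xx - cx) ** 2 + (yy - cy) ** 2
        disc = d2 <= rm**2
        annulus = (d2 > rm**2) & (d2 <= (rm + annulus_px) ** 2)
        if disc.any() and annulus.any():
            img[disc] = np.median(img[annulus])
    return img


def _ray_edge(img: np.ndarray, seed: np.ndarray, direction: np.ndarray,
              min_r: float, max_r: float, step: float,
              min_gradient: float) -> np.ndarray | None:
    """Strongest dark-to-light transition along one ray (subpixel), or None."""
    radii = np.arange(min_r, max_r, step)
    xs = seed[0] + radii * direction[0]
    ys = seed[1] + radii * direction[1]
    h, w = img.shape
    inside = (xs >= 0) & (xs <= w - 1) & (ys >= 0) & (ys <= h - 1)
    if inside.sum() < 5:
        return None
    xs, ys, radii = xs[inside], ys[inside], radii[inside]
    profile = map_coordinates(img, [ys, xs], order=1)
    grad = np.gradient(profile, step)
    i = int(np.argmax(grad))
    if grad[i] < min_gradient or i == 0 or i == grad.size - 1:
        return None
    # parabolic subpixel refinement of the gradient peak
    g0, g1, g2 = grad[i - 1], grad[i], grad[i + 1]
    denom = g0 - 2 * g1 + g2
    shift = 0.5 * (g0 - g2) / denom if denom != 0 else 0.0
    r = radii[i] + np.clip(shift, -1.0, 1.0) * step
    return seed + r * direction


def detect_pupil(image, seed_point_px, n_rays: int = 36,
                 min_radius_px: float = 3.0, max_radius_px: float = 150.0,
                 step_px: float = 0.5, min_gradient: float = 5.0,
                 max_iter: int = 10, min_edge_points: int = 8,
                 residual_threshold_px: float = 1.0,
                 seed: int = 0) -> EllipseFit:
    """Starburst pupil localization with consensus ellipse fitting.

    Casts ``n_rays`` rays from the seed point, takes the strongest
    dark-to-light gradient along each as a candidate pupil edge, re-seeds
    at the candidate centroid until the seed stabilizes, then fits an
    ellipse with RANSAC (fixed ``seed`` for reproducibility) followed by a
    least-squares refit on the inliers.  CRs should be masked first.
    Returns a non-converged fit (flagged frame) when too few edge points or
    no consensus is found.
    """
    img = gaussian_filter(np.asarray(image, dtype=float), 1.0)
    pt = np.asarray(seed_point_px, dtype=float)
    angles = np.linspace(0.0, 2.0 * np.pi, n_rays, endpoint=False)
    dirs = np.column_stack([np.cos(angles), np.sin(angles)])
    pts = np.empty((0, 2))
    for _ in range(max_iter):
        edges = [_ray_edge(img, pt, d, min_radius_px, max_radius_px,
                           step_px, min_gradient) for d in dirs]
        pts = np.array([e for e in edges if e is not None])
        if pts.shape[0] < min_edge_points:
            return _failed_fit()
        new = pts.mean(axis=0)
        if np.hypot(*(new - pt)) < 0.5:
            pt = new
            break
        pt = new
    try:
        model, inliers = ransac(pts, EllipseModel, min_samples=5,
                                residual_threshold=residual_threshold_px,
                                max_trials=100, rng=seed)
    except Exception:
        return _failed_fit()
    if model is None or inliers is None or inliers.sum() < 5:
        return _failed_fit()
    refined = EllipseModel.from_estimate(pts[inliers])
    if not refined:
        return _failed_fit()
    (xc, yc), (a, b), theta = refined.center, refined.axis_lengths, refined.theta
    if a < b:  # report major axis first, orientation accordingly
        a, b = b, a
        theta += np.pi / 2.0
    if a <= 0 or b <= 0:
        return _failed_fit()
    return EllipseFit(center_px=(float(xc), float(yc)),
                      semi_axes_px=(float(a), float(b)),
                      orientation_deg=float(np.rad2deg(theta) % 180.0),
                      inlier_fraction=float(inliers.mean()), converged=True)


def find_pupil_seed(image, blur_sigma: float = 8.0) -> tuple[float, float]:
    """Seed point for Starburst: the darkest point of a heavily blurred image."""
    img = gaussian_filter(np.asarray(image, dtype=float), blur_sigma)
    iy, ix = np.unravel_index(np.argmin(img), img.shape)
    return float(ix), float(iy)


def detect_sync_flash(frame_intensity_series, k_mad: float = 6.0) -> np.ndarray:
    """Onset frame indices of LED sync flashes in a mean-intensity series.

    Thresholds at baseline median + ``k_mad`` * MAD and merges runs of
    consecutive supra-threshold frames into single onsets (a 30 ms flash
    spans at most 2 frames at 30 frames/s).  Returns an empty array when
    nothing crosses threshold.
    """
    y = np.asarray(frame_intensity_series, dtype=float)
    if y.size < 2:
        return np.empty(0, dtype=int)
    med = np.median(y)
    mad = np.median(np.abs(y - med))
    thr = med + k_mad * max(mad, 1e-12)
    above = y > thr
    if not above.any():
        return np.empty(0, dtype=int)
    onsets = np.flatnonzero(above & ~np.roll(above, 1))
    if above[0]:
        onsets = np.unique(np.concatenate([[0], onsets]))
    return onsets
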