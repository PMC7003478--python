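"""The gray-matter-constrained bundle likelihood shared by both EM loops.

A bundle connecting ROIs (l1, l2) is a Gaussian around a centroid curve mu
with one isotropic variance sigma_bundle shared by every point of every
bundle (per-point covariances would be unstable for small bundles).  A
fiber's score under a bundle is the product of the shape density and the
best-pairing terminal density; everything is computed in log space because
the product over m points underflows double precision at moderate
distances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fiber_core import Fiber, orient_points
from .parcellation import DistanceField, InvalidBundleKeyError, terminal_pair_log_likelihood

__all__ = [
    "BundleKey",
    "UnknownBundleError",
    "canonical_key",
    "BundleModel",
    "fiber_shape_log_likelihood",
    "joint_log_likelihood",
]

BundleKey = tuple[int, int]


class UnknownBundleError(KeyError):
    """Raised when a bundle key is absent from a model."""


def canonical_key(l1: int, l2: int) -> BundleKey:
    """Canonical unordered ROI pair (l1 < l2); (l, l) is not a bundle."""
    if l1 == l2:
        raise InvalidBundleKeyError(f"bundle key requires two distinct ROIs, got ({l1}, {l2})")
    return (int(l1), int(l2)) if l1 < l2 else (int(l2), int(l1))


@dataclass
class BundleModel:
    """Centroid curves per ROI pair plus the two global sigmas (voxels)."""

    centroids: dict[BundleKey, np.ndarray]
    sigma_bundle: float = 2.0
    sigma_roi: float = 2.0

    def __post_init__(self):
        if self.sigma_bundle <= 0 or self.sigma_roi <= 0:
            raise ValueError("sigma values must be > 0")
        cleaned = {}
        m = None
        for key, mu in self.centroids.items():
            ck = canonical_key(*key)
            mu = np.asarray(mu, dtype=float)
            if m is None:
                m = len(mu)
            elif len(mu) != m:
                raise ValueError("all centroids must share the same point count")
            cleaned[ck] = mu
        self.centroids = cleaned

    @property
    def n_points(self) -> int:
        if not self.centroids:
            raise ValueError("empty model")
        return len(next(iter(self.centroids.values())))

    def keys(self) -> list[BundleKey]:
        return sorted(self.centroids)

    def __len__(self) -> int:
        return len(self.centroids)


def fiber_shape_log_likelihood(fiber, centroid: np.ndarray, sigma_bundle: float) -> float:
    """Log Gaussian shape density of a fiber around a bundle centroid.

    Points are treated as independent; the fiber must already be
    orientation-normalized to the centroid.
    """
    pts = fiber.points if isinstance(fiber, Fiber) else np.asarray(fiber, dtype=float)
    mu = np.asarray(centroid, dtype=float)
    if pts.shape != mu.shape:
        raise ValueError(f"point counts differ: {pts.shape} vs {mu.shape}")
    if sigma_bundle <= 0:
        raise ValueError("sigma_bundle must be > 0")
    m = len(pts)
    ssq = float(((pts - mu) ** 2).sum())
    return -1.5 * m * np.log(2.0 * np.pi * sigma_bundle**2) - ssq / (2.0 * sigma_bundle**2)


def joint_log_likelihood(fiber, key: BundleKey, model: BundleModel, dist: DistanceField) -> float:
    """Shape log-likelihood plus best-pairing terminal log-likelihood.

    Orientation relative to the centroid is resolved first (the max over
    terminal pairings makes the terminal factor order-free already), so the
    result is invariant to reversing the fiber's stored point order.
    """
    ck = canonical_key(*key)
    if ck not in model.centroids:
        raise UnknownBundleError(f"bundle {ck} not in model")
    pts = fiber.points if isinstance(fiber, Fiber) else np.asarray(fiber, dtype=float)
    mu = model.centroids[ck]
    oriented, _ = orient_points(pts, mu)
    shape_ll = fiber_shape_log_likelihood(oriented, mu, model.sigma_bundle)
    term_ll, _ = terminal_pair_log_likelihood(dist, pts[0], pts[-1], ck[0], ck[1], model.sigma_roi)
    return shape_ll + term_ll
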