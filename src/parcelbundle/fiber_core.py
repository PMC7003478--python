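"""Fiber geometry: representation, arc-length resampling, orientation
normalization and curve-to-curve distance.

A fiber is an ordered 3-D polyline.  All geometry in this package lives in
voxel coordinates of the parcellation grid (0-based, voxel-center
convention); world<->voxel conversion happens only at I/O time.  Streamline
files carry no canonical point order, so orientation is resolved per
comparison: a fiber is used as stored or point-reversed, whichever matches
its reference better.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DegenerateFiberError",
    "Fiber",
    "FiberSet",
    "cumulative_arc_length",
    "resample_points",
    "resample_fiber",
    "orient_points",
    "orient_fiber",
    "fiber_distance",
]


class DegenerateFiberError(ValueError):
    """Raised for fibers with no usable geometry (zero arc length, NaNs)."""


def _points_of(obj) -> np.ndarray:
    pts = obj.points if isinstance(obj, Fiber) else np.asarray(obj, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError(f"expected an (n, 3) point array, got shape {pts.shape}")
    return pts


@dataclass
class Fiber:
    """An ordered 3-D polyline in voxel coordinates of the label grid."""

    points: np.ndarray
    id: int = 0

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError(f"fiber points must be (n, 3), got {pts.shape}")
        if len(pts) < 2:
            raise DegenerateFiberError("a fiber needs at least 2 points")
        if not np.all(np.isfinite(pts)):
            raise DegenerateFiberError("fiber contains non-finite coordinates")
        if cumulative_arc_length(pts)[-1] <= 0.0:
            raise DegenerateFiberError("fiber has zero total arc length")
        self.points = pts

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def terminals(self) -> tuple[np.ndarray, np.ndarray]:
        return self.points[0], self.points[-1]


@dataclass
class FiberSet:
    """A subject's streamlines plus the world->voxel affine of the label grid.

    Fiber ids are unique and dense 0..J-1; the affine maps streamline world
    coordinates (mm) to label-grid voxel coordinates.
    """

    fibers: list[Fiber]
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    subject_id: str = ""

    def __post_init__(self):
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine must be invertible")

    def __len__(self) -> int:
        return len(self.fibers)

    @classmethod
    def from_arrays(cls, arrays, affine=None, subject_id: str = "") -> "FiberSet":
        fibers = [Fiber(np.asarray(a, dtype=float), id=i) for i, a in enumerate(arrays)]
        return cls(fibers, np.eye(4) if affine is None else affine, subject_id)

    def resampled(self, m: int) -> "FiberSet":
        return FiberSet(
            [Fiber(resample_points(f.points, m), id=f.id) for f in self.fibers],
            self.affine,
            self.subject_id,
        )

    def to_array(self) -> np.ndarray:
        """Stack fibers into a (J, m, 3) array; requires a uniform point count."""
        counts = {f.n_points for f in self.fibers}
        if len(counts) > 1:
            raise ValueError("fibers have mixed point counts; resample first")
        return np.array([f.points for f in self.fibers], dtype=float)


def cumulative_arc_length(points: np.ndarray) -> np.ndarray:
    """Cumulative polyline arc length, s[0] = 0, s[-1] = total length."""
    pts = np.asarray(points, dtype=float)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def resample_points(points: np.ndarray, m: int) -> np.ndarray:
    """Resample a polyline to ``m`` points equally spaced in arc length."""
    if m < 2:
        raise ValueError("resample count m must be >= 2")
    pts = np.asarray(points, dtype=float)
    if len(pts) < 2:
        raise DegenerateFiberError("cannot resample a fiber with < 2 points")
    s = cumulative_arc_length(pts)
    total = s[-1]
    if total <= 0.0:
        raise DegenerateFiberError("cannot resample a zero-length fiber")
    target = np.linspace(0.0, total, m)
    out = np.empty((m, 3))
    for d in range(3):
        out[:, d] = np.interp(target, s, pts[:, d])
    out[0] = pts[0]
    out[-1] = pts[-1]
    return out


def resample_fiber(fiber: Fiber, m: int) -> Fiber:
    return Fiber(resample_points(_points_of(fiber), m), id=fiber.id)


def orient_points(points: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, bool]:
    """Return (points possibly reversed, reversed-flag) to best match reference.

    The orientation minimizing the mean corresponding-point distance to the
    reference wins; ties keep the stored order.
    """
    pts = np.asarray(points, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if pts.shape != ref.shape:
        raise ValueError(f"point counts differ: {pts.shape} vs {ref.shape}")
    d_fwd = np.linalg.norm(pts - ref, axis=1).mean()
    d_rev = np.linalg.norm(pts[::-1] - ref, axis=1).mean()
    if d_rev < d_fwd:
        return pts[::-1].copy(), True
    return pts, False


def orient_fiber(fiber: Fiber, reference: Fiber) -> Fiber:
    pts, _ = orient_points(_points_of(fiber), _points_of(reference))
    return Fiber(pts, id=fiber.id)


def fiber_distance(a, b) -> float:
    """Mean Euclidean distance over corresponding points of two curves.

    A pseudometric on orientation-normalized, equally-sampled fibers: it is
    symmetric, non-negative, zero iff the curves are identical, and obeys
    the triangle inequality.
    """
    pa, pb = _points_of(a), _points_of(b)
    if pa.shape != pb.shape:
        raise ValueError(f"point counts differ: {pa.shape} vs {pb.shape}")
    return float(np.linalg.norm(pa - pb, axis=1).mean())
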