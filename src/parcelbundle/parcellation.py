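"""Parcellation handling and the terminal-to-ROI projection likelihood.

A parcellation is a 3-D integer label volume (0 = background, 1..L = ROIs).
For each ROI l a Euclidean distance transform phi_l is precomputed on the
voxel grid; the probability of a fiber terminal r belonging to ROI l is an
isotropic Gaussian in the distance phi_l(r):

    p(r | l) = (2 pi sigma_ROI^2)^(-3/2) exp(-phi_l(r)^2 / (2 sigma_ROI^2))

sigma_ROI (voxels) encodes registration/tracking uncertainty.  Off-grid
queries use trilinear interpolation with distances clamped at the grid
boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "InvalidBundleKeyError",
    "Parcellation",
    "DistanceField",
    "build_distance_fields",
    "roi_log_likelihood",
    "terminal_pair_log_likelihood",
    "closest_roi_pair",
]


class InvalidBundleKeyError(ValueError):
    """Raised when an ROI pair does not form a valid bundle key (l1 == l2)."""


@dataclass
class Parcellation:
    """Integer label volume; 0 is background, 1..L are ROIs."""

    labels: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self):
        lab = np.asarray(self.labels)
        if lab.ndim != 3:
            raise ValueError(f"label volume must be 3-D, got {lab.ndim}-D")
        if not np.issubdtype(lab.dtype, np.integer):
            if np.allclose(lab, np.round(lab)):
                lab = np.round(lab).astype(np.int32)
            else:
                raise ValueError("label volume must be integer valued")
        if lab.min() < 0:
            raise ValueError("negative labels are not allowed")
        self.labels = lab
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def L(self) -> int:
        return int(self.labels.max())

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def present_labels(self) -> np.ndarray:
        vals = np.unique(self.labels)
        return vals[vals > 0]


@dataclass
class DistanceField:
    """Per-label Euclidean distance transforms with trilinear query.

    ``fields[l-1]`` holds, at each voxel, the distance (voxels) to the
    nearest voxel of ROI l; it is 0 on the ROI itself.  Queries outside the
    grid are clamped to the nearest grid position.
    """

    fields: np.ndarray  # (L, nx, ny, nz)
    shape: tuple[int, int, int]

    @property
    def L(self) -> int:
        return self.fields.shape[0]

    def query(self, points: np.ndarray, label: int) -> np.ndarray:
        """phi_label at continuous voxel coordinates (n, 3) -> (n,)."""
        if not 1 <= label <= self.L:
            raise ValueError(f"label {label} outside 1..{self.L}")
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return ndimage.map_coordinates(
            self.fields[label - 1], pts.T, order=1, mode="nearest"
        )

    def roi_centers(self) -> dict[int, np.ndarray]:
        """Center of mass of each ROI (its phi = 0 set), voxel coordinates."""
        centers = {}
        for l in range(1, self.L + 1):
            vox = np.argwhere(self.fields[l - 1] == 0.0)
            centers[l] = vox.mean(axis=0)
        return centers

    def query_all(self, points: np.ndarray) -> np.ndarray:
        """phi for every label at the given points: (n, 3) -> (n, L)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = np.empty((len(pts), self.L))
        for l in range(1, self.L + 1):
            out[:, l - 1] = self.query(pts, l)
        return out


def build_distance_fields(parc: Parcellation) -> DistanceField:
    """Exact Euclidean distance transform for each ROI, in voxel units."""
    L = parc.L
    if L < 1:
        raise ValueError("parcellation has no ROIs")
    empty = [l for l in range(1, L + 1) if not np.any(parc.labels == l)]
    if empty:
        raise ValueError(f"empty ROI label(s): {empty}")
    fields = np.empty((L,) + parc.shape)
    for l in range(1, L + 1):
        fields[l - 1] = ndimage.distance_transform_edt(parc.labels != l)
    return DistanceField(fields=fields, shape=parc.shape)


def roi_log_likelihood(dist: DistanceField, r: np.ndarray, label: int, sigma_roi: float) -> float:
    """Log of the terminal-to-ROI Gaussian density evaluated via phi_label."""
    if sigma_roi <= 0:
        raise ValueError("sigma_roi must be > 0")
    phi = float(dist.query(np.atleast_2d(r), label)[0])
    return -1.5 * np.log(2.0 * np.pi * sigma_roi**2) - phi**2 / (2.0 * sigma_roi**2)


def terminal_pair_log_likelihood(
    dist: DistanceField,
    r1: np.ndarray,
    r2: np.ndarray,
    l1: int,
    l2: int,
    sigma_roi: float,
) -> tuple[float, bool]:
    """Best-pairing joint terminal log-likelihood for bundle (l1, l2).

    Returns (max over the two terminal->ROI pairings of the summed log
    densities, flag).  The flag is True when the direct pairing
    (r1->l1, r2->l2) wins; ties keep the direct pairing.
    """
    if l1 == l2:
        raise InvalidBundleKeyError(f"bundle key requires two distinct ROIs, got ({l1}, {l2})")
    direct = roi_log_likelihood(dist, r1, l1, sigma_roi) + roi_log_likelihood(dist, r2, l2, sigma_roi)
    swapped = roi_log_likelihood(dist, r1, l2, sigma_roi) + roi_log_likelihood(dist, r2, l1, sigma_roi)
    if direct >= swapped:
        return direct, True
    return swapped, False


def closest_roi_pair(dist: DistanceField, r1: np.ndarray, r2: np.ndarray) -> tuple[int, int]:
    """Unordered ROI pair whose members are nearest to the two terminals.

    When both terminals are closest to the same ROI the terminal with the
    larger within-label distance falls back to its second-closest ROI (the
    model has no (l, l) bundle).  Distance ties break toward the smaller
    label index.
    """
    if dist.L < 2:
        raise ValueError("need at least 2 ROIs to form a pair")
    phi1 = dist.query_all(np.atleast_2d(r1))[0]
    phi2 = dist.query_all(np.atleast_2d(r2))[0]
    l1 = int(np.argmin(phi1)) + 1
    l2 = int(np.argmin(phi2)) + 1
    if l1 == l2:
        if phi1[l1 - 1] > phi2[l2 - 1]:
            order = np.argsort(phi1, kind="stable")
            l1 = int(order[1]) + 1
        else:
            order = np.argsort(phi2, kind="stable")
            l2 = int(order[1]) + 1
    return (l1, l2) if l1 < l2 else (l2, l1)
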