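"""Bundle quality metrics and cross-subject consistency pruning.

All metrics are in voxel units of the label grid and use the mean
corresponding-point fiber distance after orientation normalization:

- MIV  (mean inbundle variation): mean distance of assigned fibers to their
  bundle centroid; lower = more coherent bundles.
- MED  (mean end-to-ROI distance): mean summed distance of a fiber's two
  terminals to the ROIs of its assigned bundle (winning terminal pairing);
  lower = more anatomically consistent bundles.
- MBCD (mean bundle centroid difference): mean distance of subject-specific
  centroids (in common space) to the group centroids.
- GMIV (groupwise MIV): mean distance of all subjects' warped fibers to
  their group bundle centroids.

Consistency pruning discards bundles whose mean per-subject centroid
difference exceeds a threshold (2.5 voxels) or which are missing in any
subject.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bundle_model import BundleKey
from .fiber_core import fiber_distance, orient_points
from .parcellation import DistanceField

__all__ = [
    "MetricsReport",
    "mean_inbundle_variation",
    "mean_end_to_roi_distance",
    "mean_bundle_centroid_difference",
    "groupwise_miv",
    "prune_inconsistent_bundles",
    "single_subject_report",
    "group_report",
]


def _curve(entry) -> np.ndarray:
    """Accept either a bare curve or a (curve, mass) tuple."""
    if isinstance(entry, tuple):
        return np.asarray(entry[0], dtype=float)
    return np.asarray(entry, dtype=float)


def _oriented_distance(a: np.ndarray, b: np.ndarray) -> float:
    oriented, _ = orient_points(a, b)
    return fiber_distance(oriented, b)


@dataclass
class MetricsReport:
    """Flat container for metric values and per-bundle bookkeeping."""

    miv: float | None = None
    med: float | None = None
    mbcd: float | None = None
    gmiv: float | None = None
    bundle_counts: dict[BundleKey, int] = field(default_factory=dict)
    n_assigned: int = 0
    n_unassigned: int = 0
    per_bundle_centroid_difference: dict[BundleKey, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {}
        for name in ("miv", "med", "mbcd", "gmiv"):
            val = getattr(self, name)
            if val is not None:
                out[name] = val
        out["n_assigned"] = self.n_assigned
        out["n_unassigned"] = self.n_unassigned
        out["bundle_counts"] = {f"{k[0]}-{k[1]}": v for k, v in self.bundle_counts.items()}
        if self.per_bundle_centroid_difference:
            out["per_bundle_centroid_difference"] = {
                f"{k[0]}-{k[1]}": v for k, v in self.per_bundle_centroid_difference.items()
            }
        return out


def mean_inbundle_variation(
    fibers: np.ndarray, assignment: list[BundleKey | None], centroids: dict[BundleKey, np.ndarray]
) -> float:
    """Mean distance of assigned fibers to their bundle centroids (voxels)."""
    total, count = 0.0, 0
    for j, key in enumerate(assignment):
        if key is None:
            continue
        if key not in centroids:
            raise KeyError(f"assigned bundle {key} has no centroid")
        total += _oriented_distance(np.asarray(fibers[j]), centroids[key])
        count += 1
    if count == 0:
        raise ValueError("no assigned fibers")
    return total / count


def mean_end_to_roi_distance(
    fibers: np.ndarray, assignment: list[BundleKey | None], dist: DistanceField
) -> float:
    """Mean summed terminal-to-ROI distance under the winning pairing."""
    total, count = 0.0, 0
    for j, key in enumerate(assignment):
        if key is None:
            continue
        l1, l2 = key
        r1 = np.asarray(fibers[j][0])
        r2 = np.asarray(fibers[j][-1])
        p11 = float(dist.query(r1, l1)[0])
        p22 = float(dist.query(r2, l2)[0])
        p12 = float(dist.query(r1, l2)[0])
        p21 = float(dist.query(r2, l1)[0])
        if p11**2 + p22**2 <= p12**2 + p21**2:
            total += p11 + p22
        else:
            total += p12 + p21
        count += 1
    if count == 0:
        raise ValueError("no assigned fibers")
    return total / count


def mean_bundle_centroid_difference(
    subject_centroids: dict[int, dict[BundleKey, object]],
    common_centroids: dict[BundleKey, np.ndarray],
) -> float:
    """Mean distance of subject centroids to group centroids (voxels).

    Averaged over (subject, bundle) pairs present on both sides; subject
    centroids must already be in the common space.
    """
    total, count = 0.0, 0
    for cents in subject_centroids.values():
        for key, entry in cents.items():
            if key not in common_centroids:
                continue
            total += _oriented_distance(_curve(entry), common_centroids[key])
            count += 1
    if count == 0:
        raise ValueError("no shared bundles between subjects and the group model")
    return total / count


def groupwise_miv(
    fiber_sets: list[np.ndarray],
    assignments: list[list[BundleKey | None]],
    common_centroids: dict[BundleKey, np.ndarray],
    transforms: list,
) -> float:
    """Mean distance of all subjects' warped fibers to group centroids."""
    total, count = 0.0, 0
    for X, assignment, T in zip(fiber_sets, assignments, transforms):
        Xw = T.apply(np.asarray(X).reshape(-1, 3)).reshape(np.asarray(X).shape)
        for j, key in enumerate(assignment):
            if key is None or key not in common_centroids:
                continue
            total += _oriented_distance(Xw[j], common_centroids[key])
            count += 1
    if count == 0:
        raise ValueError("no assigned fibers")
    return total / count


def prune_inconsistent_bundles(
    subject_centroids: dict[int, dict[BundleKey, object]],
    common_centroids: dict[BundleKey, np.ndarray],
    threshold: float = 2.5,
) -> tuple[list[BundleKey], dict[BundleKey, float]]:
    """Keep bundles consistent across the whole group.

    A bundle is retained iff it is present in every subject and its mean
    per-subject centroid difference is <= threshold (strictly above
    discards).  Returns (retained keys, per-bundle mean difference for all
    group bundles present in every subject).
    """
    S = len(subject_centroids)
    report: dict[BundleKey, float] = {}
    retained: list[BundleKey] = []
    for key in sorted(common_centroids):
        diffs = [
            _oriented_distance(_curve(cents[key]), common_centroids[key])
            for cents in subject_centroids.values()
            if key in cents
        ]
        if len(diffs) < S:
            continue  # missing in some subject: disqualified
        mean_diff = float(np.mean(diffs))
        report[key] = mean_diff
        if mean_diff <= threshold:
            retained.append(key)
    return retained, report


def single_subject_report(result, dist: DistanceField) -> MetricsReport:
    """MIV/MED and per-bundle counts for a single-subject EM result."""
    counts: dict[BundleKey, int] = {}
    for key in result.assignment:
        if key is not None:
            counts[key] = counts.get(key, 0) + 1
    return MetricsReport(
        miv=mean_inbundle_variation(result.fibers, result.assignment, result.model.centroids),
        med=mean_end_to_roi_distance(result.fibers, result.assignment, dist),
        bundle_counts=counts,
        n_assigned=sum(counts.values()),
        n_unassigned=result.n_unassigned,
    )


def group_report(result, dist: DistanceField | None = None) -> MetricsReport:
    """GMIV/MBCD (and per-bundle differences) for a group bundling result."""
    warped_cents = result.warped_subject_centroids()
    common = result.model.centroids
    counts: dict[BundleKey, int] = {}
    for assignment in result.assignments:
        for key in assignment:
            if key is not None:
                counts[key] = counts.get(key, 0) + 1
    per_bundle: dict[BundleKey, float] = {}
    S = len(warped_cents)
    for key in sorted(common):
        diffs = [
            _oriented_distance(cents[key], common[key])
            for cents in warped_cents.values()
            if key in cents
        ]
        if len(diffs) == S:
            per_bundle[key] = float(np.mean(diffs))
    return MetricsReport(
        gmiv=groupwise_miv(result.fibers, result.assignments, common, result.model.transforms),
        mbcd=mean_bundle_centroid_difference(warped_cents, common),
        bundle_counts=counts,
        n_assigned=sum(counts.values()),
        n_unassigned=sum(int(m.unassigned.sum()) for m in result.memberships),
        per_bundle_centroid_difference=per_bundle,
    )
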