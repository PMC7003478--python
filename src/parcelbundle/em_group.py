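"""Groupwise bundling: joint estimation of common bundle centroids and one
nonrigid transform per subject.

Each subject's fiber set is treated as an i.i.d. sample from a common
bundle model after warping by a subject-specific transform T^s (native ->
common space; the parcellation lives in the common space and is never
warped).  A MAP/EM scheme alternates: memberships of warped fibers against
the common centroids; common-centroid update (membership-weighted mean of
warped fibers); per-subject native-space bundle centroids; and a
thin-plate-spline update aligning each subject's centroids (downsampled 3x)
to the common ones, weighted by bundle membership mass.  Initialization
rigidly pre-aligns each subject to the template by fitting its initial
bundle-centroid endpoints to the corresponding ROI centers.

Baseline group methods:

- ``independent``  each subject bundled alone, no alignment (method I)
- ``posthoc_tps``  independent bundling, then one TPS pass aligning each
  subject's centroids to the common mean (method II)
- ``pooled``       all subjects' fibers bundled as one fiber set (method III)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .bundle_model import BundleKey, BundleModel
from .em_single import (
    EMConfig,
    MembershipMatrix,
    _endpoint_phi,
    _resampled_array,
    e_step,
    initialize_model,
    m_step,
    run_em,
)
from .fiber_core import FiberSet, orient_points
from .parcellation import DistanceField, Parcellation, build_distance_fields
from .spatial_transforms import fit_rigid, fit_tps, identity_transform, warp_points

__all__ = [
    "GroupConfig",
    "GroupModel",
    "GroupResult",
    "initialize_group",
    "group_e_step",
    "update_common_centroids",
    "subject_centroids",
    "update_transforms",
    "run_group_em",
]

_METHODS = ("group", "independent", "posthoc_tps", "pooled")
_MASS_FLOOR = 1e-12


@dataclass
class GroupConfig(EMConfig):
    """EMConfig plus groupwise controls.

    group_change_threshold defaults to 20 * S (set at run time when None);
    downsample thins each centroid to every 3rd point for the TPS fit;
    tps_lambda None means 0.01 * bounding-box diagonal of the control
    points (configurable to 0 for exact interpolation).
    """

    group_max_iterations: int = 10
    group_change_threshold: int | None = None
    downsample: int = 3
    tps_lambda: float | None = None
    centroid_normalization: str = "per_bundle"  # or "global" (printed form)

    def __post_init__(self):
        super().__post_init__()
        if self.group_max_iterations < 1:
            raise ValueError("group_max_iterations must be >= 1")
        if self.downsample < 1:
            raise ValueError("downsample must be >= 1")
        if self.centroid_normalization not in ("per_bundle", "global"):
            raise ValueError("centroid_normalization must be 'per_bundle' or 'global'")


@dataclass
class GroupModel:
    """Common centroids plus one native->common transform per subject."""

    centroids: dict[BundleKey, np.ndarray]
    transforms: list
    sigma_bundle: float = 2.0
    sigma_roi: float = 2.0

    @property
    def S(self) -> int:
        return len(self.transforms)

    def keys(self) -> list[BundleKey]:
        return sorted(self.centroids)

    def as_bundle_model(self) -> BundleModel:
        return BundleModel(dict(self.centroids), self.sigma_bundle, self.sigma_roi)


@dataclass
class GroupResult:
    """Output of a groupwise bundling run (any of the four methods)."""

    model: GroupModel
    assignments: list[list[BundleKey | None]]
    memberships: list[MembershipMatrix]
    subject_centroids: dict[int, dict[BundleKey, tuple[np.ndarray, float]]]
    trace: list[dict]
    fibers: list[np.ndarray]  # native-space resampled (J_s, m, 3) per subject
    subject_ids: list[str]
    config: GroupConfig
    method: str

    def warped_subject_centroids(self) -> dict[int, dict[BundleKey, np.ndarray]]:
        """Subject bundle centroids mapped into the common space."""
        out: dict[int, dict[BundleKey, np.ndarray]] = {}
        for s, cents in self.subject_centroids.items():
            T = self.model.transforms[s]
            out[s] = {k: warp_points(T, curve) for k, (curve, _) in cents.items()}
        return out

    def warped_fibers(self) -> list[np.ndarray]:
        out = []
        for s, X in enumerate(self.fibers):
            T = self.model.transforms[s]
            out.append(warp_points(T, X.reshape(-1, 3)).reshape(X.shape))
        return out


def _warp_fiber_array(transform, X: np.ndarray) -> np.ndarray:
    return warp_points(transform, X.reshape(-1, 3)).reshape(X.shape)


def _pooled_mean(entries: list[tuple[np.ndarray, float]]) -> tuple[np.ndarray, float]:
    """Mass-weighted mean of curves, orientation-normalized to the heaviest."""
    ref = max(entries, key=lambda e: e[1])[0]
    total = 0.0
    acc = np.zeros_like(ref)
    for curve, mass in entries:
        oriented, _ = orient_points(curve, ref)
        acc += mass * oriented
        total += mass
    return acc / total, total


def _pool_centroids(
    per_subject: dict[int, dict[BundleKey, tuple[np.ndarray, float]]]
) -> dict[BundleKey, tuple[np.ndarray, float]]:
    keys = sorted({k for cents in per_subject.values() for k in cents})
    pooled = {}
    for k in keys:
        entries = [cents[k] for cents in per_subject.values() if k in cents]
        pooled[k] = _pooled_mean(entries)
    return pooled


def _subject_init_centroids(
    X: np.ndarray, dist: DistanceField, cfg: EMConfig
) -> tuple[dict[BundleKey, tuple[np.ndarray, float]], list[BundleKey]]:
    model, assignment = initialize_model(FiberSet.from_arrays(X), dist, cfg)
    counts: dict[BundleKey, int] = {}
    for key in assignment:
        counts[key] = counts.get(key, 0) + 1
    cents = {k: (model.centroids[k], float(counts[k])) for k in model.centroids}
    return cents, assignment


def initialize_group(
    fiber_sets: list[FiberSet], parc: Parcellation | DistanceField, cfg: GroupConfig
) -> tuple[GroupModel, list[list[BundleKey]], list[np.ndarray]]:
    """Rigid pre-alignment to the template and pooled initial centroids.

    Each subject's fibers are classified by closest ROI pair in native
    space; a weighted Procrustes fit of its initial centroid endpoints to
    the ROI centers gives T^0 (kept only when it removes most of the
    residual); warped fibers are then reclassified and pooled into the
    initial common centroids.
    """
    if not fiber_sets:
        raise ValueError("need at least one subject")
    dist = parc if isinstance(parc, DistanceField) else build_distance_fields(parc)
    Xs = [_resampled_array(fs, cfg.m) for fs in fiber_sets]
    for s, X in enumerate(Xs):
        if len(X) == 0:
            sid = fiber_sets[s].subject_id or str(s)
            raise ValueError(f"subject {sid!r} has no assignable fibers")

    native_cents = {}
    for s, X in enumerate(Xs):
        native_cents[s], _ = _subject_init_centroids(X, dist, cfg)

    # rigid alignment of every subject to the template: the endpoints of a
    # subject's initial (l1, l2) centroid should sit on the centers of ROIs
    # l1 and l2, which anchors the common frame to the parcellation and
    # recovers a rigid displacement of any single subject independently
    centers = dist.roi_centers()
    transforms = [identity_transform() for _ in Xs]
    for s, cents in native_cents.items():
        src, tgt, w = [], [], []
        for (l1, l2), (curve, n) in cents.items():
            src.extend([curve[0], curve[-1]])
            tgt.extend([centers[l1], centers[l2]])
            w.extend([n, n])
        src_a, tgt_a, w_a = np.array(src), np.array(tgt), np.array(w)
        try:
            fit = fit_rigid(src_a, tgt_a, w_a)
        except ValueError:
            warnings.warn(f"subject {s}: degenerate rigid init; using identity")
            continue
        rss_id = float((w_a * ((src_a - tgt_a) ** 2).sum(axis=1)).sum())
        rss_fit = float((w_a * ((fit.apply(src_a) - tgt_a) ** 2).sum(axis=1)).sum())
        # the rigid pre-alignment corrects gross misalignment only: accept
        # the fit when it removes most of the residual, keep identity when
        # the improvement is at noise level (the TPS updates handle the
        # rest), so aligned subjects are not perturbed by jitter noise
        if rss_fit < 0.25 * rss_id:
            transforms[s] = fit

    # reclassify warped fibers and pool the initial common centroids
    warped_cents = {}
    assignments = []
    for s, X in enumerate(Xs):
        Xw = _warp_fiber_array(transforms[s], X)
        warped_cents[s], assignment = _subject_init_centroids(Xw, dist, cfg)
        assignments.append(assignment)
    pooled = _pool_centroids(warped_cents)
    centroids = {k: curve for k, (curve, _) in pooled.items()}
    model = GroupModel(centroids, transforms, cfg.sigma_bundle, cfg.sigma_roi)
    return model, assignments, Xs


def group_e_step(
    Xs: list[np.ndarray], group: GroupModel, dist: DistanceField, cfg: GroupConfig
) -> tuple[list[MembershipMatrix], list[np.ndarray]]:
    """Memberships of each subject's warped fibers against the common model.

    Returns the per-subject membership matrices and the warped fiber arrays
    (terminal distances are evaluated on warped terminals in common space).
    """
    bm = group.as_bundle_model()
    membs, Xws = [], []
    for s, X in enumerate(Xs):
        Xw = _warp_fiber_array(group.transforms[s], X)
        phi = _endpoint_phi(Xw, dist)
        membs.append(e_step(Xw, bm, dist, cfg, phi=phi))
        Xws.append(Xw)
    return membs, Xws


def update_common_centroids(
    Xws: list[np.ndarray], membs: list[MembershipMatrix], cfg: GroupConfig
) -> dict[BundleKey, np.ndarray]:
    """Membership-weighted mean of all subjects' warped fibers per bundle.

    Normalization is per bundle by default; 'global' reproduces the printed
    all-bundle denominator for comparison (it does not yield mean curves).
    """
    keys = membs[0].keys
    K = len(keys)
    num = [np.zeros_like(Xws[0][0]) for _ in range(K)]
    den = np.zeros(K)
    for X, memb in zip(Xws, membs):
        Xrev = X[:, ::-1, :]
        w = memb.values
        if cfg.m_step_assignment == "hard":
            hard = np.zeros_like(w)
            idx = np.argmax(w, axis=1)
            rows = np.where(~memb.unassigned)[0]
            hard[rows, idx[rows]] = 1.0
            w = hard
        for k in range(K):
            wk = w[:, k]
            if wk.sum() < _MASS_FLOOR:
                continue
            Xo = np.where(memb.orientations[:, k][:, None, None], Xrev, X)
            num[k] += np.tensordot(wk, Xo, axes=1)
            den[k] += wk.sum()
    out = {}
    total = den.sum()
    for k, key in enumerate(keys):
        if den[k] < _MASS_FLOOR:
            continue
        norm = total if cfg.centroid_normalization == "global" else den[k]
        out[key] = num[k] / norm
    return out


def subject_centroids(
    Xs: list[np.ndarray], membs: list[MembershipMatrix], cfg: GroupConfig
) -> dict[int, dict[BundleKey, tuple[np.ndarray, float]]]:
    """Per-subject native-space bundle centroids with membership mass."""
    out: dict[int, dict[BundleKey, tuple[np.ndarray, float]]] = {}
    for s, (X, memb) in enumerate(zip(Xs, membs)):
        cents = m_step(X, memb, cfg)
        masses = memb.values.sum(axis=0)
        out[s] = {
            key: (curve, float(masses[memb.keys.index(key)]))
            for key, curve in cents.items()
        }
    return out


def update_transforms(
    subj_cents: dict[int, dict[BundleKey, tuple[np.ndarray, float]]],
    common: dict[BundleKey, np.ndarray],
    cfg: GroupConfig,
    previous: list | None = None,
) -> list:
    """TPS per subject from native centroid points to common centroid points.

    Each centroid contributes every ``cfg.downsample``-th point (indices
    0, 3, 6, ...), weighted by its bundle membership mass.  Subjects with
    too few or degenerate correspondences keep their previous transform.
    """
    S = len(subj_cents)
    transforms = list(previous) if previous is not None else [identity_transform()] * S
    step = cfg.downsample
    for s, cents in subj_cents.items():
        src, tgt, w = [], [], []
        for k, (curve, mass) in cents.items():
            if k not in common or mass < _MASS_FLOOR:
                continue
            idx = np.arange(0, len(curve), step)
            src.append(curve[idx])
            tgt.append(common[k][idx])
            w.append(np.full(len(idx), mass))
        if not src:
            warnings.warn(f"subject {s}: no shared bundles; keeping previous transform")
            continue
        src_pts = np.vstack(src)
        tgt_pts = np.vstack(tgt)
        weights = np.concatenate(w)
        if cfg.tps_lambda is None:
            span = src_pts.max(axis=0) - src_pts.min(axis=0)
            lam = 0.01 * float(np.linalg.norm(span))
        else:
            lam = cfg.tps_lambda
        try:
            transforms[s] = fit_tps(src_pts, tgt_pts, lam=lam, weights=weights)
        except ValueError as exc:
            warnings.warn(f"subject {s}: TPS fit failed ({exc}); keeping previous transform")
    return transforms


def _count_changes(a, b) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def _run_full_group(
    fiber_sets: list[FiberSet], dist: DistanceField, cfg: GroupConfig
) -> GroupResult:
    group, assigns_prev, Xs = initialize_group(fiber_sets, dist, cfg)
    threshold = (
        cfg.group_change_threshold
        if cfg.group_change_threshold is not None
        else cfg.change_threshold * len(Xs)
    )
    trace: list[dict] = []
    membs: list[MembershipMatrix] = []
    for it in range(1, cfg.group_max_iterations + 1):
        membs, Xws = group_e_step(Xs, group, dist, cfg)
        assigns = [m.hard_assignment() for m in membs]
        changes = sum(_count_changes(a, b) for a, b in zip(assigns, assigns_prev))
        loglik = sum(m.total_log_likelihood() for m in membs)
        trace.append(
            {
                "iteration": it,
                "changes": changes,
                "log_likelihood": loglik,
                "n_bundles": len(group.centroids),
            }
        )
        new_common = update_common_centroids(Xws, membs, cfg)
        if not new_common:
            raise ValueError("all bundles lost their membership mass")
        group = GroupModel(new_common, group.transforms, cfg.sigma_bundle, cfg.sigma_roi)
        subj_cents = subject_centroids(Xs, membs, cfg)
        group = GroupModel(
            group.centroids,
            update_transforms(subj_cents, group.centroids, cfg, previous=group.transforms),
            cfg.sigma_bundle,
            cfg.sigma_roi,
        )
        assigns_prev = assigns
        if changes <= threshold:
            break
    # refresh against the final model so outputs are self-consistent
    membs, _ = group_e_step(Xs, group, dist, cfg)
    assigns = [m.hard_assignment() for m in membs]
    subj_cents = subject_centroids(Xs, membs, cfg)
    return GroupResult(
        model=group,
        assignments=assigns,
        memberships=membs,
        subject_centroids=subj_cents,
        trace=trace,
        fibers=Xs,
        subject_ids=[fs.subject_id or str(s) for s, fs in enumerate(fiber_sets)],
        config=cfg,
        method="group",
    )


def _single_cfg(cfg: GroupConfig) -> EMConfig:
    return EMConfig(
        sigma_roi=cfg.sigma_roi,
        sigma_bundle=cfg.sigma_bundle,
        m=cfg.m,
        max_iterations=cfg.max_iterations,
        change_threshold=cfg.change_threshold,
        mode=cfg.mode,
        gate_multiplier=cfg.gate_multiplier,
        m_step_assignment=cfg.m_step_assignment,
        seed=cfg.seed,
    )


def _run_independent(
    fiber_sets: list[FiberSet], dist: DistanceField, cfg: GroupConfig, method: str
) -> GroupResult:
    scfg = _single_cfg(cfg)
    results = [run_em(fs, dist, scfg) for fs in fiber_sets]
    Xs = [r.fibers for r in results]
    subj_cents: dict[int, dict[BundleKey, tuple[np.ndarray, float]]] = {}
    for s, r in enumerate(results):
        masses = r.memberships.values.sum(axis=0)
        subj_cents[s] = {
            k: (r.model.centroids[k], float(masses[r.memberships.keys.index(k)]))
            for k in r.model.centroids
        }
    pooled = _pool_centroids(subj_cents)
    common = {k: curve for k, (curve, _) in pooled.items()}
    transforms = [identity_transform() for _ in fiber_sets]
    if method == "posthoc_tps":
        transforms = update_transforms(subj_cents, common, cfg, previous=transforms)
        warped = {
            s: {k: (warp_points(transforms[s], c), n) for k, (c, n) in cents.items()}
            for s, cents in subj_cents.items()
        }
        pooled = _pool_centroids(warped)
        common = {k: curve for k, (curve, _) in pooled.items()}
    model = GroupModel(common, transforms, cfg.sigma_bundle, cfg.sigma_roi)
    return GroupResult(
        model=model,
        assignments=[r.assignment for r in results],
        memberships=[r.memberships for r in results],
        subject_centroids=subj_cents,
        trace=[{"per_subject_iterations": [r.n_iterations for r in results]}],
        fibers=Xs,
        subject_ids=[fs.subject_id or str(s) for s, fs in enumerate(fiber_sets)],
        config=cfg,
        method=method,
    )


def _run_pooled(
    fiber_sets: list[FiberSet], dist: DistanceField, cfg: GroupConfig
) -> GroupResult:
    scfg = _single_cfg(cfg)
    Xs = [_resampled_array(fs, cfg.m) for fs in fiber_sets]
    pooled_fs = FiberSet.from_arrays(np.concatenate(Xs, axis=0))
    result = run_em(pooled_fs, dist, scfg)
    bounds = np.cumsum([0] + [len(X) for X in Xs])
    assignments = [
        result.assignment[bounds[s] : bounds[s + 1]] for s in range(len(Xs))
    ]
    membs = []
    subj_cents: dict[int, dict[BundleKey, tuple[np.ndarray, float]]] = {}
    for s in range(len(Xs)):
        sl = slice(bounds[s], bounds[s + 1])
        sub = MembershipMatrix(
            keys=result.memberships.keys,
            values=result.memberships.values[sl],
            orientations=result.memberships.orientations[sl],
            log_liks=result.memberships.log_liks[sl],
            gated=result.memberships.gated[sl],
            unassigned=result.memberships.unassigned[sl],
            log_evidence=result.memberships.log_evidence[sl],
        )
        membs.append(sub)
        cents = m_step(Xs[s], sub, cfg)
        masses = sub.values.sum(axis=0)
        subj_cents[s] = {
            k: (curve, float(masses[sub.keys.index(k)])) for k, curve in cents.items()
        }
    model = GroupModel(
        dict(result.model.centroids),
        [identity_transform() for _ in Xs],
        cfg.sigma_bundle,
        cfg.sigma_roi,
    )
    return GroupResult(
        model=model,
        assignments=assignments,
        memberships=membs,
        subject_centroids=subj_cents,
        trace=result.trace,
        fibers=Xs,
        subject_ids=[fs.subject_id or str(s) for s, fs in enumerate(fiber_sets)],
        config=cfg,
        method="pooled",
    )


def run_group_em(
    fiber_sets: list[FiberSet],
    parc: Parcellation | DistanceField,
    cfg: GroupConfig,
    method: str = "group",
) -> GroupResult:
    """Run groupwise bundling with the chosen method.

    ``group`` is the full joint alignment+clustering EM; ``independent``,
    ``posthoc_tps`` and ``pooled`` are the comparison baselines (methods
    I-III).
    """
    if method not in _METHODS:
        raise ValueError(f"method must be one of {_METHODS}, got {method!r}")
    if not fiber_sets:
        raise ValueError("need at least one subject")
    dist = parc if isinstance(parc, DistanceField) else build_distance_fields(parc)
    if method == "group":
        return _run_full_group(fiber_sets, dist, cfg)
    if method in ("independent", "posthoc_tps"):
        return _run_independent(fiber_sets, dist, cfg, method)
    return _run_pooled(fiber_sets, dist, cfg)
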