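"""Synthetic ground-truthed phantoms emulating the bundling model.

A phantom is a parcellation of ball-shaped ROIs at Poisson-disk-sampled
centers, smooth (quadratic Bezier) bundle centroids between ROI-center
pairs, and fibers sampled as centroid plus i.i.d. isotropic Gaussian point
noise with separate terminal jitter (terminal displacements are clipped at
3x the jitter scale so terminals stay attached to their true ROIs).  Fiber
point order is reversed with probability 1/2 to exercise orientation
handling.  Group phantoms add one independent smooth TPS misregistration
per subject, recorded as ground truth.

Randomness flows from a single seed through per-operation substreams, so
changing e.g. the fiber count does not perturb the parcellation geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .bundle_model import BundleKey, canonical_key
from .fiber_core import FiberSet, resample_points
from .parcellation import Parcellation
from .spatial_transforms import fit_tps, identity_transform

__all__ = [
    "Phantom",
    "GroupPhantom",
    "make_parcellation",
    "roi_centers",
    "make_bundles",
    "sample_fibers",
    "make_phantom",
    "make_group",
]


def _substreams(seed: int, n: int) -> list[int]:
    """Derive n child seeds (< 2**31) from one master seed."""
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s & 0x7FFFFFFF) for s in state]


def make_parcellation(
    grid: int = 48,
    L: int = 12,
    roi_radius: float = 3.5,
    seed: int = 0,
    min_gap: float = 2.0,
    max_tries: int = 20000,
) -> Parcellation:
    """L disjoint ball-shaped ROIs at Poisson-disk-sampled centers."""
    rng = np.random.default_rng(seed)
    margin = roi_radius + 1.5
    lo, hi = margin, grid - 1 - margin
    if hi <= lo:
        raise ValueError("grid too small for the requested ROI radius")
    min_dist = 2.0 * roi_radius + min_gap
    centers: list[np.ndarray] = []
    tries = 0
    while len(centers) < L:
        if tries >= max_tries:
            raise RuntimeError(
                f"could not place {L} ROIs of radius {roi_radius} in a {grid}^3 "
                "grid; reduce L or roi_radius"
            )
        tries += 1
        cand = rng.uniform(lo, hi, size=3)
        if all(np.linalg.norm(cand - c) > min_dist for c in centers):
            centers.append(cand)
    labels = np.zeros((grid, grid, grid), dtype=np.int16)
    ii, jj, kk = np.indices(labels.shape)
    coords = np.stack([ii, jj, kk], axis=-1).astype(float)
    for l, c in enumerate(centers, start=1):
        mask = np.linalg.norm(coords - c, axis=-1) <= roi_radius
        labels[mask] = l
    return Parcellation(labels)


def roi_centers(parc: Parcellation) -> dict[int, np.ndarray]:
    """Center of mass of each ROI, in voxel coordinates."""
    labs = parc.present_labels()
    coms = ndimage.center_of_mass(np.ones_like(parc.labels), parc.labels, labs)
    return {int(l): np.asarray(c, dtype=float) for l, c in zip(labs, coms)}


def make_bundles(
    parc: Parcellation, K: int = 10, m: int = 20, seed: int = 0
) -> dict[BundleKey, np.ndarray]:
    """K smooth centroid curves between distinct ROI-center pairs.

    Each centroid is a quadratic Bezier from one ROI center to another with
    a randomized perpendicular mid-point bow (5-15% of the chord, keeping
    turning angles gentle), resampled to m equal-arc-length points and
    stored from the smaller to the larger label.
    """
    rng = np.random.default_rng(seed)
    centers = roi_centers(parc)
    labels = sorted(centers)
    pairs = [(a, b) for i, a in enumerate(labels) for b in labels[i + 1 :]]
    if K > len(pairs):
        raise ValueError(f"K={K} exceeds the {len(pairs)} available ROI pairs")
    chosen = [pairs[i] for i in rng.choice(len(pairs), size=K, replace=False)]
    centroids: dict[BundleKey, np.ndarray] = {}
    for l1, l2 in chosen:
        p0, p2 = centers[l1], centers[l2]
        chord = p2 - p0
        length = np.linalg.norm(chord)
        u = chord / length
        # random unit vector perpendicular to the chord
        v = rng.normal(size=3)
        v -= (v @ u) * u
        v /= np.linalg.norm(v)
        bow = rng.uniform(0.05, 0.15) * length
        p1 = 0.5 * (p0 + p2) + bow * v
        t = np.linspace(0.0, 1.0, 200)[:, None]
        bez = (1 - t) ** 2 * p0 + 2 * t * (1 - t) * p1 + t**2 * p2
        centroids[canonical_key(l1, l2)] = resample_points(bez, m)
    return centroids


def sample_fibers(
    centroids: dict[BundleKey, np.ndarray],
    n_per_bundle: int = 50,
    point_noise: float = 1.0,
    terminal_jitter: float = 1.0,
    seed: int = 0,
    subject_id: str = "",
) -> tuple[FiberSet, list[BundleKey]]:
    """Fibers = centroid + i.i.d. N(0, point_noise^2 I) per interior point.

    Terminals get independent jitter of scale ``terminal_jitter`` instead,
    clipped to norm <= 3 * terminal_jitter, so they stay within reach of
    their true ROIs.  Each fiber's point order is reversed with probability
    1/2.
    """
    if point_noise < 0 or terminal_jitter < 0:
        raise ValueError("noise scales must be >= 0")
    rng = np.random.default_rng(seed)
    arrays: list[np.ndarray] = []
    labels: list[BundleKey] = []
    for key in sorted(centroids):
        mu = np.asarray(centroids[key], dtype=float)
        m = len(mu)
        for _ in range(n_per_bundle):
            pts = mu + rng.normal(0.0, point_noise, size=(m, 3)) if point_noise > 0 else mu.copy()
            for end in (0, m - 1):
                jit = rng.normal(0.0, terminal_jitter, size=3) if terminal_jitter > 0 else np.zeros(3)
                norm = np.linalg.norm(jit)
                cap = 3.0 * terminal_jitter
                if norm > cap > 0:
                    jit *= cap / norm
                pts[end] = mu[end] + jit
            if rng.random() < 0.5:
                pts = pts[::-1]
            arrays.append(pts)
            labels.append(key)
    return FiberSet.from_arrays(arrays, subject_id=subject_id), labels


@dataclass
class Phantom:
    """A fully ground-truthed single-subject dataset."""

    parcellation: Parcellation
    centroids: dict[BundleKey, np.ndarray]
    fiber_set: FiberSet
    labels: list[BundleKey]
    params: dict = field(default_factory=dict)


def make_phantom(
    grid: int = 48,
    L: int = 12,
    K: int = 10,
    n_per_bundle: int = 50,
    point_noise: float = 1.0,
    terminal_jitter: float = 1.0,
    m: int = 20,
    roi_radius: float = 3.5,
    seed: int = 0,
) -> Phantom:
    """Default phantom: 48^3 grid, 12 ROIs, 10 bundles, 50 fibers each."""
    s_parc, s_bund, s_fib = _substreams(seed, 3)
    parc = make_parcellation(grid=grid, L=L, roi_radius=roi_radius, seed=s_parc)
    centroids = make_bundles(parc, K=K, m=m, seed=s_bund)
    fibers, labels = sample_fibers(
        centroids,
        n_per_bundle=n_per_bundle,
        point_noise=point_noise,
        terminal_jitter=terminal_jitter,
        seed=s_fib,
    )
    return Phantom(
        parcellation=parc,
        centroids=centroids,
        fiber_set=fibers,
        labels=labels,
        params=dict(
            grid=grid,
            L=L,
            K=K,
            n_per_bundle=n_per_bundle,
            point_noise=point_noise,
            terminal_jitter=terminal_jitter,
            m=m,
            roi_radius=roi_radius,
            seed=seed,
        ),
    )


@dataclass
class GroupPhantom:
    """A multi-subject phantom with per-subject smooth misregistration."""

    parcellation: Parcellation
    centroids: dict[BundleKey, np.ndarray]
    fiber_sets: list[FiberSet]
    labels: list[list[BundleKey]]
    warps: list  # recorded ground-truth common->native transforms
    params: dict = field(default_factory=dict)


def _random_smooth_warp(
    grid: int, magnitude: float, rng: np.random.Generator, n_ctrl: int = 3, max_tries: int = 20
):
    """A TPS warp with fixed-magnitude random control displacements.

    Resamples (bounded retries) if a sampled Jacobian determinant goes
    non-positive (folding).
    """
    axis = np.linspace(4.0, grid - 5.0, n_ctrl)
    gx, gy, gz = np.meshgrid(axis, axis, axis, indexing="ij")
    ctrl = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
    for _ in range(max_tries):
        direc = rng.normal(size=ctrl.shape)
        direc /= np.linalg.norm(direc, axis=1, keepdims=True)
        warp = fit_tps(ctrl, ctrl + magnitude * direc, lam=0.0)
        probe = rng.uniform(6.0, grid - 7.0, size=(60, 3))
        eps = 0.5
        ok = True
        for p in probe[:20]:
            J = np.empty((3, 3))
            for d in range(3):
                dp = np.zeros(3)
                dp[d] = eps
                J[:, d] = (warp.apply(p + dp) - warp.apply(p - dp)) / (2 * eps)
            if np.linalg.det(J) <= 0:
                ok = False
                break
        if ok:
            return warp
    raise RuntimeError("could not sample a fold-free warp; reduce magnitude")


def make_group(
    S: int = 5,
    warp_magnitude: float = 2.0,
    seed: int = 0,
    grid: int = 48,
    L: int = 12,
    K: int = 10,
    n_per_bundle: int = 50,
    point_noise: float = 1.0,
    terminal_jitter: float = 1.0,
    m: int = 20,
    roi_radius: float = 3.5,
) -> GroupPhantom:
    """S subjects sampled from common true bundles, each smoothly misregistered."""
    if warp_magnitude >= roi_radius:
        raise ValueError("warp magnitude must stay below the ROI radius")
    s_parc, s_bund, s_grp = _substreams(seed, 3)
    parc = make_parcellation(grid=grid, L=L, roi_radius=roi_radius, seed=s_parc)
    centroids = make_bundles(parc, K=K, m=m, seed=s_bund)
    subj_seeds = _substreams(s_grp, 2 * S)
    fiber_sets: list[FiberSet] = []
    labels: list[list[BundleKey]] = []
    warps = []
    for s in range(S):
        fibers, lab = sample_fibers(
            centroids,
            n_per_bundle=n_per_bundle,
            point_noise=point_noise,
            terminal_jitter=terminal_jitter,
            seed=subj_seeds[2 * s],
            subject_id=f"sub-{s:02d}",
        )
        if warp_magnitude > 0:
            rng = np.random.default_rng(subj_seeds[2 * s + 1])
            warp = _random_smooth_warp(grid, warp_magnitude, rng)
            arrays = [warp.apply(f.points) for f in fibers.fibers]
            fibers = FiberSet.from_arrays(arrays, subject_id=fibers.subject_id)
        else:
            warp = identity_transform()
        fiber_sets.append(fibers)
        labels.append(lab)
        warps.append(warp)
    return GroupPhantom(
        parcellation=parc,
        centroids=centroids,
        fiber_sets=fiber_sets,
        labels=labels,
        warps=warps,
        params=dict(
            S=S,
            warp_magnitude=warp_magnitude,
            seed=seed,
            grid=grid,
            L=L,
            K=K,
            n_per_bundle=n_per_bundle,
            point_noise=point_noise,
            terminal_jitter=terminal_jitter,
            m=m,
            roi_radius=roi_radius,
        ),
    )
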