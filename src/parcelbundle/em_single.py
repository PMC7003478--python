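"""Single-subject EM bundling.

Fibers of a whole brain are modeled as a mixture of gray-matter-constrained
bundle models, one per ROI pair, with unit mixture proportions.  The only
free parameters are the bundle centroids; sigma_bundle and sigma_ROI are
fixed inputs.  The E-step computes fiber-to-bundle memberships (normalized
exponentials of the joint log-likelihood, with a 3*sigma_ROI terminal gate
sparsifying the computation); the M-step updates each centroid as the
membership-weighted mean of its orientation-normalized member fibers.
Iteration stops when the number of hard-assignment changes drops to the
change threshold or the iteration cap is hit (defaults 20 and 10).

Modes:

- ``constrained``     the full model (shape x terminal likelihood, gated)
- ``clustering_only`` shape likelihood only (no terminal factor, no gate)
- ``roi_only``        closest-ROI-pair labeling, no EM iterations
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bundle_model import BundleKey, BundleModel, canonical_key
from .fiber_core import FiberSet
from .parcellation import DistanceField, Parcellation, build_distance_fields

__all__ = [
    "EMConfig",
    "MembershipMatrix",
    "EMResult",
    "initialize_model",
    "e_step",
    "m_step",
    "run_em",
]

_MODES = ("constrained", "clustering_only", "roi_only")
_MASS_FLOOR = 1e-12


@dataclass
class EMConfig:
    """Parameters of the bundling run (lengths in voxels of the label grid).

    sigma_roi / sigma_bundle: terminal and shape Gaussian scales.
    m: resample point count per fiber.
    change_threshold / max_iterations: convergence controls (20 / 10).
    gate_multiplier: memberships are zeroed (and never evaluated) for
        bundles where no terminal pairing keeps both distances within
        gate_multiplier * sigma_roi.  ``inf`` disables gating.
    m_step_assignment: 'soft' uses memberships in the centroid update,
        'hard' uses the argmax assignment only.
    """

    sigma_roi: float = 2.0
    sigma_bundle: float = 2.0
    m: int = 20
    max_iterations: int = 10
    change_threshold: int = 20
    mode: str = "constrained"
    gate_multiplier: float = 3.0
    m_step_assignment: str = "soft"
    seed: int = 0

    def __post_init__(self):
        if self.sigma_roi <= 0 or self.sigma_bundle <= 0:
            raise ValueError("sigma values must be > 0")
        if self.m < 2:
            raise ValueError("m must be >= 2")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}, got {self.mode!r}")
        if self.m_step_assignment not in ("soft", "hard"):
            raise ValueError("m_step_assignment must be 'soft' or 'hard'")


@dataclass
class MembershipMatrix:
    """Fiber x bundle responsibilities with explicit gating.

    ``values[j, k]`` is the membership of fiber j in bundle ``keys[k]``;
    each non-gated row sums to 1.  ``gated`` marks entries zeroed by the
    terminal gate; a fiber gated from every bundle is ``unassigned``.
    ``orientations[j, k]`` is True when fiber j is point-reversed relative
    to centroid k; ``log_liks`` holds the joint log-likelihoods (-inf where
    gated) and ``log_evidence`` the per-fiber logsumexp over bundles.
    """

    keys: list[BundleKey]
    values: np.ndarray
    orientations: np.ndarray
    log_liks: np.ndarray
    gated: np.ndarray
    unassigned: np.ndarray
    log_evidence: np.ndarray

    @property
    def n_fibers(self) -> int:
        return self.values.shape[0]

    def hard_assignment(self) -> list[BundleKey | None]:
        """Argmax bundle per fiber; ties go to the smaller canonical key."""
        out: list[BundleKey | None] = []
        idx = np.argmax(self.values, axis=1)  # keys sorted -> first max wins
        for j in range(self.n_fibers):
            out.append(None if self.unassigned[j] else self.keys[idx[j]])
        return out

    def total_log_likelihood(self) -> float:
        """Mixture log-likelihood (sum of per-fiber log evidences)."""
        return float(self.log_evidence[~self.unassigned].sum())

    def q_objective(self) -> float:
        """Expected complete-data log-likelihood at the current memberships."""
        with np.errstate(invalid="ignore"):
            terms = np.where(self.values > 0, self.values * self.log_liks, 0.0)
        return float(terms.sum())


def _resampled_array(fibers: FiberSet, m: int) -> np.ndarray:
    counts = {f.n_points for f in fibers.fibers}
    if counts == {m}:
        return fibers.to_array()
    return fibers.resampled(m).to_array()


def _endpoint_phi(X: np.ndarray, dist: DistanceField) -> np.ndarray:
    """phi for every label at both stored terminals: (J, 2, L)."""
    J = len(X)
    phi = np.empty((J, 2, dist.L))
    phi[:, 0, :] = dist.query_all(X[:, 0, :])
    phi[:, 1, :] = dist.query_all(X[:, -1, :])
    return phi


def _log_lik_matrix(
    X: np.ndarray,
    phi: np.ndarray,
    keys: list[BundleKey],
    centroids: np.ndarray,
    cfg: EMConfig,
):
    """Joint log-likelihoods, orientations and gate mask for all fibers/bundles.

    Returns (ll (J,K) with -inf at gated entries, orient (J,K) bool,
    gated (J,K) bool).
    """
    J, m = X.shape[0], X.shape[1]
    K = len(keys)
    ll = np.empty((J, K))
    orient = np.zeros((J, K), dtype=bool)
    gated = np.zeros((J, K), dtype=bool)
    sb2 = cfg.sigma_bundle**2
    sr2 = cfg.sigma_roi**2
    const_shape = -1.5 * m * np.log(2.0 * np.pi * sb2)
    const_term = -3.0 * np.log(2.0 * np.pi * sr2)
    Xrev = X[:, ::-1, :]
    gate = cfg.gate_multiplier * cfg.sigma_roi
    for k, (l1, l2) in enumerate(keys):
        mu = centroids[k]
        ssq_f = ((X - mu) ** 2).sum(axis=(1, 2))
        ssq_r = ((Xrev - mu) ** 2).sum(axis=(1, 2))
        rev = ssq_r < ssq_f
        ssq = np.where(rev, ssq_r, ssq_f)
        orient[:, k] = rev
        shape_ll = const_shape - ssq / (2.0 * sb2)
        if cfg.mode == "clustering_only":
            ll[:, k] = shape_ll
            continue
        p_a1, p_a2 = phi[:, 0, l1 - 1], phi[:, 1, l2 - 1]
        p_b1, p_b2 = phi[:, 0, l2 - 1], phi[:, 1, l1 - 1]
        pair_sq = np.minimum(p_a1**2 + p_a2**2, p_b1**2 + p_b2**2)
        ll[:, k] = shape_ll + const_term - pair_sq / (2.0 * sr2)
        if np.isfinite(gate):
            ok = ((p_a1 <= gate) & (p_a2 <= gate)) | ((p_b1 <= gate) & (p_b2 <= gate))
            gated[:, k] = ~ok
    ll[gated] = -np.inf
    return ll, orient, gated


def memberships_from_log_liks(
    keys: list[BundleKey], ll: np.ndarray, orient: np.ndarray, gated: np.ndarray
) -> MembershipMatrix:
    """Normalize joint log-likelihoods into responsibilities (log-sum-exp)."""
    finite_any = np.isfinite(ll).any(axis=1)
    values = np.zeros_like(ll)
    log_ev = np.full(len(ll), -np.inf)
    rows = np.where(finite_any)[0]
    if len(rows):
        sub = ll[rows]
        mx = sub.max(axis=1, keepdims=True)
        w = np.exp(sub - mx)
        w[~np.isfinite(sub)] = 0.0
        tot = w.sum(axis=1, keepdims=True)
        values[rows] = w / tot
        log_ev[rows] = (mx[:, 0] + np.log(tot[:, 0]))
    return MembershipMatrix(
        keys=list(keys),
        values=values,
        orientations=orient,
        log_liks=ll,
        gated=gated,
        unassigned=~finite_any,
        log_evidence=log_ev,
    )


def initialize_model(
    fibers: FiberSet, parc: Parcellation | DistanceField, cfg: EMConfig
) -> tuple[BundleModel, list[BundleKey]]:
    """Closest-ROI-pair classification and per-pair mean-fiber centroids.

    Each fiber is assigned to the ROI pair its terminals are closest to;
    the winning terminal correspondence orients the fiber (first point to
    the smaller label) before the point-wise mean.
    """
    dist = parc if isinstance(parc, DistanceField) else build_distance_fields(parc)
    X = _resampled_array(fibers, cfg.m)
    if len(X) == 0:
        raise ValueError("no fibers to initialize from")
    phi = _endpoint_phi(X, dist)
    assignment: list[BundleKey] = []
    oriented: list[np.ndarray] = []
    for j in range(len(X)):
        l1 = int(np.argmin(phi[j, 0])) + 1
        l2 = int(np.argmin(phi[j, 1])) + 1
        if l1 == l2:
            if phi[j, 0, l1 - 1] > phi[j, 1, l2 - 1]:
                l1 = int(np.argsort(phi[j, 0], kind="stable")[1]) + 1
            else:
                l2 = int(np.argsort(phi[j, 1], kind="stable")[1]) + 1
        key = canonical_key(l1, l2)
        # winning terminal pairing orients the fiber: first point <-> key[0]
        direct = phi[j, 0, key[0] - 1] ** 2 + phi[j, 1, key[1] - 1] ** 2
        swapped = phi[j, 0, key[1] - 1] ** 2 + phi[j, 1, key[0] - 1] ** 2
        pts = X[j] if direct <= swapped else X[j, ::-1]
        assignment.append(key)
        oriented.append(pts)
    centroids: dict[BundleKey, np.ndarray] = {}
    sums: dict[BundleKey, tuple[np.ndarray, int]] = {}
    for key, pts in zip(assignment, oriented):
        if key in sums:
            acc, n = sums[key]
            sums[key] = (acc + pts, n + 1)
        else:
            sums[key] = (pts.copy(), 1)
    for key, (acc, n) in sums.items():
        centroids[key] = acc / n
    model = BundleModel(centroids, sigma_bundle=cfg.sigma_bundle, sigma_roi=cfg.sigma_roi)
    return model, assignment


def e_step(
    fibers: FiberSet | np.ndarray,
    model: BundleModel,
    dist: DistanceField,
    cfg: EMConfig,
    phi: np.ndarray | None = None,
) -> MembershipMatrix:
    """Responsibilities of every fiber over the model's bundles."""
    if len(model) == 0:
        raise ValueError("cannot run an E-step with an empty model")
    X = fibers if isinstance(fibers, np.ndarray) else _resampled_array(fibers, cfg.m)
    if phi is None:
        phi = _endpoint_phi(X, dist)
    keys = model.keys()
    centroids = np.array([model.centroids[k] for k in keys])
    ll, orient, gated = _log_lik_matrix(X, phi, keys, centroids, cfg)
    return memberships_from_log_liks(keys, ll, orient, gated)


def m_step(
    fibers: FiberSet | np.ndarray, memberships: MembershipMatrix, cfg: EMConfig
) -> dict[BundleKey, np.ndarray]:
    """Membership-weighted mean of orientation-normalized fibers per bundle."""
    X = fibers if isinstance(fibers, np.ndarray) else _resampled_array(fibers, cfg.m)
    w = memberships.values
    if cfg.m_step_assignment == "hard":
        hard = np.zeros_like(w)
        idx = np.argmax(w, axis=1)
        rows = np.where(~memberships.unassigned)[0]
        hard[rows, idx[rows]] = 1.0
        w = hard
    Xrev = X[:, ::-1, :]
    centroids: dict[BundleKey, np.ndarray] = {}
    for k, key in enumerate(memberships.keys):
        wk = w[:, k]
        mass = wk.sum()
        if mass < _MASS_FLOOR:
            continue
        Xo = np.where(memberships.orientations[:, k][:, None, None], Xrev, X)
        centroids[key] = np.tensordot(wk, Xo, axes=1) / mass
    return centroids


@dataclass
class EMResult:
    """Output of a single-subject bundling run."""

    model: BundleModel
    assignment: list[BundleKey | None]
    memberships: MembershipMatrix
    trace: list[dict]
    fibers: np.ndarray  # resampled (J, m, 3)
    config: EMConfig
    initial_assignment: list[BundleKey]

    @property
    def n_unassigned(self) -> int:
        return int(self.memberships.unassigned.sum())

    @property
    def n_iterations(self) -> int:
        return len(self.trace)


def _count_changes(a, b) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def run_em(fibers: FiberSet, parc: Parcellation | DistanceField, cfg: EMConfig) -> EMResult:
    """Alternate E and M steps from the closest-ROI-pair initialization.

    The hard assignment (argmax membership) drives convergence counting;
    the centroid update uses soft memberships unless cfg.m_step_assignment
    is 'hard'.  In 'roi_only' mode the initialization is the answer.
    """
    dist = parc if isinstance(parc, DistanceField) else build_distance_fields(parc)
    X = _resampled_array(fibers, cfg.m)
    model, init_assignment = initialize_model(fibers, dist, cfg)
    phi = _endpoint_phi(X, dist)

    if cfg.mode == "roi_only":
        keys = model.keys()
        kidx = {k: i for i, k in enumerate(keys)}
        values = np.zeros((len(X), len(keys)))
        orient = np.zeros_like(values, dtype=bool)
        for j, key in enumerate(init_assignment):
            values[j, kidx[key]] = 1.0
        memb = MembershipMatrix(
            keys=keys,
            values=values,
            orientations=orient,
            log_liks=np.log(np.maximum(values, 1e-300)),
            gated=np.zeros_like(values, dtype=bool),
            unassigned=np.zeros(len(X), dtype=bool),
            log_evidence=np.zeros(len(X)),
        )
        return EMResult(model, list(init_assignment), memb, [], X, cfg, init_assignment)

    assignment_prev: list[BundleKey | None] = list(init_assignment)
    trace: list[dict] = []
    memb = None
    for it in range(1, cfg.max_iterations + 1):
        memb = e_step(X, model, dist, cfg, phi=phi)
        assignment = memb.hard_assignment()
        changes = _count_changes(assignment, assignment_prev)
        trace.append(
            {
                "iteration": it,
                "changes": changes,
                "log_likelihood": memb.total_log_likelihood(),
                "q_objective": memb.q_objective(),
                "n_unassigned": int(memb.unassigned.sum()),
                "n_bundles": len(memb.keys),
            }
        )
        new_centroids = m_step(X, memb, cfg)
        if not new_centroids:
            raise ValueError("all bundles lost their membership mass")
        model = BundleModel(new_centroids, sigma_bundle=cfg.sigma_bundle, sigma_roi=cfg.sigma_roi)
        assignment_prev = assignment
        if changes <= cfg.change_threshold:
            break
    # refresh memberships against the final centroids so outputs are
    # self-consistent (assignment, memberships and model match)
    memb = e_step(X, model, dist, cfg, phi=phi)
    assignment = memb.hard_assignment()
    return EMResult(model, assignment, memb, trace, X, cfg, init_assignment)
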