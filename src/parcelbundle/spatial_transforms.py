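"""Rigid and thin-plate-spline (TPS) transforms for groupwise alignment.

The rigid fit is weighted orthogonal Procrustes with translation.  The TPS
uses the standard 3-D biharmonic kernel U(r) = r; fitting solves the usual
augmented linear system with an optional smoothing term lambda (lambda = 0
interpolates the control correspondences exactly, lambda -> inf degenerates
to the weighted least-squares affine fit).  Per-point weights let strong
bundles dominate the alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RigidTransform",
    "TPSTransform",
    "identity_transform",
    "fit_rigid",
    "fit_tps",
    "warp_points",
]


@dataclass
class RigidTransform:
    """x -> R x + t with R a proper rotation."""

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        if R.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8) or np.linalg.det(R) < 0:
            raise ValueError("rotation must be orthonormal with determinant +1")
        self.rotation = R
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def to_dict(self) -> dict:
        return {
            "type": "rigid",
            "rotation": self.rotation.tolist(),
            "translation": self.translation.tolist(),
        }


@dataclass
class TPSTransform:
    """3-D thin-plate spline: x -> A^T [1, x] + sum_i w_i U(|x - c_i|)."""

    control_points: np.ndarray
    coefficients: np.ndarray  # (n, 3) kernel weights
    affine: np.ndarray  # (4, 3): row 0 translation, rows 1..3 linear part
    lam: float = 0.0

    def __post_init__(self):
        self.control_points = np.asarray(self.control_points, dtype=float)
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        r = np.linalg.norm(pts[:, None, :] - self.control_points[None, :, :], axis=2)
        out = r @ self.coefficients  # U(r) = r
        out += self.affine[0] + pts @ self.affine[1:]
        return out if np.asarray(points).ndim == 2 else out[0]

    def bending_energy(self) -> float:
        r = np.linalg.norm(
            self.control_points[:, None, :] - self.control_points[None, :, :], axis=2
        )
        return float(np.trace(self.coefficients.T @ r @ self.coefficients))

    def to_dict(self) -> dict:
        return {
            "type": "tps",
            "control_points": self.control_points.tolist(),
            "coefficients": self.coefficients.tolist(),
            "affine": self.affine.tolist(),
            "lam": self.lam,
        }


def identity_transform() -> RigidTransform:
    return RigidTransform()


def transform_from_dict(d: dict):
    if d["type"] == "rigid":
        return RigidTransform(np.array(d["rotation"]), np.array(d["translation"]))
    if d["type"] == "tps":
        return TPSTransform(
            np.array(d["control_points"]),
            np.array(d["coefficients"]),
            np.array(d["affine"]),
            float(d.get("lam", 0.0)),
        )
    raise ValueError(f"unknown transform type {d.get('type')!r}")


def fit_rigid(source: np.ndarray, target: np.ndarray, weights=None) -> RigidTransform:
    """Weighted least-squares rigid alignment (Kabsch with translation)."""
    src = np.asarray(source, dtype=float)
    tgt = np.asarray(target, dtype=float)
    if src.shape != tgt.shape or src.ndim != 2 or src.shape[1] != 3:
        raise ValueError("source/target must be matching (n, 3) arrays")
    if len(src) < 3:
        raise ValueError("need >= 3 point pairs for a rigid fit")
    w = np.ones(len(src)) if weights is None else np.asarray(weights, dtype=float)
    w = w / w.sum()
    cs = w @ src
    ct = w @ tgt
    H = (src - cs).T @ ((tgt - ct) * w[:, None])
    if np.linalg.matrix_rank(H) < 2:
        raise ValueError("degenerate geometry: source points are (near) collinear")
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = ct - R @ cs
    return RigidTransform(R, t)


def fit_tps(
    source: np.ndarray,
    target: np.ndarray,
    lam: float = 0.0,
    weights=None,
) -> TPSTransform:
    """Fit a 3-D TPS mapping source control points to targets.

    Minimizes the weighted sum of squared residuals plus lam times the
    bending energy.  lam = 0 interpolates; larger lam smooths toward the
    weighted least-squares affine map.  Requires >= 4 non-coplanar source
    points.
    """
    src = np.asarray(source, dtype=float)
    tgt = np.asarray(target, dtype=float)
    if src.shape != tgt.shape or src.ndim != 2 or src.shape[1] != 3:
        raise ValueError("source/target must be matching (n, 3) arrays")
    n = len(src)
    P = np.hstack([np.ones((n, 1)), src])
    if n < 4 or np.linalg.matrix_rank(P) < 4:
        raise ValueError(
            "TPS needs >= 4 non-coplanar source points; add points or "
            "increase the regularization weight lam"
        )
    if lam < 0:
        raise ValueError("lam must be >= 0")
    K = np.linalg.norm(src[:, None, :] - src[None, :, :], axis=2)
    if weights is not None:
        w = np.asarray(weights, dtype=float)
        if np.any(w < 0):
            raise ValueError("weights must be >= 0")
        wbar = w[w > 0].mean() if np.any(w > 0) else 1.0
        smooth = lam * np.diag(wbar / np.maximum(w, 1e-12 * wbar))
    else:
        smooth = lam * np.eye(n)
    A = np.zeros((n + 4, n + 4))
    A[:n, :n] = K + smooth
    A[:n, n:] = P
    A[n:, :n] = P.T
    b = np.zeros((n + 4, 3))
    b[:n] = tgt
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    return TPSTransform(src, sol[:n], sol[n:], lam)


def warp_points(transform, points: np.ndarray) -> np.ndarray:
    """Apply a fitted rigid or TPS transform; preserves count and order."""
    return transform.apply(points)
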