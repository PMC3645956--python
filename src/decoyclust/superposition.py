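"""Optimal rigid superposition and coordinate RMSD.

The cRMSD between two equal-length point sets is the per-atom RMSD after
the proper rigid motion (rotation + translation) that minimizes it. It can
be obtained without constructing the rotation: with both sets centered,
form the 3x3 cross-covariance matrix M, take the three singular values
lambda_1 >= lambda_2 >= lambda_3 of M, and let S = sign(det M). Then

    cRMSD^2 = Rg_A^2 + Rg_B^2 - 2 (lambda_1 + lambda_2 + S lambda_3)

where Rg is the radius of gyration about the centroid. S = -1 encodes the
reflection correction: when the best unconstrained orthogonal map is
improper, the best proper rotation flips the smallest singular direction.

The singular values are computed as square roots of the eigenvalues of
M^T M, obtained from the characteristic cubic in closed (trigonometric)
form, which is cheaper than a full SVD; an SVD fallback covers the rare
near-degenerate discriminants where the closed form is ill-conditioned.

Normalization convention: M = (1/N) sum (a_i - abar)(b_i - bbar)^T and
Rg^2 = (1/N) sum |a_i - abar|^2, so the identity holds per atom exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .models import InputError

__all__ = [
    "CovarianceDecomposition",
    "RigidTransform",
    "covariance_decomposition",
    "crmsd",
    "kabsch_rotation",
]


@dataclass(frozen=True)
class CovarianceDecomposition:
    """Cross-covariance matrix of two centered coordinate sets and its parts.

    Attributes
    ----------
    M : (3, 3) array
        Per-atom-normalized cross-covariance.
    lambdas : (3,) array
        Singular values of ``M``, descending, all >= 0.
    S : int
        +1, or -1 when ``det(M) < 0`` (mirror-related sets).
    Rg_A, Rg_B : float
        Radii of gyration of each set about its own centroid, Angstroms.
    """

    M: np.ndarray
    lambdas: np.ndarray
    S: int
    Rg_A: float
    Rg_B: float


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid motion ``x -> rotation @ x + translation``."""

    rotation: np.ndarray
    translation: np.ndarray

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation


def _as_coords(X, name: str) -> np.ndarray:
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] != 3:
        raise InputError(f"{name}: expected (n, 3) coordinates, got {X.shape}")
    if not np.all(np.isfinite(X)):
        raise InputError(f"{name}: non-finite coordinates")
    return X


def _check_pair(A, B, min_atoms: int = 3) -> tuple[np.ndarray, np.ndarray]:
    A = _as_coords(A, "A")
    B = _as_coords(B, "B")
    if len(A) != len(B):
        raise InputError(f"length mismatch: {len(A)} vs {len(B)} atoms")
    if len(A) < min_atoms:
        raise InputError(f"need at least {min_atoms} atoms, got {len(A)}")
    return A, B


def _singular_values_descending(M: np.ndarray) -> np.ndarray:
    """Singular values of the 3x3 covariance by the trigonometric cubic.

    Solves the characteristic cubic of K = M^T M in closed form. Near a
    degenerate discriminant — a (near-)repeated root, where the closed
    form loses several digits — it falls back to a direct SVD of M.
    """
    K = M.T @ M
    q = np.trace(K) / 3.0
    Kq = K - q * np.eye(3)
    p2 = np.sum(Kq * Kq) / 6.0
    scale = max(np.sum(K * K), 1.0)
    if p2 < 1e-12 * scale:
        # near-triple eigenvalue (isotropic covariance)
        return np.linalg.svd(M, compute_uv=False)
    p = np.sqrt(p2)
    r = np.linalg.det(Kq / p) / 2.0
    if 1.0 - abs(r) < 1e-9:
        # near-double eigenvalue: arccos is ill-conditioned here
        return np.linalg.svd(M, compute_uv=False)
    phi = np.arccos(r) / 3.0
    e1 = q + 2.0 * p * np.cos(phi)
    e3 = q + 2.0 * p * np.cos(phi + 2.0 * np.pi / 3.0)
    e2 = 3.0 * q - e1 - e3
    return np.sqrt(np.maximum(np.array([e1, e2, e3]), 0.0))


def covariance_decomposition(A, B) -> CovarianceDecomposition:
    """Centered cross-covariance of two paired coordinate sets.

    ``lambdas`` are the square roots of the (clamped) eigenvalues of
    ``M.T @ M`` — i.e. the singular values of ``M`` — sorted descending.
    """
    A, B = _check_pair(A, B)
    n = len(A)
    Ac = A - A.mean(axis=0)
    Bc = B - B.mean(axis=0)
    M = (Ac.T @ Bc) / n
    lambdas = _singular_values_descending(M)
    S = -1 if np.linalg.det(M) < 0.0 else 1
    Rg_A = float(np.sqrt(np.sum(Ac * Ac) / n))
    Rg_B = float(np.sqrt(np.sum(Bc * Bc) / n))
    return CovarianceDecomposition(M=M, lambdas=lambdas, S=S, Rg_A=Rg_A, Rg_B=Rg_B)


def crmsd(A, B) -> float:
    """Minimum RMSD over proper rigid motions, by the closed form.

    No rotation matrix is constructed. The radicand is clamped at zero:
    round-off can drive it to ~-1e-16 for identical sets.
    """
    dec = covariance_decomposition(A, B)
    lam = dec.lambdas
    radicand = dec.Rg_A**2 + dec.Rg_B**2 - 2.0 * (lam[0] + lam[1] + dec.S * lam[2])
    return float(np.sqrt(max(radicand, 0.0)))


def kabsch_rotation(A, B) -> RigidTransform:
    """Proper rotation + translation mapping B onto A with minimal RMSD.

    Uses the SVD construction: H = Bc^T Ac, H = U diag(s) V^T, and
    R = V diag(1, 1, d) U^T with d = sign(det(V U^T)) — the column of the
    smallest singular value is flipped when the unconstrained optimum is a
    reflection, which also fixes degenerate (collinear/coincident) sets
    deterministically through numpy's SVD sign convention.
    """
    A, B = _check_pair(A, B)
    a_mean = A.mean(axis=0)
    b_mean = B.mean(axis=0)
    H = (B - b_mean).T @ (A - a_mean)
    U, s, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    if d == 0.0:  # fully degenerate covariance; pick the proper branch
        d = 1.0
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = a_mean - R @ b_mean
    return RigidTransform(rotation=R, translation=t)


def rmsd_after(transform: RigidTransform, A, B) -> float:
    """Plain per-atom RMSD of ``transform(B)`` against ``A`` (no re-fit)."""
    A, B = _check_pair(A, B, min_atoms=1)
    diff = A - transform.apply(B)
    return float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))
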