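"""Deterministic synthetic decoy ensembles with planted cluster structure.

Real decoy sets (e.g. the 6256-conformer molecular-dynamics ensemble of
the 36-residue villin headpiece subdomain) group into clusters by
trajectory of origin, with within-cluster cRMSD well below the spread
between trajectories. The generator emulates exactly that geometry:

* a base Calpha trace (ideal alpha-helix, extended strand, or fixed-step
  random walk);
* one *seed* conformation per planted cluster, made by rotating the chain
  about an internal hinge — a smooth deformation that survives optimal
  superposition (a pure translation would not: superposition removes it);
  the hinge angle is calibrated by bisection so each seed sits at a
  prescribed cRMSD from the base;
* cluster members = seed + isotropic Gaussian coordinate noise.

Everything is a pure function of (recipe, seed): the same inputs give a
bit-identical ensemble.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .models import Ensemble, InputError, StructureModel
from .superposition import crmsd

__all__ = [
    "DecoyRecipe",
    "make_base_structure",
    "make_decoy_ensemble",
    "mirror_structure",
]

CA_STEP = 3.8  # consecutive Calpha-Calpha distance, Angstroms


@dataclass(frozen=True)
class DecoyRecipe:
    """Recipe for a planted-cluster decoy ensemble.

    ``between_offset`` is the target cRMSD (A) of each cluster seed from
    the base structure; ``within_noise_sd`` the per-coordinate Gaussian
    noise inside a cluster. Ensembles with
    ``between_offset / within_noise_sd >= 5`` are cleanly separable and
    are what the clustering tests rely on.
    """

    n_residues: int = 36
    per_cluster_sizes: tuple = (20, 20, 20)
    within_noise_sd: float = 0.3
    between_offset: float = 6.0
    base_kind: str = "helix"
    seed: int = 0

    @property
    def n_clusters(self) -> int:
        return len(self.per_cluster_sizes)

    @property
    def n_models(self) -> int:
        return int(sum(self.per_cluster_sizes))


def make_base_structure(n: int, kind: str = "helix",
                        seed: int = 0) -> StructureModel:
    """An idealized n-residue Calpha trace.

    ``helix`` uses ideal alpha-helix geometry (2.3 A radius, 1.5 A rise,
    ~100 deg twist per residue); ``extended`` a 3.8 A zig-zag strand;
    ``random_walk`` fixed 3.8 A steps in seeded random directions.
    """
    if n < 4:
        raise InputError(f"need at least 4 residues, got {n}")
    i = np.arange(n)
    if kind == "helix":
        theta = np.deg2rad(100.0) * i
        coords = np.column_stack([2.3 * np.cos(theta), 2.3 * np.sin(theta),
                                  1.5 * i])
    elif kind == "extended":
        dx = np.sqrt(CA_STEP**2 - 1.0)
        coords = np.column_stack([dx * i, 0.5 * (-1.0) ** i, np.zeros(n)])
    elif kind == "random_walk":
        rng = np.random.default_rng(seed)
        steps = rng.normal(size=(n - 1, 3))
        steps *= CA_STEP / np.linalg.norm(steps, axis=1, keepdims=True)
        coords = np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])
    else:
        raise InputError(f"unknown base kind {kind!r}")
    return StructureModel(model_id=f"synthetic:{kind}:{n}:{seed}", coords=coords)


def _hinge_deform(coords: np.ndarray, hinge: int, axis: np.ndarray,
                  angle: float) -> np.ndarray:
    """Rotate residues hinge..end about an axis through residue ``hinge``."""
    out = coords.copy()
    rot = Rotation.from_rotvec(angle * axis).as_matrix()
    pivot = coords[hinge]
    out[hinge:] = (coords[hinge:] - pivot) @ rot.T + pivot
    return out


def _calibrated_hinge_seed(base: np.ndarray, hinge: int, axis: np.ndarray,
                           target_crmsd: float, n_iter: int = 60) -> np.ndarray:
    """Bisection on the hinge angle so the deformed copy sits at
    ``target_crmsd`` from the base (clamped at the half-turn maximum)."""
    if crmsd(base, _hinge_deform(base, hinge, axis, np.pi)) <= target_crmsd:
        return _hinge_deform(base, hinge, axis, np.pi)
    lo, hi = 0.0, np.pi
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        if crmsd(base, _hinge_deform(base, hinge, axis, mid)) < target_crmsd:
            lo = mid
        else:
            hi = mid
    return _hinge_deform(base, hinge, axis, hi)


def make_decoy_ensemble(recipe: DecoyRecipe) -> tuple[Ensemble, np.ndarray]:
    """Generate a planted-cluster ensemble and its ground-truth labels."""
    if recipe.n_clusters < 1 or any(s < 1 for s in recipe.per_cluster_sizes):
        raise InputError("recipe needs at least one non-empty cluster")
    base = make_base_structure(recipe.n_residues, recipe.base_kind, recipe.seed)
    rng = np.random.default_rng(recipe.seed)
    n = recipe.n_residues
    # hinge points staggered around the middle, one rotation axis per cluster
    models = []
    labels = []
    for c, size in enumerate(recipe.per_cluster_sizes):
        hinge = n // 3 + (c * n // (3 * max(recipe.n_clusters - 1, 1))
                          if recipe.n_clusters > 1 else 0)
        hinge = min(max(hinge, 1), n - 2)
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        seed_coords = _calibrated_hinge_seed(base.coords, hinge, axis,
                                             recipe.between_offset)
        for m in range(size):
            noise = rng.normal(scale=recipe.within_noise_sd,
                               size=seed_coords.shape) if recipe.within_noise_sd > 0 \
                else np.zeros_like(seed_coords)
            models.append(StructureModel(
                model_id=f"synthetic:cluster{c}:member{m}",
                coords=seed_coords + noise,
                residue_numbers=base.residue_numbers))
            labels.append(c)
    return Ensemble(models=tuple(models)), np.asarray(labels, dtype=np.int64)


def mirror_structure(model: StructureModel) -> StructureModel:
    """Reflection through the yz-plane (x -> -x).

    Preserves all internal distances (so dRMSD to the original is 0) but
    flips chirality, which cRMSD detects.
    """
    coords = model.coords.copy()
    coords[:, 0] *= -1.0
    return StructureModel(model_id=f"{model.model_id}|mirror", coords=coords,
                          residue_numbers=model.residue_numbers)
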