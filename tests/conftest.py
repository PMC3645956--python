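import itertools

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import decoyclust as dc


@pytest.fixture
def rng():
    return np.random.default_rng(20130222)


@pytest.fixture
def helix36():
    return dc.make_base_structure(36, "helix")


@pytest.fixture
def chiral_coords(rng):
    """A decidedly chiral point set (random walk, no mirror symmetry)."""
    return dc.make_base_structure(20, "random_walk", seed=3).coords


def random_pair(rng, n=None, noise=1.0, reflect=False):
    """A seeded random coordinate pair of equal length."""
    n = int(rng.integers(4, 120)) if n is None else n
    A = rng.normal(size=(n, 3)) * 3.0
    B = A + rng.normal(size=(n, 3)) * noise
    if reflect:
        B = B * np.array([-1.0, 1.0, 1.0])
    return A, B


def oracle_crmsd(A, B):
    """Independent minimum-RMSD oracle via scipy's Wahba solver.

    Rotation.align_vectors solves for the best *proper* rotation, which
    is exactly the reflection-corrected Kabsch optimum; kept independent
    of the package's closed-form eigenvalue path.
    """
    A = np.asarray(A, float)
    B = np.asarray(B, float)
    Ac = A - A.mean(axis=0)
    Bc = B - B.mean(axis=0)
    rot, _ = Rotation.align_vectors(Ac, Bc)
    diff = Ac - rot.apply(Bc)
    return float(np.sqrt((diff**2).sum() / len(A)))


def random_rigid(rng):
    R = Rotation.random(random_state=int(rng.integers(2**31))).as_matrix()
    t = rng.normal(size=3) * 10.0
    return R, t


@pytest.fixture
def separable_recipe():
    return dc.DecoyRecipe(n_residues=36, per_cluster_sizes=(20, 20, 20),
                          within_noise_sd=0.3, between_offset=6.0, seed=7)


@pytest.fixture
def half_matched_pair():
    """8-atom pair whose last four atoms are displaced ~1000 A in mutually
    inconsistent directions: no rigid motion can fit more than 4 pairs
    within 8 A (verifiable by exhaustive subset superposition)."""
    A = dc.make_base_structure(8, "extended").coords
    B = A.copy()
    B[4:] += np.array([[1000.0, 0, 0], [0, 1000.0, 0],
                       [0, 0, 1000.0], [700.0, 700.0, 700.0]])
    return A, B


def exhaustive_best_fit_count(A, B, cutoff, sizes=(3, 4, 5, 6)):
    """Best atoms-within-cutoff count over every subset superposition."""
    n = len(A)
    best = 0
    for size in sizes:
        for sub in itertools.combinations(range(n), size):
            sub = list(sub)
            t = dc.kabsch_rotation(A[sub], B[sub])
            d = np.linalg.norm(A - t.apply(B), axis=1)
            best = max(best, int((d < cutoff).sum()))
    return best
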