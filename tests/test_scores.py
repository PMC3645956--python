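"""dRMSD, contact-map overlap, and the fragment-search scores."""

import numpy as np
import pytest

import decoyclust as dc
from decoyclust.models import InputError
from decoyclust.scores import GdtParameters

from conftest import exhaustive_best_fit_count, random_pair, random_rigid


def drmsd_loop(A, B):
    """Explicit O(N^2) double-loop oracle for dRMSD."""
    n = len(A)
    total = 0.0
    for i in range(n - 1):
        for j in range(i + 1, n):
            da = np.linalg.norm(A[i] - A[j])
            db = np.linalg.norm(B[i] - B[j])
            total += (da - db) ** 2
    return np.sqrt(2.0 * total / (n * (n - 1)))


class TestDrmsd:
    def test_identical_structures_score_zero(self, helix36):
        assert dc.drmsd(helix36, helix36) == 0.0

    def test_collinear_hand_case(self):
        A = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0]])
        B = np.array([[0.0, 0, 0], [1, 0, 0], [3, 0, 0]])
        # pair diffs 0, 1, 1 -> sqrt(2 * 2 / (3*2)) = sqrt(2/3)
        assert dc.drmsd(A, B) == pytest.approx(np.sqrt(2.0 / 3.0), abs=1e-12)

    def test_matches_double_loop_oracle(self, rng):
        for _ in range(100):
            A, B = random_pair(rng, n=int(rng.integers(4, 40)))
            assert dc.drmsd(A, B) == pytest.approx(drmsd_loop(A, B), abs=1e-10)

    def test_mirror_blind_while_crmsd_is_not(self, chiral_coords):
        M = chiral_coords * np.array([-1.0, 1.0, 1.0])
        assert dc.drmsd(chiral_coords, M) == pytest.approx(0.0, abs=1e-12)
        assert dc.crmsd(chiral_coords, M) > 0.5

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(InputError):
            dc.drmsd(rng.normal(size=(5, 3)), rng.normal(size=(6, 3)))


class TestContactMap:
    def test_pair_within_cutoff_is_a_contact(self):
        A = np.array([[0.0, 0, 0], [5.0, 0, 0]])
        cm = dc.contact_map(A, cutoff=8.0, min_separation=0)
        assert cm.contacts == frozenset({(0, 1)})

    def test_distance_exactly_at_cutoff_is_not_a_contact(self):
        A = np.array([[0.0, 0, 0], [5.0, 0, 0]])
        assert len(dc.contact_map(A, cutoff=5.0)) == 0

    def test_matches_brute_force_enumeration(self, rng):
        X = dc.make_base_structure(10, "helix").coords
        for cutoff, sep in [(8.0, 3), (6.0, 0), (10.0, 2)]:
            cm = dc.contact_map(X, cutoff=cutoff, min_separation=sep)
            expected = {
                (i, j)
                for i in range(10) for j in range(i + 1, 10)
                if j - i >= sep and np.linalg.norm(X[i] - X[j]) < cutoff
            }
            assert cm.contacts == frozenset(expected)

    def test_min_separation_excludes_near_neighbors(self, helix36):
        cm = dc.contact_map(helix36, cutoff=8.0, min_separation=3)
        assert all(j - i >= 3 for i, j in cm.contacts)


class TestCmoSorensen:
    def _map(self, n, pairs):
        return dc.ContactMap(n=n, contacts=frozenset(pairs), cutoff=8.0,
                             min_separation=0)

    def test_identical_nonempty_maps_score_100(self, helix36):
        cm = dc.contact_map(helix36)
        assert dc.cmo_sorensen(cm, cm) == 100.0

    def test_constructed_overlap_arithmetic(self):
        a_pairs = {(0, j) for j in range(1, 11)}               # |A| = 10
        shared = {(0, j) for j in range(1, 9)}                 # overlap 8
        b_pairs = shared | {(1, j) for j in range(2, 8)}       # |B| = 14
        score = dc.cmo_sorensen(self._map(20, a_pairs), self._map(20, b_pairs))
        assert score == pytest.approx(100.0 * 16.0 / 24.0, abs=1e-9)  # 66.667

    def test_disjoint_maps_score_zero(self):
        assert dc.cmo_sorensen(self._map(5, {(0, 1)}), self._map(5, {(2, 3)})) == 0.0

    def test_empty_map_conventions(self):
        empty = self._map(5, set())
        assert dc.cmo_sorensen(empty, empty) == 100.0
        assert dc.cmo_sorensen(empty, self._map(5, {(0, 1)})) == 0.0

    def test_mismatched_parameters_rejected(self):
        a = self._map(5, set())
        b = dc.ContactMap(n=5, contacts=frozenset(), cutoff=6.0, min_separation=0)
        with pytest.raises(InputError):
            dc.cmo_sorensen(a, b)


class TestD0:
    def test_villin_length(self):
        # 1.24 * 21**(1/3) - 1.8
        assert dc.d0_tm(36) == pytest.approx(1.6211, abs=1e-4)

    def test_small_n_clamped_to_floor(self):
        assert dc.d0_tm(15) == 0.5
        assert dc.d0_tm(4) == 0.5

    def test_maxsub_uses_fixed_d0(self, rng):
        A, B = random_pair(rng, n=30, noise=1.0)
        from decoyclust.scores import gdt_search
        implicit = gdt_search(A, B, measure="maxsub").value
        explicit = gdt_search(A, B, measure="tm", d0=3.5).value
        assert implicit == explicit


class TestGdtSearch:
    def test_self_comparison_identities(self, helix36):
        X = helix36.coords
        assert dc.gdt_ts(X, X) == 100.0
        assert dc.tm_score(X, X) == pytest.approx(1.0, abs=1e-12)
        assert dc.maxsub(X, X) == pytest.approx(1.0, abs=1e-12)

    def test_half_matched_chain_scores_fifty(self, half_matched_pair):
        A, B = half_matched_pair
        res = dc.gdt_search(A, B)
        assert res.value == 50.0
        assert res.gdt_counts == (4, 4, 4, 4)
        # no subset superposition beats the intact half at the widest cutoff
        assert exhaustive_best_fit_count(A, B, cutoff=8.0) == 4

    def test_per_cutoff_counts_monotone(self, rng):
        for _ in range(10):
            A, B = random_pair(rng, n=24, noise=float(rng.uniform(0.5, 4.0)))
            counts = dc.gdt_search(A, B).gdt_counts
            assert counts[0] <= counts[1] <= counts[2] <= counts[3]

    def test_beats_single_whole_chain_superposition(self, rng):
        for _ in range(5):
            A, B = random_pair(rng, n=20, noise=2.0)
            t = dc.kabsch_rotation(A, B)
            d = np.linalg.norm(A - t.apply(B), axis=1)
            whole = 100.0 * sum(
                (d < c).sum() for c in (1.0, 2.0, 4.0, 8.0)) / (4 * len(A))
            assert dc.gdt_ts(A, B) >= whole - 1e-9

    def test_invariant_under_rigid_motion(self, rng):
        A, B = random_pair(rng, n=20, noise=1.5)
        ref = {m: dc.gdt_search(A, B, measure=m).value
               for m in ("gdt_ts", "tm", "maxsub")}
        R, t = random_rigid(rng)
        B2 = B @ R.T + t
        for m, v in ref.items():
            assert dc.gdt_search(A, B2, measure=m).value == pytest.approx(v, abs=1e-6)

    def test_deterministic(self, rng):
        A, B = random_pair(rng, n=25, noise=1.0)
        assert dc.gdt_ts(A, B) == dc.gdt_ts(A, B)
        assert dc.tm_score(A, B) == dc.tm_score(A, B)

    def test_extended_search_never_scores_lower(self, rng):
        for _ in range(50):
            A, B = random_pair(rng, n=int(rng.integers(20, 60)),
                               noise=float(rng.uniform(0.5, 4.0)))
            std = dc.gdt_ts(A, B)
            ext = dc.gdt_ts(A, B, GdtParameters(extended=True))
            assert ext >= std - 1e-9

    def test_scores_within_range(self, rng):
        for _ in range(10):
            A, B = random_pair(rng, n=18, noise=float(rng.uniform(0.1, 5.0)))
            assert 0.0 <= dc.gdt_ts(A, B) <= 100.0
            assert 0.0 < dc.tm_score(A, B) <= 1.0
            assert 0.0 < dc.maxsub(A, B) <= 1.0

    def test_too_short_chain_rejected(self):
        A = np.zeros((3, 3))
        with pytest.raises(InputError):
            dc.gdt_ts(A, A)
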