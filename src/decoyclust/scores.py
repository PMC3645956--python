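"""Similarity measures between equal-length Calpha traces.

Besides cRMSD (see :mod:`.superposition`) the package scores model pairs
with:

* **dRMSD** — RMS difference of the two internal distance matrices; needs
  no superposition and cannot tell a structure from its mirror image.
* **Contact-map overlap (CMO)** — Sorensen similarity of the two binary
  contact sets, ``100 * 2|A & B| / (|A| + |B|)``.
* **GDT_TS, TM-score, MaxSub** — superposition-search scores. Exact GDT
  optimization is NP-hard; all three are computed with one shared
  fragment-seeded heuristic: every contiguous fragment of a few window
  lengths seeds a whole-chain superposition, which is then iteratively
  refined on the subset of atom pairs closer than 3.5 A. The measure is
  evaluated at every superposition visited and the maximum kept.

GDT_TS averages, over cutoffs 1/2/4/8 A, the maximal fraction of atom
pairs within each cutoff (each cutoff maximized independently), scaled to
[0, 100]. TM-score is max (1/N) sum 1/(1 + (d_i/d0)^2) with
d0 = 1.24 (N-15)^(1/3) - 1.8 A; MaxSub is the same score with d0 fixed at
3.5 A.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist

from .models import InputError, StructureModel
from .superposition import RigidTransform, kabsch_rotation

__all__ = [
    "ContactMap",
    "GdtParameters",
    "SearchScore",
    "drmsd",
    "contact_map",
    "cmo_sorensen",
    "d0_tm",
    "gdt_search",
    "gdt_ts",
    "tm_score",
    "maxsub",
]

GDT_CUTOFFS = (1.0, 2.0, 4.0, 8.0)
MAXSUB_D0 = 3.5
D0_FLOOR = 0.5


def _coords(X) -> np.ndarray:
    if isinstance(X, StructureModel):
        return X.coords
    return np.asarray(X, dtype=np.float64)


def drmsd(A, B) -> float:
    """RMS deviation of the two inter-atom distance matrices.

    sqrt( 2/(N(N-1)) * sum_{i<j} (d_ij^A - d_ij^B)^2 ); superposition-free
    and mirror-blind.
    """
    A, B = _coords(A), _coords(B)
    if len(A) != len(B):
        raise InputError(f"length mismatch: {len(A)} vs {len(B)}")
    if len(A) < 2:
        raise InputError("drmsd needs at least 2 atoms")
    diff = pdist(A) - pdist(B)
    return float(np.sqrt(np.mean(diff * diff)))


@dataclass(frozen=True)
class ContactMap:
    """Binary symmetric residue-contact set at a stated cutoff.

    ``contacts`` holds unordered index pairs (i, j) with i < j, distance
    strictly below ``cutoff`` and sequence separation |i-j| >=
    ``min_separation``.
    """

    n: int
    contacts: frozenset
    cutoff: float
    min_separation: int

    def __len__(self) -> int:
        return len(self.contacts)


def contact_map(A, cutoff: float = 8.0, min_separation: int = 0) -> ContactMap:
    """Contacts of one model: pairs strictly closer than ``cutoff``."""
    X = _coords(A)
    if cutoff <= 0:
        raise InputError(f"cutoff must be positive, got {cutoff}")
    if min_separation < 0:
        raise InputError(f"min_separation must be >= 0, got {min_separation}")
    n = len(X)
    d = np.linalg.norm(X[:, None, :] - X[None, :, :], axis=-1)
    i, j = np.triu_indices(n, k=max(min_separation, 1))
    mask = d[i, j] < cutoff
    pairs = frozenset(zip(i[mask].tolist(), j[mask].tolist()))
    return ContactMap(n=n, contacts=pairs, cutoff=float(cutoff),
                      min_separation=int(min_separation))


def cmo_sorensen(A: ContactMap, B: ContactMap) -> float:
    """Sorensen similarity of two contact sets, in percent.

    Two empty maps are identically empty and score 100; one empty map
    against a non-empty one scores 0 (the ratio is otherwise 0/0).
    """
    if A.n != B.n:
        raise InputError(f"contact maps over different lengths: {A.n} vs {B.n}")
    if A.cutoff != B.cutoff or A.min_separation != B.min_separation:
        raise InputError("contact maps built with different parameters")
    total = len(A) + len(B)
    if total == 0:
        return 100.0
    return 100.0 * 2.0 * len(A.contacts & B.contacts) / total


def d0_tm(n: int) -> float:
    """TM-score distance scale d0 = 1.24 (N-15)^(1/3) - 1.8 A.

    The formula goes non-positive for N <= 17; the result is floored at
    0.5 A since the score needs a positive scale.
    """
    if n < 1:
        raise InputError(f"residue count must be >= 1, got {n}")
    d0 = 1.24 * np.cbrt(n - 15.0) - 1.8
    return float(max(d0, D0_FLOOR))


def _powers_of_two_below(n: int, start: int = 8):
    k = start
    while k < n:
        yield k
        k *= 2


@dataclass(frozen=True)
class GdtParameters:
    """Knobs of the shared fragment-search heuristic.

    ``fragment_lengths`` defaults to {4, N/4, N/2, N}; ``extended`` adds
    powers of two (8, 16, 32, ...) below N for a denser, more exact search.
    """

    cutoffs: tuple = GDT_CUTOFFS
    refine_cutoff: float = 3.5
    stability_window: int = 4
    max_iterations: int = 100
    fragment_lengths: tuple | None = None
    extended: bool = False

    def __post_init__(self) -> None:
        cuts = tuple(float(c) for c in self.cutoffs)
        if any(b <= a for a, b in zip(cuts, cuts[1:])):
            raise InputError(f"cutoffs must be strictly increasing: {cuts}")
        if self.refine_cutoff <= 0:
            raise InputError("refine_cutoff must be positive")
        object.__setattr__(self, "cutoffs", cuts)

    def seed_lengths(self, n: int) -> tuple:
        if self.fragment_lengths is not None:
            lengths = {min(int(l), n) for l in self.fragment_lengths}
        else:
            lengths = {4, n // 4, n // 2, n}
            if self.extended:
                lengths.update(_powers_of_two_below(n))
        return tuple(sorted(l for l in lengths if 4 <= l <= n))


@dataclass(frozen=True)
class SearchScore:
    """Result of the fragment-seeded search for one model pair."""

    value: float
    best_transform: RigidTransform
    seeds_tried: int
    gdt_counts: tuple = field(default=())


def _gdt_value(counts, cutoffs, n: int) -> float:
    return 100.0 * sum(counts) / (len(cutoffs) * n)


def gdt_search(A, B, params: GdtParameters | None = None,
               measure: str = "gdt_ts", d0: float | None = None) -> SearchScore:
    """Shared superposition search behind GDT_TS, TM-score and MaxSub.

    Every contiguous window of each seed length is superimposed by the
    Kabsch rotation, the whole chains are overlaid with that transform,
    and the overlay is refined: atom pairs closer than ``refine_cutoff``
    are re-superimposed until the selected count is unchanged for
    ``stability_window`` consecutive iterations (hard-capped). The
    requested measure is evaluated at every visited superposition.
    """
    A, B = _coords(A), _coords(B)
    if len(A) != len(B):
        raise InputError(f"length mismatch: {len(A)} vs {len(B)}")
    n = len(A)
    params = params or GdtParameters()
    if measure not in ("gdt_ts", "tm", "maxsub"):
        raise InputError(f"unknown search measure {measure!r}")
    lengths = params.seed_lengths(n)
    if not lengths:
        raise InputError(f"chain of {n} atoms is shorter than the smallest "
                         f"seed fragment (4)")

    cutoffs = np.asarray(params.cutoffs)
    if measure == "tm":
        d0 = d0_tm(n) if d0 is None else float(d0)
    elif measure == "maxsub":
        d0 = MAXSUB_D0 if d0 is None else float(d0)

    best_counts = np.zeros(len(cutoffs), dtype=np.int64)
    best_value = -np.inf
    best_transform: RigidTransform | None = None
    seeds_tried = 0

    def visit(transform: RigidTransform) -> np.ndarray:
        nonlocal best_value, best_transform
        d = np.linalg.norm(A - transform.apply(B), axis=1)
        if measure == "gdt_ts":
            counts = (d[:, None] < cutoffs[None, :]).sum(axis=0)
            np.maximum(best_counts, counts, out=best_counts)
            value = float(counts.sum())
        else:
            value = float(np.mean(1.0 / (1.0 + (d / d0) ** 2)))
        if value > best_value:
            best_value = value
            best_transform = transform
        return d

    for length in lengths:
        for start in range(n - length + 1):
            seeds_tried += 1
            window = slice(start, start + length)
            transform = kabsch_rotation(A[window], B[window])
            d = visit(transform)
            prev_count = -1
            stable = 0
            for _ in range(params.max_iterations):
                sel = d < params.refine_cutoff
                count = int(sel.sum())
                if count < 3:
                    break
                stable = stable + 1 if count == prev_count else 1
                if stable >= params.stability_window:
                    break
                prev_count = count
                transform = kabsch_rotation(A[sel], B[sel])
                d = visit(transform)

    if measure == "gdt_ts":
        value = _gdt_value(best_counts, cutoffs, n)
    else:
        value = best_value
    return SearchScore(value=float(value), best_transform=best_transform,
                       seeds_tried=seeds_tried,
                       gdt_counts=tuple(int(c) for c in best_counts))


def gdt_ts(A, B, params: GdtParameters | None = None) -> float:
    """Global distance test total score in [0, 100]."""
    return gdt_search(A, B, params, measure="gdt_ts").value


def tm_score(A, B, params: GdtParameters | None = None,
             d0: float | None = None) -> float:
    """TM-score in (0, 1]; d0 defaults to the length-dependent formula."""
    return gdt_search(A, B, params, measure="tm", d0=d0).value


def maxsub(A, B, params: GdtParameters | None = None) -> float:
    """MaxSub score in (0, 1]: TM-score functional form with d0 = 3.5 A."""
    return gdt_search(A, B, params, measure="maxsub").value
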