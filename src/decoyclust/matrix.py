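"""All-versus-all and versus-reference score matrices.

For N conformers the all-versus-all comparison costs exactly N(N-1)/2
pair evaluations: each unordered pair is scored once and mirrored, which
also makes the matrix symmetric by construction even for the (potentially
asymmetric) search heuristics. Work may be split across workers; results
are assembled in pair order, so the matrix is bit-identical for any
worker count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from joblib import Parallel, delayed

from .models import ConfigError, Ensemble, InputError, StructureModel
from . import scores as _scores
from . import superposition as _sup

__all__ = [
    "MEASURES",
    "SimilarityMatrix",
    "all_vs_all",
    "vs_reference",
    "filter_pairs",
    "to_distance",
]


def _pair_rmsd(a: StructureModel, b: StructureModel, params: dict) -> float:
    return _sup.crmsd(a.coords, b.coords)


def _pair_drmsd(a: StructureModel, b: StructureModel, params: dict) -> float:
    return _scores.drmsd(a, b)


def _pair_cmo(a: StructureModel, b: StructureModel, params: dict) -> float:
    cutoff = params.get("contact_cutoff", 8.0)
    min_sep = params.get("min_separation", 0)
    return _scores.cmo_sorensen(_scores.contact_map(a, cutoff, min_sep),
                                _scores.contact_map(b, cutoff, min_sep))


def _gdt_params(params: dict, extended: bool = False) -> _scores.GdtParameters:
    gp = params.get("gdt_params")
    if gp is not None:
        return gp
    return _scores.GdtParameters(extended=extended)


def _pair_gdt(a, b, params):
    return _scores.gdt_ts(a, b, _gdt_params(params))


def _pair_gdt_ext(a, b, params):
    return _scores.gdt_ts(a, b, _gdt_params(params, extended=True))


def _pair_tm(a, b, params):
    return _scores.tm_score(a, b, _gdt_params(params), d0=params.get("d0"))


def _pair_maxsub(a, b, params):
    return _scores.maxsub(a, b, _gdt_params(params))


@dataclass(frozen=True)
class Measure:
    name: str
    pair_func: callable
    diagonal_value: float
    similarity: bool  # True: larger = more similar; distance = invert


#: Registry of the supported measures, keyed by their CLI names.
MEASURES: dict[str, Measure] = {
    "rmsd": Measure("rmsd", _pair_rmsd, 0.0, similarity=False),
    "drmsd": Measure("drmsd", _pair_drmsd, 0.0, similarity=False),
    "gdt": Measure("gdt", _pair_gdt, 100.0, similarity=True),
    "gdtExt": Measure("gdtExt", _pair_gdt_ext, 100.0, similarity=True),
    "tm": Measure("tm", _pair_tm, 1.0, similarity=True),
    "maxsub": Measure("maxsub", _pair_maxsub, 1.0, similarity=True),
    "cmo": Measure("cmo", _pair_cmo, 100.0, similarity=True),
}


def get_measure(name: str) -> Measure:
    try:
        return MEASURES[name]
    except KeyError:
        raise ConfigError(
            f"unknown measure {name!r}; choose from {sorted(MEASURES)}"
        ) from None


@dataclass(frozen=True)
class SimilarityMatrix:
    """Symmetric N x N score store with the measure's self-score diagonal."""

    measure: str
    values: np.ndarray
    model_ids: tuple

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise InputError(f"matrix must be square, got {v.shape}")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "model_ids", tuple(self.model_ids))
        if len(self.model_ids) != v.shape[0]:
            raise InputError("one model id per matrix row required")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def diagonal_value(self) -> float:
        return get_measure(self.measure).diagonal_value if self.measure in MEASURES else 0.0


def all_vs_all(ensemble: Ensemble, measure: str, params: dict | None = None,
               n_workers: int = 1) -> SimilarityMatrix:
    """Score every unordered model pair once; mirror into a full matrix.

    The pair list (i < j, lexicographic) is mapped in order — serially or
    over ``n_workers`` joblib workers — so the result does not depend on
    the worker count.
    """
    m = get_measure(measure)
    params = params or {}
    n = len(ensemble)
    if n == 0:
        raise InputError("empty ensemble")
    ensemble.require_uniform_length()
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    if n_workers > 1 and len(pairs) > 1:
        vals = Parallel(n_jobs=n_workers, batch_size=max(1, len(pairs) // (4 * n_workers)))(
            delayed(m.pair_func)(ensemble[i], ensemble[j], params) for i, j in pairs
        )
    else:
        vals = [m.pair_func(ensemble[i], ensemble[j], params) for i, j in pairs]
    values = np.full((n, n), m.diagonal_value, dtype=np.float64)
    for (i, j), v in zip(pairs, vals):
        values[i, j] = v
        values[j, i] = v
    return SimilarityMatrix(measure=measure, values=values,
                            model_ids=tuple(mod.model_id for mod in ensemble))


def vs_reference(ensemble: Ensemble, reference: StructureModel, measure: str,
                 params: dict | None = None, n_workers: int = 1) -> list:
    """Score every model against one reference, in ensemble order.

    For TM-score the d0 length scale is taken from the reference length
    (the usual convention when the reference is the experimental
    structure).
    """
    m = get_measure(measure)
    params = dict(params or {})
    for mod in ensemble:
        if mod.n_atoms != reference.n_atoms:
            raise InputError(
                f"model {mod.model_id!r} has {mod.n_atoms} atoms but the "
                f"reference {reference.model_id!r} has {reference.n_atoms}"
            )
    if measure == "tm" and "d0" not in params:
        params["d0"] = _scores.d0_tm(reference.n_atoms)
    models = list(ensemble)
    if n_workers > 1 and len(models) > 1:
        vals = Parallel(n_jobs=n_workers)(
            delayed(m.pair_func)(reference, mod, params) for mod in models
        )
    else:
        vals = [m.pair_func(reference, mod, params) for mod in models]
    return [(mod.model_id, float(v)) for mod, v in zip(models, vals)]


def filter_pairs(matrix: SimilarityMatrix, threshold: float,
                 direction: str = "below") -> list:
    """Unordered pairs strictly below (or above) a score threshold.

    Mirrors post-hoc filtering of the 3-column pair output (e.g. keeping
    cRMSD pairs strictly under 3.2 A); sorted by (i, j).
    """
    if direction not in ("below", "above"):
        raise ConfigError(f"direction must be 'below' or 'above', got {direction!r}")
    if not np.isfinite(threshold):
        raise InputError("threshold must be finite")
    out = []
    v = matrix.values
    for i in range(matrix.n):
        for j in range(i + 1, matrix.n):
            s = v[i, j]
            if (s < threshold) if direction == "below" else (s > threshold):
                out.append((i, j, float(s)))
    return out


def to_distance(matrix: SimilarityMatrix) -> SimilarityMatrix:
    """Convert a score matrix to a dissimilarity matrix for clustering.

    RMSD-type measures pass through; TM/MaxSub map to 1 - score and
    GDT/CMO to 100 - score, so the diagonal becomes 0 and pair order is
    reversed for similarity measures.
    """
    m = get_measure(matrix.measure)
    if not m.similarity:
        return matrix
    values = m.diagonal_value - matrix.values
    return SimilarityMatrix(measure=f"{matrix.measure}_distance", values=values,
                            model_ids=matrix.model_ids)
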