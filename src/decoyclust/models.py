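"""Core in-memory containers for decoy ensembles.

A *decoy* is one candidate conformation of a protein, represented here by
its Calpha trace: an ordered array of 3-D coordinates in Angstroms. All
similarity measures in this package are alignment-free — they pair atom i
of one model with atom i of the other — so every pairwise operation
requires models of identical length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class InputError(ValueError):
    """Invalid input data (bad file, mismatched lengths, empty model)."""


class ConfigError(ValueError):
    """Invalid configuration (unknown measure, bad parameter combination)."""


@dataclass(frozen=True)
class StructureModel:
    """One conformer's Calpha coordinates plus identity metadata.

    Parameters
    ----------
    model_id : str
        Origin of the model, conventionally ``"<path>#<model index>"``.
    coords : (n, 3) float array
        Calpha positions in Angstroms, in record order.
    residue_numbers : (n,) int array
        Residue sequence numbers as printed in the source PDB.
    """

    model_id: str
    coords: np.ndarray
    residue_numbers: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=np.float64)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise InputError(f"coords must be (n, 3), got {coords.shape}")
        if not np.all(np.isfinite(coords)):
            raise InputError(f"non-finite coordinate in model {self.model_id!r}")
        object.__setattr__(self, "coords", coords)
        if self.residue_numbers is None:
            resnum = np.arange(1, len(coords) + 1)
        else:
            resnum = np.asarray(self.residue_numbers, dtype=np.int64)
        if resnum.shape != (len(coords),):
            raise InputError(
                f"model {self.model_id!r}: {len(resnum)} residue numbers "
                f"for {len(coords)} atoms"
            )
        object.__setattr__(self, "residue_numbers", resnum)

    @property
    def n_atoms(self) -> int:
        return len(self.coords)


@dataclass(frozen=True)
class Ensemble:
    """An ordered collection of models, typically one decoy set."""

    models: tuple[StructureModel, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "models", tuple(self.models))

    def __len__(self) -> int:
        return len(self.models)

    def __iter__(self):
        return iter(self.models)

    def __getitem__(self, i: int) -> StructureModel:
        return self.models[i]

    @property
    def uniform_length(self) -> bool:
        """True when every model has the same atom count (vacuously for <2)."""
        lengths = {m.n_atoms for m in self.models}
        return len(lengths) <= 1

    def require_uniform_length(self) -> int:
        """Return the common length, or raise naming the offending models."""
        if not self.models:
            raise InputError("empty ensemble")
        n0 = self.models[0].n_atoms
        for m in self.models[1:]:
            if m.n_atoms != n0:
                raise InputError(
                    f"length mismatch: model {self.models[0].model_id!r} has "
                    f"{n0} atoms but {m.model_id!r} has {m.n_atoms}"
                )
        return n0
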