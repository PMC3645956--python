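"""Reading and writing decoy ensembles and score reports.

Input is either a multi-model PDB file (MODEL/ENDMDL blocks; a file with
no MODEL record is one model) or a one-column list file of PDB paths
('#' comments and blank lines skipped). Comparison is on a single named
atom per residue — Calpha by default. Hetero records are ignored; when a
residue carries alternate locations, the first-encountered altloc is
kept, which is deterministic across PDB dialects.

Outputs are plain text: 3-column pair scores (ids + score, fixed to 3
decimals, so the score in column 3 can be filtered with standard line
tools), square matrices with an id header, 2-column reference scores,
and human/machine-readable cluster reports.
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

import gemmi
import numpy as np

from .models import Ensemble, InputError, StructureModel

__all__ = [
    "read_pdb_models",
    "read_list_file",
    "write_pdb_models",
    "write_pair_scores",
    "write_matrix",
    "write_reference_scores",
    "write_cluster_report",
]

SCORE_FMT = "{:.3f}"


def read_pdb_models(path, atom_name: str = "CA") -> Ensemble:
    """Read one model per MODEL/ENDMDL block, keeping ``atom_name`` atoms.

    Atoms are taken in record order; only ATOM records with a matching
    atom name contribute, one per residue (first altloc wins).
    """
    path = os.fspath(path)
    try:
        structure = gemmi.read_structure(path, format=gemmi.CoorFormat.Pdb)
    except (OSError, RuntimeError, ValueError) as exc:
        raise InputError(f"cannot read PDB file {path!r}: {exc}") from exc
    models = []
    for idx, gmodel in enumerate(structure, start=1):
        coords = []
        resnums = []
        for chain in gmodel:
            for residue in chain:
                if residue.het_flag == "H":
                    continue
                for atom in residue:
                    if atom.name == atom_name:
                        coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
                        resnums.append(residue.seqid.num)
                        break  # first-encountered altloc only
        if not coords:
            raise InputError(
                f"model {idx} of {path!r} has no {atom_name!r} atoms"
            )
        models.append(StructureModel(
            model_id=f"{path}#{idx}",
            coords=np.asarray(coords, dtype=np.float64),
            residue_numbers=np.asarray(resnums, dtype=np.int64)))
    if not models:
        raise InputError(f"no models found in {path!r}")
    return Ensemble(models=tuple(models))


def read_list_file(path, atom_name: str = "CA") -> Ensemble:
    """Concatenate the models of every PDB path listed, one per line."""
    path = os.fspath(path)
    try:
        with open(path) as fh:
            lines = fh.readlines()
    except OSError as exc:
        raise InputError(f"cannot read list file {path!r}: {exc}") from exc
    base = os.path.dirname(path)
    models: list[StructureModel] = []
    for lineno, raw in enumerate(lines, start=1):
        entry = raw.strip()
        if not entry or entry.startswith("#"):
            continue
        pdb_path = entry if os.path.isabs(entry) else os.path.join(base, entry)
        if not os.path.exists(pdb_path):
            # also honor paths relative to the current directory
            if os.path.exists(entry):
                pdb_path = entry
            else:
                raise InputError(
                    f"{path!r} line {lineno}: file {entry!r} not found"
                )
        models.extend(read_pdb_models(pdb_path, atom_name=atom_name).models)
    return Ensemble(models=tuple(models))


def write_pdb_models(ensemble: Ensemble, path, atom_name: str = "CA",
                     residue_name: str = "ALA") -> None:
    """Write an ensemble as a multi-model PDB file (one atom per residue)."""
    structure = gemmi.Structure()
    for mnum, model in enumerate(ensemble, start=1):
        gmodel = gemmi.Model(mnum)
        chain = gemmi.Chain("A")
        for xyz, resnum in zip(model.coords, model.residue_numbers):
            residue = gemmi.Residue()
            residue.name = residue_name
            residue.seqid = gemmi.SeqId(int(resnum), " ")
            residue.het_flag = "A"
            atom = gemmi.Atom()
            atom.name = atom_name
            atom.pos = gemmi.Position(*map(float, xyz))
            atom.element = gemmi.Element("C")
            residue.add_atom(atom)
            chain.add_residue(residue)
        gmodel.add_chain(chain)
        structure.add_model(gmodel)
    structure.write_pdb(os.fspath(path))


def write_pair_scores(pairs: Iterable, path, model_ids: Sequence | None = None) -> None:
    """3-column text: id-A, id-B, score (column 3, 3 decimals).

    ``pairs`` yields (i, j, score); indices are written as-is unless
    ``model_ids`` maps them to names.
    """
    with open(os.fspath(path), "w") as fh:
        for i, j, score in pairs:
            a = model_ids[i] if model_ids is not None else i
            b = model_ids[j] if model_ids is not None else j
            fh.write(f"{a} {b} {SCORE_FMT.format(score)}\n")


def write_matrix(matrix, path) -> None:
    """Square score matrix with a header row of model ids."""
    with open(os.fspath(path), "w") as fh:
        fh.write(" ".join(matrix.model_ids) + "\n")
        for row in matrix.values:
            fh.write(" ".join(SCORE_FMT.format(v) for v in row) + "\n")


def write_reference_scores(scores: Iterable, path) -> None:
    """2-column text: model id, score versus the reference."""
    with open(os.fspath(path), "w") as fh:
        for model_id, score in scores:
            fh.write(f"{model_id} {SCORE_FMT.format(score)}\n")


def write_cluster_report(result, matrix, path, representative: int | None = None) -> None:
    """Human-readable cluster report plus a CSV companion (``path + '.csv'``).

    One block per cluster: size, fraction f, mean internal distance <R>,
    selection criterion <R>/f, the cluster medoid, then the member ids.
    """
    ids = matrix.model_ids
    path = os.fspath(path)
    with open(path, "w") as fh:
        fh.write(f"# method={result.method} k={result.k} "
                 f"n_models={len(result.labels)} measure={matrix.measure}\n")
        if representative is not None:
            fh.write(f"# ensemble representative: {ids[representative]} "
                     f"(index {representative})\n")
        for st in result.per_cluster:
            fh.write(f"cluster {st.label}: size={st.size} "
                     f"f={st.fraction:.4f} <R>={st.mean_internal:.3f} "
                     f"<R>/f={st.criterion:.3f} "
                     f"representative={ids[st.representative]}\n")
            for idx in np.flatnonzero(result.labels == st.label):
                fh.write(f"  {ids[idx]}\n")
    with open(path + ".csv", "w") as fh:
        fh.write("model_index,model_id,cluster,is_representative\n")
        reps = {st.representative for st in result.per_cluster}
        for idx, lab in enumerate(result.labels):
            fh.write(f"{idx},{ids[idx]},{lab},{int(idx in reps)}\n")
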