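"""PDB structure I/O and conservation painting.

Structures are held as a thin wrapper over a biotite ``AtomArray``; parsing
and fixed-column writing go through ``biotite.structure.io.pdb``.  The module
implements the surface-mapping step of conservation analysis: per-column
alignment entropies are written into the B-factor field of every atom of the
corresponding residue, so a molecular viewer colouring by B-factor shows
sequence conservation on the protein surface.  Residues with no alignment
column keep a sentinel B-factor (99.99, the largest value printable in the
fixed-width field) so they are visually distinct and never mistaken for
conserved (H near 0) sites.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as pdbio
from Bio import Align

from .alphabet import ONE_TO_THREE, THREE_TO_ONE
from .entropy import EntropyProfile

#: B-factor written to residues with no alignment correspondence.
SENTINEL_BFACTOR: float = 99.99


class PdbParseError(ValueError):
    """Raised when a PDB file cannot be parsed."""


class MappingError(ValueError):
    """Raised when a correspondence names residues absent from the model."""


ResidueKey = tuple[str, int, str]  # (chain_id, res_seq, insertion_code)


@dataclass
class StructureModel:
    """Atomic model with chain/residue identity, coordinates and B-factors.

    ``atoms`` is a biotite AtomArray carrying ``chain_id``, ``res_id``,
    ``ins_code``, ``res_name``, ``atom_name``, ``element``, ``occupancy``
    and ``b_factor`` annotations.  Author residue numbering is preserved.
    """

    atoms: struc.AtomArray

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.atoms.coord)):
            raise PdbParseError("non-finite coordinates in structure")

    @property
    def n_atoms(self) -> int:
        return self.atoms.array_length()

    def chain_ids(self) -> list[str]:
        seen: list[str] = []
        for c in self.atoms.chain_id:
            if c not in seen:
                seen.append(c)
        return seen

    def chain(self, chain_id: str) -> "StructureModel":
        mask = self.atoms.chain_id == chain_id
        if not mask.any():
            raise KeyError(f"chain {chain_id!r} not in model "
                           f"(has {self.chain_ids()})")
        return StructureModel(self.atoms[mask])

    def residue_keys(self, chain_id: str | None = None) -> list[ResidueKey]:
        """Ordered unique (chain, res_seq, icode) keys."""
        atoms = self.atoms
        if chain_id is not None:
            atoms = atoms[atoms.chain_id == chain_id]
        keys: list[ResidueKey] = []
        seen: set[ResidueKey] = set()
        ins = atoms.ins_code if "ins_code" in atoms.get_annotation_categories() \
            else [""] * atoms.array_length()
        for c, r, i in zip(atoms.chain_id, atoms.res_id, ins):
            key = (str(c), int(r), str(i))
            if key not in seen:
                seen.add(key)
                keys.append(key)
        return keys

    def residue_mask(self, key: ResidueKey) -> np.ndarray:
        c, r, i = key
        atoms = self.atoms
        mask = (atoms.chain_id == c) & (atoms.res_id == r)
        if "ins_code" in atoms.get_annotation_categories():
            mask &= atoms.ins_code == i
        return mask

    def one_letter_sequence(self, chain_id: str) -> tuple[str, list[ResidueKey]]:
        """One-letter sequence of a chain's amino-acid residues, with keys.

        Non-amino-acid residues (waters, ligands) are skipped; unknown
        amino-acid residue names become 'X'.
        """
        seq_chars: list[str] = []
        keys: list[ResidueKey] = []
        for key in self.residue_keys(chain_id):
            mask = self.residue_mask(key)
            res_name = str(self.atoms.res_name[mask][0])
            hetero = bool(self.atoms.hetero[mask][0])
            if res_name in THREE_TO_ONE:
                seq_chars.append(THREE_TO_ONE[res_name])
                keys.append(key)
            elif not hetero:
                seq_chars.append("X")
                keys.append(key)
        return "".join(seq_chars), keys

    def ca_coordinates(self, chain_id: str) -> tuple[np.ndarray, list[ResidueKey]]:
        """Cα coordinates of a chain in residue order, with residue keys."""
        coords: list[np.ndarray] = []
        keys: list[ResidueKey] = []
        for key in self.residue_keys(chain_id):
            mask = self.residue_mask(key) & (self.atoms.atom_name == "CA")
            if mask.any():
                coords.append(self.atoms.coord[mask][0])
                keys.append(key)
        return np.asarray(coords, dtype=float), keys

    def copy(self) -> "StructureModel":
        return StructureModel(self.atoms.copy())


@dataclass
class ResidueCorrespondence:
    """Map from alignment columns (0-based) to structure residues."""

    pairs: list[tuple[int, ResidueKey]]
    source: Literal["user-supplied", "sequence-alignment"] = "user-supplied"

    def __post_init__(self) -> None:
        res = [p[1] for p in self.pairs]
        if len(set(res)) != len(res):
            raise MappingError("a structure residue is mapped more than once")


@dataclass
class PaintReport:
    n_mapped: int
    n_unmapped: int
    unmapped_keys: list[ResidueKey] = field(default_factory=list)


# ---------------------------------------------------------------------------
# PDB input / output
# ---------------------------------------------------------------------------

def read_pdb(path: str | Path) -> StructureModel:
    """Read a fixed-column PDB file into a StructureModel.

    ATOM and HETATM records are parsed; alternate locations are resolved to
    the first conformer (blank or 'A'); models beyond the first are ignored
    with a warning.
    """
    try:
        pdb_file = pdbio.PDBFile.read(str(path))
        n_models = pdb_file.get_model_count()
        atoms = pdb_file.get_structure(
            model=1, altloc="first", extra_fields=["b_factor", "occupancy"]
        )
    except Exception as exc:  # biotite raises various error types
        raise PdbParseError(f"cannot parse PDB file {path}: {exc}") from exc
    if n_models > 1:
        warnings.warn(
            f"{path}: {n_models} models present; only model 1 is read",
            stacklevel=2,
        )
    return StructureModel(atoms)


def write_pdb(model: StructureModel, path: str | Path) -> None:
    """Write fixed-column PDB (B-factor printed %6.2f, serials from 1)."""
    pdb_file = pdbio.PDBFile()
    pdb_file.set_structure(model.atoms)
    pdb_file.write(str(path))


def model_from_arrays(
    chain_ids: Sequence[str],
    res_ids: Sequence[int],
    res_names: Sequence[str],
    atom_names: Sequence[str],
    coords: np.ndarray,
    elements: Sequence[str] | None = None,
    b_factors: Sequence[float] | None = None,
) -> StructureModel:
    """Assemble a StructureModel from parallel per-atom arrays."""
    n = len(atom_names)
    atoms = struc.AtomArray(n)
    atoms.coord = np.asarray(coords, dtype=np.float32).reshape(n, 3)
    atoms.chain_id = np.asarray(chain_ids, dtype="U4")
    atoms.res_id = np.asarray(res_ids, dtype=int)
    atoms.res_name = np.asarray(res_names, dtype="U5")
    atoms.atom_name = np.asarray(atom_names, dtype="U6")
    atoms.hetero = np.zeros(n, dtype=bool)
    atoms.set_annotation("ins_code", np.asarray([""] * n, dtype="U1"))
    if elements is None:
        elements = [name.strip()[0] for name in atom_names]
    atoms.element = np.asarray(elements, dtype="U2")
    atoms.set_annotation("occupancy", np.ones(n, dtype=float))
    bf = np.zeros(n, dtype=float) if b_factors is None else np.asarray(b_factors, float)
    atoms.set_annotation("b_factor", bf)
    return StructureModel(atoms)


# ---------------------------------------------------------------------------
# Correspondence and painting
# ---------------------------------------------------------------------------

def correspondence_from_sequence(
    model: StructureModel,
    aln_row: str,
    chain_id: str,
) -> ResidueCorrespondence:
    """Derive a column<->residue correspondence by global sequence alignment.

    The chain's one-letter sequence is globally aligned to the (gapped)
    alignment row; matched positions map the row's alignment columns to
    structure residues.  Gaps on either side leave residues unmapped.
    """
    seq, keys = model.one_letter_sequence(chain_id)
    row_ungapped = aln_row.replace("-", "").replace(".", "")
    # columns of the original row corresponding to its ungapped positions
    col_of_pos = [j for j, ch in enumerate(aln_row) if ch not in "-."]

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -0.5
    alignment = aligner.align(seq, row_ungapped)[0]

    pairs: list[tuple[int, ResidueKey]] = []
    for (s_start, s_end), (r_start, r_end) in zip(*alignment.aligned):
        for off in range(s_end - s_start):
            pairs.append((col_of_pos[r_start + off], keys[s_start + off]))
    return ResidueCorrespondence(pairs=pairs, source="sequence-alignment")


def map_entropy_to_bfactors(
    model: StructureModel,
    profile: EntropyProfile,
    corr: ResidueCorrespondence,
    sentinel: float = SENTINEL_BFACTOR,
) -> tuple[StructureModel, PaintReport]:
    """Paint per-column entropies into the B-factor field.

    Every atom of a mapped residue receives the column's H (bits); unmapped
    residues get the sentinel.  Undefined (NaN) entropies also map to the
    sentinel.  Returns the painted copy and mapped/unmapped counts.
    """
    painted = model.copy()
    missing = [key for _, key in corr.pairs if not painted.residue_mask(key).any()]
    if missing:
        raise MappingError(f"correspondence names absent residues: {missing}")
    bad_cols = [col for col, _ in corr.pairs if not (0 <= col < len(profile))]
    if bad_cols:
        raise MappingError(f"correspondence columns out of range: {bad_cols}")

    bf = np.full(painted.n_atoms, sentinel, dtype=float)
    mapped_keys: set[ResidueKey] = set()
    for col, key in corr.pairs:
        h = profile.H[col]
        if np.isfinite(h):
            bf[painted.residue_mask(key)] = round(h, 2)
            mapped_keys.add(key)
    painted.atoms.set_annotation("b_factor", bf)
    all_keys = painted.residue_keys()
    unmapped = [k for k in all_keys if k not in mapped_keys]
    return painted, PaintReport(
        n_mapped=len(mapped_keys), n_unmapped=len(unmapped), unmapped_keys=unmapped
    )


def classify_conserved(
    model: StructureModel,
    cap: float = 0.3,
    sentinel: float = SENTINEL_BFACTOR,
) -> tuple[dict[ResidueKey, bool], dict[str, int]]:
    """Flag residues whose painted entropy is strictly below the cap.

    Residues still carrying the sentinel are excluded and counted
    separately.  Returns (per-residue flags, summary counts).
    """
    flags: dict[ResidueKey, bool] = {}
    n_sentinel = 0
    for key in model.residue_keys():
        h = float(model.atoms.b_factor[model.residue_mask(key)][0])
        if abs(h - sentinel) < 1e-9:
            n_sentinel += 1
            continue
        flags[key] = h < cap
    summary = {
        "n_conserved": sum(flags.values()),
        "n_variable": sum(not v for v in flags.values()),
        "n_excluded_sentinel": n_sentinel,
    }
    if not flags and n_sentinel:
        warnings.warn("all residues carry the sentinel B-factor; "
                      "nothing classified", stacklevel=2)
    return flags, summary


def pdb_string(model: StructureModel) -> str:
    """Render the model as PDB text (for tests and in-memory round-trips)."""
    pdb_file = pdbio.PDBFile()
    pdb_file.set_structure(model.atoms)
    buf = io.StringIO()
    pdb_file.write(buf)
    return buf.getvalue()


def residue_name_for(one_letter: str) -> str:
    return ONE_TO_THREE.get(one_letter.upper(), "UNK")
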