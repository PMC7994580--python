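"""Synthetic inputs with known ground truth for every pipeline stage.

Four generators emulate the data the analyses consume, so conservation
mapping, superposition, interface analysis and motif scanning can all be
exercised — and their outputs checked against planted truth — without any
external downloads:

* :func:`generate_msa` — alignment columns with a specified majority-residue
  fraction (e.g. 0.97) and the remaining probability spread uniformly over
  the other 19 amino acids, matching the identity/entropy calibration of the
  conservation analysis.
* :func:`generate_structure_pair` — a backbone chain and a copy related by a
  known rigid rotation/translation plus Gaussian coordinate noise, with a
  chosen number of residues additionally displaced as planted outliers.
* :func:`generate_split_motif_set` — protein sequences carrying 0–5 planted
  copies of a three-segment split motif separated by spacers drawn from
  given ranges, with a conservation parameter controlling per-position match
  to the consensus.
* :func:`generate_complex` — a two-chain complex of single-sphere residues
  facing each other across a planar gap, with a controllable hydrophobic
  fraction at the interface.

Identical seeds give byte-identical outputs; each call uses one fresh RNG
stream seeded from its spec.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .alphabet import AA_ORDER, N_AA, ONE_TO_THREE
from .entropy import MultipleAlignment, alignment_from_rows
from .structure import StructureModel, model_from_arrays

CA_SPACING: float = 3.8  # Å, consecutive Cα distance in extended chains


class SpecificationError(ValueError):
    """Raised when a generator spec violates its invariants."""


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MsaSpec:
    n_sequences: int
    length: int
    column_identity: tuple[float, ...]
    gap_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sequences < 1 or self.length < 1:
            raise SpecificationError("n_sequences and length must be positive")
        if len(self.column_identity) != self.length:
            raise SpecificationError("one identity fraction per column required")
        for p in self.column_identity:
            if not (1.0 / N_AA <= p <= 1.0):
                raise SpecificationError(
                    f"column identity {p} outside [1/20, 1]")
        if not (0.0 <= self.gap_rate < 1.0):
            raise SpecificationError("gap_rate must lie in [0, 1)")

    @classmethod
    def uniform_identity(cls, n_sequences: int, length: int, identity: float,
                         gap_rate: float = 0.0, seed: int = 0) -> "MsaSpec":
        return cls(n_sequences=n_sequences, length=length,
                   column_identity=(identity,) * length,
                   gap_rate=gap_rate, seed=seed)


@dataclass(frozen=True)
class StructurePairSpec:
    n_residues: int
    rotation_axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    rotation_angle: float = 0.0       # radians
    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    noise_sd: float = 0.0             # Å
    n_outliers: int = 0
    outlier_displacement: float = 0.0  # Å
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_residues < 1:
            raise SpecificationError("n_residues must be positive")
        if np.linalg.norm(self.rotation_axis) < 1e-12:
            raise SpecificationError("rotation axis must be non-zero")
        if self.noise_sd < 0:
            raise SpecificationError("noise_sd must be non-negative")
        if not (0 <= self.n_outliers < self.n_residues):
            raise SpecificationError("n_outliers must be < n_residues")


@dataclass(frozen=True)
class SplitMotifSpec:
    segment_widths: tuple[int, int, int] = (8, 10, 9)
    spacer_ranges: tuple[tuple[int, int], tuple[int, int]] = ((2, 6), (4, 10))
    copies_per_sequence: int = 3
    n_sequences: int = 10
    background_length: int = 400
    conservation: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.segment_widths) != 3 or min(self.segment_widths) < 1:
            raise SpecificationError("three positive segment widths required")
        for lo, hi in self.spacer_ranges:
            if lo < 0 or lo > hi:
                raise SpecificationError(f"invalid spacer range ({lo}, {hi})")
        if not (0 <= self.copies_per_sequence <= 5):
            raise SpecificationError("copies_per_sequence must be in [0, 5]")
        if self.n_sequences < 1 or self.background_length < 1:
            raise SpecificationError("n_sequences/background_length positive")
        if not (0.0 < self.conservation <= 1.0):
            raise SpecificationError("conservation must lie in (0, 1]")
        max_span = self.max_copy_span * self.copies_per_sequence
        if max_span > self.background_length:
            raise SpecificationError(
                f"planted span {max_span} exceeds background_length "
                f"{self.background_length}")

    @property
    def max_copy_span(self) -> int:
        w = self.segment_widths
        return (w[0] + self.spacer_ranges[0][1] + w[1]
                + self.spacer_ranges[1][1] + w[2])


@dataclass(frozen=True)
class ComplexSpec:
    chain_sizes: tuple[int, int] = (25, 25)
    interface_spacing: float = 4.0    # Å between the facing planes
    hydrophobic_fraction_at_interface: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.chain_sizes) < 1:
            raise SpecificationError("chain sizes must be positive")
        if self.interface_spacing <= 0:
            raise SpecificationError("interface_spacing must be > 0")
        if not (0.0 <= self.hydrophobic_fraction_at_interface <= 1.0):
            raise SpecificationError("hydrophobic fraction must lie in [0, 1]")


# ---------------------------------------------------------------------------
# Alignment generator
# ---------------------------------------------------------------------------

def generate_msa(spec: MsaSpec) -> tuple[MultipleAlignment, dict]:
    """Sample an alignment with per-column majority-residue fractions.

    Each column's majority residue is drawn uniformly (seeded); each row
    then carries the majority residue with probability ``identity`` and one
    of the other 19 amino acids uniformly otherwise.  Gaps replace residues
    independently at ``gap_rate``.  Returns the alignment and a truth record
    with the majority residue per column.
    """
    rng = np.random.default_rng(spec.seed)
    majority_idx = rng.integers(0, N_AA, size=spec.length)
    cols = np.empty((spec.n_sequences, spec.length), dtype="U1")
    for j in range(spec.length):
        p = spec.column_identity[j]
        is_major = rng.random(spec.n_sequences) < p
        others = np.delete(np.arange(N_AA), majority_idx[j])
        draw = rng.integers(0, N_AA - 1, size=spec.n_sequences)
        col_idx = np.where(is_major, majority_idx[j], others[draw])
        cols[:, j] = [AA_ORDER[i] for i in col_idx]
    if spec.gap_rate > 0:
        gaps = rng.random(cols.shape) < spec.gap_rate
        cols[gaps] = "-"
    rows = ["".join(r) for r in cols]
    truth = {
        "majority_residue": [AA_ORDER[i] for i in majority_idx],
        "column_identity": list(spec.column_identity),
    }
    return alignment_from_rows(rows), truth


# ---------------------------------------------------------------------------
# Structure-pair generator
# ---------------------------------------------------------------------------

def _rotation_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation about a (normalised) axis."""
    u = np.asarray(axis, float)
    u = u / np.linalg.norm(u)
    K = np.array([[0, -u[2], u[1]], [u[2], 0, -u[0]], [-u[1], u[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def _backbone_chain(n_residues: int, rng: np.random.Generator,
                    chain_id: str = "A") -> StructureModel:
    """Random-walk Cα trace at 3.8 Å spacing with rigid local backbone
    frames (N, CA, C, O per residue)."""
    ca = np.zeros((n_residues, 3))
    direction = np.array([1.0, 0.0, 0.0])
    for i in range(1, n_residues):
        # biased walk: new direction within ~60 degrees of the previous
        perturb = rng.normal(scale=0.5, size=3)
        direction = direction + perturb
        direction /= np.linalg.norm(direction)
        ca[i] = ca[i - 1] + CA_SPACING * direction

    chain_ids, res_ids, res_names, atom_names, coords, elements = \
        [], [], [], [], [], []
    aa_choices = rng.integers(0, N_AA, size=n_residues)
    for i in range(n_residues):
        # orthonormal local frame per residue for the N/C/O offsets
        e1 = rng.normal(size=3)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(e1, rng.normal(size=3))
        e2 /= np.linalg.norm(e2)
        offsets = {
            "N": -1.46 * e1,
            "CA": np.zeros(3),
            "C": 1.52 * e1,
            "O": 1.52 * e1 + 1.23 * e2,
        }
        res_name = ONE_TO_THREE[AA_ORDER[aa_choices[i]]]
        for name in ("N", "CA", "C", "O"):
            chain_ids.append(chain_id)
            res_ids.append(i + 1)
            res_names.append(res_name)
            atom_names.append(name)
            coords.append(ca[i] + offsets[name])
            elements.append(name[0])
    return model_from_arrays(chain_ids, res_ids, res_names, atom_names,
                             np.array(coords), elements)


def generate_structure_pair(
    spec: StructurePairSpec,
) -> tuple[StructureModel, StructureModel, dict]:
    """A backbone chain A and its transformed copy B with planted outliers.

    B = R·A + t + Gaussian noise; ``n_outliers`` residues of B are further
    displaced by ``outlier_displacement`` along random directions.  The truth
    record carries R, t and the 0-based outlier residue indices.
    """
    rng = np.random.default_rng(spec.seed)
    model_a = _backbone_chain(spec.n_residues, rng, chain_id="A")
    R = _rotation_matrix(np.array(spec.rotation_axis), spec.rotation_angle)
    t = np.asarray(spec.translation, float)

    coords_b = model_a.atoms.coord.astype(float) @ R.T + t
    if spec.noise_sd > 0:
        coords_b = coords_b + rng.normal(scale=spec.noise_sd,
                                         size=coords_b.shape)
    outlier_idx = np.sort(rng.choice(spec.n_residues, size=spec.n_outliers,
                                     replace=False)) if spec.n_outliers else \
        np.array([], dtype=int)
    for ridx in outlier_idx:
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        mask = model_a.atoms.res_id == ridx + 1
        coords_b[mask] += spec.outlier_displacement * direction

    model_b = model_a.copy()
    model_b.atoms.coord = coords_b.astype(np.float32)
    model_b.atoms.chain_id = np.full(model_b.n_atoms, "A", dtype="U4")
    truth = {
        "rotation": R.tolist(),
        "translation": t.tolist(),
        "outlier_residues": outlier_idx.tolist(),
    }
    return model_a, model_b, truth


# ---------------------------------------------------------------------------
# Split-motif sequence generator
# ---------------------------------------------------------------------------

def _mutate(consensus: str, conservation: float,
            rng: np.random.Generator) -> str:
    """Per-position: consensus residue w.p. ``conservation``, else one of
    the other 19 uniformly."""
    out = []
    for ch in consensus:
        if rng.random() < conservation:
            out.append(ch)
        else:
            others = [a for a in AA_ORDER if a != ch]
            out.append(others[rng.integers(0, N_AA - 1)])
    return "".join(out)


def generate_split_motif_set(
    spec: SplitMotifSpec,
) -> tuple[dict[str, str], dict]:
    """Sequences with planted three-segment split-motif copies.

    Returns ``{sequence_id: sequence}`` and a truth record holding the
    consensus segments and, per sequence, the planted placements (segment
    offsets and spacer lengths).
    """
    rng = np.random.default_rng(spec.seed)
    consensus = ["".join(AA_ORDER[i] for i in rng.integers(0, N_AA, size=w))
                 for w in spec.segment_widths]
    w1, w2, w3 = spec.segment_widths
    sequences: dict[str, str] = {}
    placements: dict[str, list[dict]] = {}

    for s in range(spec.n_sequences):
        seq_id = f"synth{s + 1}"
        seq = list("".join(
            AA_ORDER[i] for i in rng.integers(0, N_AA,
                                              size=spec.background_length)))
        sequences[seq_id] = ""
        placements[seq_id] = []

        copies = spec.copies_per_sequence
        if copies == 0:
            sequences[seq_id] = "".join(seq)
            continue
        spacer1 = rng.integers(spec.spacer_ranges[0][0],
                               spec.spacer_ranges[0][1] + 1, size=copies)
        spacer2 = rng.integers(spec.spacer_ranges[1][0],
                               spec.spacer_ranges[1][1] + 1, size=copies)
        spans = w1 + spacer1 + w2 + spacer2 + w3
        slack = spec.background_length - int(spans.sum())
        # distribute the slack as gaps before/between/after the copies
        gaps = rng.multinomial(slack, np.full(copies + 1, 1 / (copies + 1)))

        pos = 0
        for c in range(copies):
            pos += int(gaps[c])
            o1 = pos
            o2 = o1 + w1 + int(spacer1[c])
            o3 = o2 + w2 + int(spacer2[c])
            for off, cons in zip((o1, o2, o3), consensus):
                inst = _mutate(cons, spec.conservation, rng)
                seq[off:off + len(inst)] = inst
            placements[seq_id].append({
                "offsets": [o1, o2, o3],
                "spacers": [int(spacer1[c]), int(spacer2[c])],
            })
            pos = o3 + w3
        sequences[seq_id] = "".join(seq)

    truth = {"consensus_segments": consensus, "placements": placements}
    return sequences, truth


# ---------------------------------------------------------------------------
# Complex generator
# ---------------------------------------------------------------------------

def generate_complex(spec: ComplexSpec) -> tuple[StructureModel, dict]:
    """Two single-sphere-residue chains facing across a planar gap.

    Chain A sits on a square lattice in the z=0 plane, chain B on a matching
    lattice at z=``interface_spacing``; each residue is a lone Cα carbon.
    Residues are LEU with probability ``hydrophobic_fraction_at_interface``
    and SER otherwise.  At large spacing (e.g. 100 Å) the chains do not
    contact and the buried area is zero.
    """
    rng = np.random.default_rng(spec.seed)
    chain_ids, res_ids, res_names, atom_names, coords, elements = \
        [], [], [], [], [], []
    truth_residues: dict[str, list[dict]] = {"A": [], "B": []}

    for chain, size, z in (("A", spec.chain_sizes[0], 0.0),
                           ("B", spec.chain_sizes[1], spec.interface_spacing)):
        n_cols = int(np.ceil(np.sqrt(size)))
        for r in range(size):
            x = (r % n_cols) * CA_SPACING
            y = (r // n_cols) * CA_SPACING
            hydro = bool(rng.random() < spec.hydrophobic_fraction_at_interface)
            res_name = "LEU" if hydro else "SER"
            chain_ids.append(chain)
            res_ids.append(r + 1)
            res_names.append(res_name)
            atom_names.append("CA")
            coords.append([x, y, z])
            elements.append("C")
            truth_residues[chain].append(
                {"res_seq": r + 1, "hydrophobic": hydro})
    model = model_from_arrays(chain_ids, res_ids, res_names, atom_names,
                              np.array(coords, dtype=float), elements)
    truth = {"residues": truth_residues,
             "interface_spacing": spec.interface_spacing}
    return model, truth


# ---------------------------------------------------------------------------
# File output helpers
# ---------------------------------------------------------------------------

def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    lines = []
    for seq_id, seq in sequences.items():
        lines.append(f">{seq_id}")
        lines.extend(seq[i:i + 60] for i in range(0, len(seq), 60))
    Path(path).write_text("\n".join(lines) + "\n")


def write_truth(truth: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth, indent=1))


def spec_to_json(spec) -> str:
    return json.dumps(asdict(spec), indent=1)
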