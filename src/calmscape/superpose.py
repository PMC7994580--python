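"""Rigid-body structural superposition with iterative outlier rejection.

The optimal least-squares rotation is found by the Kabsch SVD construction,
with the determinant sign corrected so the result is always a proper rotation
(no reflection).  Structural similarity between homologous domains is
reported as the RMSD over the retained atom pairs, mirroring the convention
of refinement-with-rejection superposition tools: fit, measure per-pair
deviations, drop pairs deviating more than ``reject_factor`` times the
current RMSD, refit, and repeat until stable.  Reported values therefore
read "RMSD x Å over n atoms".

A structure-based sequence alignment is derived afterwards: with the mobile
chain transformed onto the reference, residues are paired greedily by Cα
distance (closest first, order-preserving — crossings forbidden) and the
pairing is emitted as a two-row gapped alignment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .structure import StructureModel

BACKBONE_ATOMS = ("N", "CA", "C", "O")

Selection = Literal["CA-only", "backbone", "all-atom"]


class SuperpositionError(ValueError):
    """Raised for degenerate inputs (too few pairs, all pairs rejected)."""


@dataclass
class AtomCorrespondence:
    """Paired atom indices between two coordinate sets.

    ``groups`` optionally labels each pair with the residue it belongs to,
    enabling residue-granular outlier rejection.
    """

    pairs: list[tuple[int, int]]
    selection: Selection = "backbone"
    groups: list[int] | None = None

    def __post_init__(self) -> None:
        a_side = [p[0] for p in self.pairs]
        b_side = [p[1] for p in self.pairs]
        if len(set(a_side)) != len(a_side) or len(set(b_side)) != len(b_side):
            raise SuperpositionError("atom repeated within one side of "
                                     "a correspondence")
        if self.groups is not None and len(self.groups) != len(self.pairs):
            raise SuperpositionError("one group label per pair required")


@dataclass
class SuperpositionResult:
    """Rotation/translation mapping mobile B onto reference A, with RMSD."""

    rotation: np.ndarray          # 3x3 proper rotation
    translation: np.ndarray       # length-3, Å
    rmsd: float                   # Å, over retained pairs
    n_retained: int
    cycles_run: int = 1
    rejected: list[list[int]] = field(default_factory=list)  # pair idx / cycle

    def transform(self, coords: np.ndarray) -> np.ndarray:
        """Apply the fitted transform to mobile-frame coordinates."""
        return coords @ self.rotation.T + self.translation

    @property
    def rejected_pairs(self) -> list[int]:
        return [i for cycle in self.rejected for i in cycle]


def kabsch(
    correspondence: AtomCorrespondence,
    coords_a: np.ndarray,
    coords_b: np.ndarray,
) -> SuperpositionResult:
    """Least-squares optimal rigid superposition of B onto A.

    Centroids are removed, the cross-covariance is decomposed by SVD and the
    rotation determinant corrected to +1.  RMSD is the root mean squared
    deviation over all correspondence pairs after transforming B.
    """
    idx_a = np.array([p[0] for p in correspondence.pairs], dtype=int)
    idx_b = np.array([p[1] for p in correspondence.pairs], dtype=int)
    if len(idx_a) < 3:
        raise SuperpositionError(
            f"need at least 3 atom pairs, got {len(idx_a)}")
    A = np.asarray(coords_a, dtype=float)[idx_a]
    B = np.asarray(coords_b, dtype=float)[idx_b]

    cen_a = A.mean(axis=0)
    cen_b = B.mean(axis=0)
    A0 = A - cen_a
    B0 = B - cen_b
    # degenerate geometry: all points collinear -> rotation underdetermined
    if np.linalg.matrix_rank(A0, tol=1e-8) < 2:
        raise SuperpositionError("degenerate (collinear) reference geometry")

    H = B0.T @ A0
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cen_a - R @ cen_b

    diff = B @ R.T + t - A
    rmsd = float(np.sqrt(np.mean(np.sum(diff ** 2, axis=1))))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd,
                               n_retained=len(idx_a))


def iterative_superpose(
    correspondence: AtomCorrespondence,
    coords_a: np.ndarray,
    coords_b: np.ndarray,
    max_cycles: int = 5,
    reject_factor: float = 2.0,
    reject_unit: Literal["pair", "residue"] = "pair",
    min_cutoff: float = 0.01,
) -> SuperpositionResult:
    """Superpose with cycles of outlier rejection.

    Each cycle refits on the retained pairs, then rejects pairs whose
    deviation exceeds ``reject_factor`` x the cycle RMSD.  Stops when no pair
    is rejected, fewer than 3 pairs would remain, or ``max_cycles`` is
    reached.  Rejected pair indices refer to the original correspondence.

    With ``reject_unit="residue"`` (requires ``correspondence.groups``) the
    deviation is the RMS over each residue's atoms and whole residues are
    rejected together.  Structural outliers are displaced residues, not lone
    atoms, so pooling a residue's atoms suppresses chance rejections from
    the tail of the coordinate-noise distribution while leaving genuinely
    displaced residues far above the cutoff.

    ``min_cutoff`` (Å) floors the rejection cutoff so essentially exact
    fits (RMSD at coordinate-precision level) never shed pairs on rounding
    noise.
    """
    if reject_unit == "residue" and correspondence.groups is None:
        raise SuperpositionError("residue-level rejection requires group "
                                 "labels on the correspondence")
    active = list(range(len(correspondence.pairs)))
    rejected_per_cycle: list[list[int]] = []
    result: SuperpositionResult | None = None

    for cycle in range(1, max_cycles + 1):
        sub = AtomCorrespondence(
            pairs=[correspondence.pairs[i] for i in active],
            selection=correspondence.selection,
        )
        result = kabsch(sub, coords_a, coords_b)
        result.cycles_run = cycle
        result.rejected = rejected_per_cycle

        idx_a = np.array([p[0] for p in sub.pairs], dtype=int)
        idx_b = np.array([p[1] for p in sub.pairs], dtype=int)
        dev = np.linalg.norm(
            result.transform(np.asarray(coords_b, float)[idx_b])
            - np.asarray(coords_a, float)[idx_a],
            axis=1,
        )
        if reject_unit == "residue":
            assert correspondence.groups is not None
            labels = np.array([correspondence.groups[i] for i in active])
            group_rms = {
                g: float(np.sqrt(np.mean(dev[labels == g] ** 2)))
                for g in np.unique(labels)
            }
            dev = np.array([group_rms[g] for g in labels])
        cutoff = max(reject_factor * result.rmsd, min_cutoff)
        reject_local = np.nonzero(dev > cutoff)[0]
        if reject_local.size == 0 or cycle == max_cycles:
            break
        if len(active) - reject_local.size < 3:
            break
        rejected_per_cycle.append([active[i] for i in reject_local])
        keep = np.ones(len(active), dtype=bool)
        keep[reject_local] = False
        active = [a for a, k in zip(active, keep) if k]

    assert result is not None
    if result.n_retained < 3:
        raise SuperpositionError("all pairs rejected during refinement")
    return result


def correspondence_from_residues(
    model_a: StructureModel,
    model_b: StructureModel,
    chain_a: str,
    chain_b: str,
    selection: Selection = "backbone",
) -> tuple[AtomCorrespondence, np.ndarray, np.ndarray]:
    """Pair atoms of two chains by residue order and atom name.

    Residues are matched positionally (i-th residue of A to i-th of B, up to
    the shorter chain); within each residue pair, atoms of the selected set
    present in both are paired.  Returns the correspondence plus the full
    coordinate arrays it indexes into.
    """
    wanted = {"CA-only": ("CA",), "backbone": BACKBONE_ATOMS,
              "all-atom": None}[selection]
    sub_a = model_a.chain(chain_a)
    sub_b = model_b.chain(chain_b)
    keys_a = sub_a.residue_keys()
    keys_b = sub_b.residue_keys()
    pairs: list[tuple[int, int]] = []
    groups: list[int] = []
    for res_index, (ka, kb) in enumerate(zip(keys_a, keys_b)):
        mask_a = sub_a.residue_mask(ka)
        mask_b = sub_b.residue_mask(kb)
        names_a = {n: i for i, n in zip(np.nonzero(mask_a)[0],
                                        sub_a.atoms.atom_name[mask_a])}
        names_b = {n: i for i, n in zip(np.nonzero(mask_b)[0],
                                        sub_b.atoms.atom_name[mask_b])}
        names = wanted if wanted is not None else tuple(names_a)
        for n in names:
            if n in names_a and n in names_b:
                pairs.append((int(names_a[n]), int(names_b[n])))
                groups.append(res_index)
    corr = AtomCorrespondence(pairs=pairs, selection=selection, groups=groups)
    return corr, sub_a.atoms.coord.astype(float), sub_b.atoms.coord.astype(float)


# ---------------------------------------------------------------------------
# Structure-based sequence alignment
# ---------------------------------------------------------------------------

def structure_based_alignment(
    model_a: StructureModel,
    model_b: StructureModel,
    result: SuperpositionResult,
    chain_a: str,
    chain_b: str,
    pair_cutoff: float = 4.0,
) -> tuple[str, str]:
    """Two-row gapped alignment implied by the superposition.

    Mobile Cα positions are transformed onto the reference frame; residue
    pairs are accepted greedily by increasing Cα distance (ties broken by
    lower reference residue number), each residue used once, pairs beyond
    ``pair_cutoff`` discarded, and crossings forbidden so sequence order is
    preserved.  Unpaired residues appear against gaps.
    """
    seq_a, keys_ca_a = model_a.one_letter_sequence(chain_a)
    seq_b, keys_ca_b = model_b.one_letter_sequence(chain_b)
    ca_a, keys_a = model_a.ca_coordinates(chain_a)
    ca_b, keys_b = model_b.ca_coordinates(chain_b)
    if len(ca_a) == 0 or len(ca_b) == 0 or pair_cutoff <= 0:
        warnings.warn("no residue pairs under the distance cutoff; "
                      "empty alignment", stacklevel=2)
        return "", ""
    pos_a = {k: i for i, k in enumerate(keys_ca_a)}
    pos_b = {k: i for i, k in enumerate(keys_ca_b)}

    ca_b_t = result.transform(ca_b)
    dists = np.linalg.norm(ca_a[:, None, :] - ca_b_t[None, :, :], axis=2)
    candidates = [
        (float(dists[i, j]), pos_a[keys_a[i]], pos_b[keys_b[j]])
        for i in range(len(keys_a))
        for j in range(len(keys_b))
        if dists[i, j] <= pair_cutoff
        and keys_a[i] in pos_a and keys_b[j] in pos_b
    ]
    candidates.sort(key=lambda c: (c[0], c[1], c[2]))

    used_a: set[int] = set()
    used_b: set[int] = set()
    accepted: list[tuple[int, int]] = []
    for _, ia, ib in candidates:
        if ia in used_a or ib in used_b:
            continue
        # order preservation: no crossings with already-accepted pairs
        if any((ia < pa) != (ib < pb) for pa, pb in accepted):
            continue
        accepted.append((ia, ib))
        used_a.add(ia)
        used_b.add(ib)
    if not accepted:
        warnings.warn("no residue pairs under the distance cutoff; "
                      "empty alignment", stacklevel=2)
        return "", ""
    accepted.sort()

    row_a: list[str] = []
    row_b: list[str] = []
    prev_a = prev_b = -1
    for ia, ib in accepted:
        for k in range(prev_a + 1, ia):        # unpaired A residues
            row_a.append(seq_a[k])
            row_b.append("-")
        for k in range(prev_b + 1, ib):        # unpaired B residues
            row_a.append("-")
            row_b.append(seq_b[k])
        row_a.append(seq_a[ia])
        row_b.append(seq_b[ib])
        prev_a, prev_b = ia, ib
    for k in range(prev_a + 1, len(seq_a)):
        row_a.append(seq_a[k])
        row_b.append("-")
    for k in range(prev_b + 1, len(seq_b)):
        row_a.append("-")
        row_b.append(seq_b[k])
    return "".join(row_a), "".join(row_b)
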