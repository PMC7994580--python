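"""Solvent-accessible surface area, buried interfaces and hydrophobic patches.

SASA follows the Shrake–Rupley construction: each atom is expanded by the
probe radius (1.4 Å water by default) and sampled with a deterministic
Fibonacci sphere of ``n_points`` points; the accessible fraction is the
fraction of points not strictly inside any neighbouring expanded sphere,
scaled by the expanded sphere's area.  Points lying exactly on a neighbour's
surface count as accessible, which makes coincident-sphere cases
deterministic.

Buried surface area (BSA) of a two-chain complex is half the SASA lost on
association:

    BSA = (SASA(A alone) + SASA(B alone) - SASA(AB)) / 2

Interface residues are those losing more than a ΔSASA threshold on
association; the fraction of them that are hydrophobic characterises the
chemical nature of the binding surface.  Hydrophobic surface patches —
connected components of exposed hydrophobic residues under an atom-distance
adjacency — quantify the contiguous greasy faces that binding partners cover.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .structure import ResidueKey, StructureModel

# van der Waals radii (Å) by element; FALLBACK_RADIUS for anything else.
RADII: dict[str, float] = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20, "P": 1.80,
}
FALLBACK_RADIUS: float = 1.80
DEFAULT_PROBE: float = 1.4
DEFAULT_N_POINTS: int = 960

#: ɸ hydrophobic set; Ω aromatic subset (Y/F/W).
HYDROPHOBIC_PHI: frozenset[str] = frozenset("AVLIMFWCY")
AROMATIC_OMEGA: frozenset[str] = frozenset("YFW")

# Kyte–Doolittle hydropathy (alternative scheme: hydrophobic iff > 0).
KYTE_DOOLITTLE: dict[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2,
}

# Maximum accessible areas (Å²) of residue X in an extended Gly-X-Gly
# tripeptide (Tien et al. theoretical values), used for relative SASA.
GXG_MAX_SASA: dict[str, float] = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "Q": 225.0, "E": 223.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}


@dataclass(frozen=True)
class HydropathyScheme:
    """Residue classification into hydrophobic / aromatic / other."""

    name: str
    hydrophobic: frozenset[str]
    aromatic: frozenset[str]

    def classify(self, one_letter: str) -> str:
        a = one_letter.upper()
        if a in self.aromatic:
            return "aromatic"
        if a in self.hydrophobic:
            return "hydrophobic"
        return "other"

    def is_hydrophobic(self, one_letter: str) -> bool:
        a = one_letter.upper()
        return a in self.hydrophobic or a in self.aromatic


PHI_DEFAULT = HydropathyScheme("phi-default", HYDROPHOBIC_PHI, AROMATIC_OMEGA)
KD_SCHEME = HydropathyScheme(
    "kyte-doolittle",
    frozenset(a for a, v in KYTE_DOOLITTLE.items() if v > 0),
    frozenset(),
)
SCHEMES: dict[str, HydropathyScheme] = {
    "phi-default": PHI_DEFAULT,
    "kyte-doolittle": KD_SCHEME,
}


@dataclass
class SasaResult:
    per_atom: np.ndarray                       # Å² per atom
    per_residue: dict[ResidueKey, float]       # Å² summed per residue
    probe: float
    n_points: int

    @property
    def total(self) -> float:
        return float(self.per_atom.sum())


@dataclass
class InterfaceReport:
    bsa: float                                     # Å²
    interface_residues: dict[str, list[ResidueKey]]
    hydrophobic_fraction: float
    delta_sasa: dict[ResidueKey, float]            # Å² lost on association
    threshold: float


@dataclass
class Patch:
    residues: list[ResidueKey]
    total_sasa: float
    classes: list[str] = field(default_factory=list)


def fibonacci_sphere(n_points: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere point set (golden spiral)."""
    i = np.arange(n_points, dtype=float)
    phi = math.pi * (3.0 - math.sqrt(5.0))      # golden angle
    z = 1.0 - 2.0 * (i + 0.5) / n_points
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    theta = phi * i
    return np.stack([r * np.cos(theta), r * np.sin(theta), z], axis=1)


def atom_radii(model: StructureModel) -> np.ndarray:
    return np.array(
        [RADII.get(str(e).upper(), FALLBACK_RADIUS) for e in model.atoms.element]
    )


def sasa(
    model: StructureModel,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
    include_hydrogens: bool = False,
) -> SasaResult:
    """Shrake–Rupley solvent-accessible surface area.

    Hydrogens are ignored by default (experimental models typically lack
    them).  Per-residue SASA is the sum over the residue's atoms.
    """
    atoms = model.atoms
    if not include_hydrogens:
        keep = np.array([str(e).upper() != "H" for e in atoms.element])
        model = StructureModel(atoms[keep])
        atoms = model.atoms
    n = atoms.array_length()
    per_atom = np.zeros(n)
    if n:
        radii = atom_radii(model)
        expanded = radii + probe
        coords = atoms.coord.astype(float)
        sphere = fibonacci_sphere(n_points)
        tree = cKDTree(coords)
        max_reach = 2.0 * expanded.max()
        for i in range(n):
            pts = coords[i] + expanded[i] * sphere
            neighbours = [j for j in tree.query_ball_point(coords[i], max_reach)
                          if j != i]
            accessible = np.ones(n_points, dtype=bool)
            for j in neighbours:
                d = np.linalg.norm(pts - coords[j], axis=1)
                # strict inequality: on-surface points stay accessible
                accessible &= ~(d < expanded[j])
            per_atom[i] = (4.0 * math.pi * expanded[i] ** 2
                           * accessible.sum() / n_points)

    per_residue: dict[ResidueKey, float] = {}
    for key in model.residue_keys():
        per_residue[key] = float(per_atom[model.residue_mask(key)].sum())
    return SasaResult(per_atom=per_atom, per_residue=per_residue,
                      probe=probe, n_points=n_points)


def interface_bsa(
    model: StructureModel,
    chain_a: str,
    chain_b: str,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
    delta_threshold: float = 1.0,
    scheme: HydropathyScheme = PHI_DEFAULT,
) -> InterfaceReport:
    """Buried surface area and interface characterisation of a two-chain
    complex.

    Missing chains raise ``KeyError`` naming the chain.  The hydrophobic
    fraction is computed over interface residues of both chains under the
    active scheme; it is 0.0 for an empty interface.
    """
    sub_a = model.chain(chain_a)
    sub_b = model.chain(chain_b)
    both_mask = (model.atoms.chain_id == chain_a) | (model.atoms.chain_id == chain_b)
    complex_model = StructureModel(model.atoms[both_mask])

    sasa_a = sasa(sub_a, probe, n_points)
    sasa_b = sasa(sub_b, probe, n_points)
    sasa_ab = sasa(complex_model, probe, n_points)

    bsa = (sasa_a.total + sasa_b.total - sasa_ab.total) / 2.0
    # non-contacting chains give 0 up to float cancellation error
    bsa = 0.0 if abs(bsa) < 1e-9 else max(bsa, 0.0)

    delta: dict[ResidueKey, float] = {}
    iface: dict[str, list[ResidueKey]] = {chain_a: [], chain_b: []}
    for chain_id, iso in ((chain_a, sasa_a), (chain_b, sasa_b)):
        for key, area in iso.per_residue.items():
            d = area - sasa_ab.per_residue.get(key, 0.0)
            delta[key] = d
            if d > delta_threshold:
                iface[chain_id].append(key)

    iface_keys = iface[chain_a] + iface[chain_b]
    if iface_keys:
        seqs = {}
        for cid in (chain_a, chain_b):
            letters, keys = complex_model.one_letter_sequence(cid)
            seqs.update(dict(zip(keys, letters)))
        n_hydro = sum(scheme.is_hydrophobic(seqs.get(k, "X")) for k in iface_keys)
        hydro_frac = n_hydro / len(iface_keys)
    else:
        hydro_frac = 0.0
    return InterfaceReport(
        bsa=float(bsa),
        interface_residues=iface,
        hydrophobic_fraction=float(hydro_frac),
        delta_sasa=delta,
        threshold=delta_threshold,
    )


def hydrophobic_patches(
    model: StructureModel,
    sasa_result: SasaResult,
    scheme: HydropathyScheme = PHI_DEFAULT,
    exposure_cutoff: float = 0.05,
    adjacency_cutoff: float = 6.0,
) -> list[Patch]:
    """Connected hydrophobic surface patches.

    Surface residues (relative SASA above ``exposure_cutoff`` w.r.t. the
    Gly-X-Gly maxima) classified hydrophobic under the scheme are linked
    whenever any inter-atom distance is within ``adjacency_cutoff``; each
    connected component is a patch, reported with its summed SASA and sorted
    by area descending.
    """
    letters: dict[ResidueKey, str] = {}
    for cid in model.chain_ids():
        seq, keys = model.one_letter_sequence(cid)
        letters.update(dict(zip(keys, seq)))

    surface_hydro: list[ResidueKey] = []
    for key, area in sasa_result.per_residue.items():
        aa = letters.get(key, "X")
        max_area = GXG_MAX_SASA.get(aa)
        if max_area is None:
            continue
        if area / max_area > exposure_cutoff and scheme.is_hydrophobic(aa):
            surface_hydro.append(key)
    if not surface_hydro:
        return []

    coords = {key: model.atoms.coord[model.residue_mask(key)].astype(float)
              for key in surface_hydro}
    # union-find over residues, edge = min inter-atom distance <= cutoff
    parent = {k: k for k in surface_hydro}

    def find(k: ResidueKey) -> ResidueKey:
        while parent[k] != k:
            parent[k] = parent[parent[k]]
            k = parent[k]
        return k

    for i, ka in enumerate(surface_hydro):
        for kb in surface_hydro[i + 1:]:
            d = np.linalg.norm(
                coords[ka][:, None, :] - coords[kb][None, :, :], axis=2
            ).min()
            if d <= adjacency_cutoff:
                parent[find(ka)] = find(kb)

    groups: dict[ResidueKey, list[ResidueKey]] = {}
    for k in surface_hydro:
        groups.setdefault(find(k), []).append(k)
    patches = [
        Patch(
            residues=sorted(members),
            total_sasa=float(sum(sasa_result.per_residue[m] for m in members)),
            classes=[scheme.classify(letters.get(m, "X")) for m in sorted(members)],
        )
        for members in groups.values()
    ]
    patches.sort(key=lambda p: -p.total_sasa)
    return patches
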