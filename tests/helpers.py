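"""Independent oracles used by the test suite.

The quaternion superposition here is a deliberately separate route from the
package's SVD-based Kabsch fit: the optimal rotation is the eigenvector of
the 4x4 quaternion key matrix (Horn's method), and the minimal RMSD follows
from its largest eigenvalue without ever forming the rotation.
"""

from __future__ import annotations

import numpy as np


def quaternion_rmsd(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    """Minimal RMSD superposing B onto A via Horn's quaternion method.

    Uses the largest eigenvalue lam of the 4x4 key matrix K built from the
    cross-covariance of the centred point sets:
        rmsd = sqrt(max(0, G_A + G_B - 2 lam) / n)
    """
    A = np.asarray(coords_a, float)
    B = np.asarray(coords_b, float)
    A0 = A - A.mean(axis=0)
    B0 = B - B.mean(axis=0)
    n = len(A0)
    G = float((A0 ** 2).sum() + (B0 ** 2).sum())
    S = B0.T @ A0
    Sxx, Sxy, Sxz = S[0]
    Syx, Syy, Syz = S[1]
    Szx, Szy, Szz = S[2]
    K = np.array([
        [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
        [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
        [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
        [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
    ])
    lam = float(np.linalg.eigvalsh(K)[-1])
    return float(np.sqrt(max(0.0, G - 2.0 * lam) / n))


def quaternion_rotation(coords_a: np.ndarray, coords_b: np.ndarray) -> np.ndarray:
    """The optimal rotation from the same quaternion eigenproblem."""
    A = np.asarray(coords_a, float)
    B = np.asarray(coords_b, float)
    A0 = A - A.mean(axis=0)
    B0 = B - B.mean(axis=0)
    S = B0.T @ A0
    Sxx, Sxy, Sxz = S[0]
    Syx, Syy, Syz = S[1]
    Szx, Szy, Szz = S[2]
    K = np.array([
        [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
        [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
        [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
        [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
    ])
    _, vecs = np.linalg.eigh(K)
    w, x, y, z = vecs[:, -1]
    return np.array([
        [w * w + x * x - y * y - z * z, 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), w * w - x * x + y * y - z * z, 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), w * w - x * x - y * y + z * z],
    ])


def planted_outlier_check(seed: int, n_residues: int = 50,
                          n_outliers: int = 2) -> tuple[bool, list[int], list[int]]:
    """Run the full generate->superpose->reject loop for one seed.

    Returns (exact_recovery, rejected_residue_indices, truth_indices) using
    backbone selection with residue-granular rejection.
    """
    import calmscape as cs

    spec = cs.StructurePairSpec(
        n_residues=n_residues, rotation_axis=(0.3, 0.4, 0.8),
        rotation_angle=1.1, translation=(5.0, -3.0, 2.0), noise_sd=0.1,
        n_outliers=n_outliers, outlier_displacement=10.0, seed=seed,
    )
    model_a, model_b, truth = cs.generate_structure_pair(spec)
    corr, ca, cb = cs.correspondence_from_residues(model_a, model_b,
                                                   "A", "A", "backbone")
    result = cs.iterative_superpose(corr, ca, cb, reject_unit="residue")
    rejected = sorted({
        int(model_a.atoms.res_id[corr.pairs[i][0]]) - 1
        for cycle in result.rejected for i in cycle
    })
    return rejected == truth["outlier_residues"], rejected, \
        truth["outlier_residues"]


def split_motif_recovery(seed: int, copies: int = 3,
                         conservation: float = 0.9,
                         n_train: int = 8, n_test: int = 10
                         ) -> tuple[float, int, int]:
    """Full synthetic split-motif round trip for one seed.

    Generates one motif-bearing set, builds segment PSSMs from the planted
    instances of a training split, calibrates thresholds on motif-free null
    sequences, scans the held-out split and returns (recovery rate at exact
    offsets, n false positives, n planted).
    """
    import calmscape as cs

    spec = cs.SplitMotifSpec(copies_per_sequence=copies,
                             n_sequences=n_train + n_test,
                             conservation=conservation, seed=seed)
    seqs, truth = cs.generate_split_motif_set(spec)
    ids = list(seqs)
    train_ids, test_ids = ids[:n_train], ids[n_train:]
    model = cs.split_model_from_placements(
        {i: seqs[i] for i in train_ids},
        {i: truth["placements"][i] for i in train_ids},
        spec.segment_widths, spec.spacer_ranges,
    )
    null_seqs, _ = cs.generate_split_motif_set(
        cs.SplitMotifSpec(copies_per_sequence=0, n_sequences=6,
                          seed=seed + 1000))
    thresholds = [cs.calibrate_threshold(p, list(null_seqs.values()))
                  for p in model.segments]
    n_truth = n_found = n_fp = 0
    for sid in test_ids:
        hits = cs.scan_split(model, seqs[sid], thresholds, sequence_id=sid)
        planted = [tuple(p["offsets"]) for p in truth["placements"][sid]]
        hit_offs = [tuple(h.offsets) for h in hits]
        n_truth += len(planted)
        n_found += sum(1 for p in planted if p in hit_offs)
        n_fp += sum(1 for h in hit_offs if h not in planted)
    return (n_found / n_truth if n_truth else 1.0), n_fp, n_truth
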