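"""Per-site Shannon entropy of protein multiple sequence alignments.

Sequence variability at each alignment column is quantified as the Shannon
entropy in bits,

    H = - sum_i (n_i / N) log2 (n_i / N),

where the sum runs over the 20 standard amino acids, ``n_i`` is the number of
sequences carrying residue *i* at that column and ``N`` normalises the
frequencies.  H = 0 means the column is invariant; the maximum,
log2(20) ~ 4.32 bits, means every residue is equally likely.  A column where a
single majority residue occurs with frequency ~97% (remaining mass spread
evenly over the other 19 residues) has H ~ 0.3 bits, which is the default cap
used to flag "strictly conserved" sites for surface colouring.

Two normalisation conventions are offered for columns containing gaps or
nonstandard residues:

* ``gap_mode="exclude"`` (default): N = sum of amino-acid counts only, so the
  frequencies form a proper distribution and H is a true entropy.
* ``gap_mode="total"``: N = total number of rows, so gapped columns are
  penalised toward lower apparent frequencies (frequencies no longer sum
  to 1).  Offered for compatibility with pipelines that count every row.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
from Bio import SeqIO
from scipy.optimize import brentq

from .alphabet import AA_ORDER, GAP_CHARS, N_AA, NONSTANDARD

MAX_ENTROPY_BITS: float = math.log2(N_AA)

#: Default display cap: columns with H strictly below this are "strictly
#: conserved" (corresponds to roughly 97% majority identity).
DEFAULT_CAP: float = 0.3

#: Sentinel reported for columns whose entropy is undefined (all gap).
UNDEFINED_ENTROPY: float = float("nan")


class AlignmentFormatError(ValueError):
    """Raised for ragged rows, duplicate ids or empty alignment input."""


@dataclass(frozen=True)
class MultipleAlignment:
    """An aligned set of protein sequences.

    Rows are uppercase strings of equal length over the 20 standard amino
    acids, the gap character ``-`` and nonstandard codes such as ``X``.
    """

    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise AlignmentFormatError("ids and rows must have equal length")
        if not self.rows:
            raise AlignmentFormatError("alignment must contain at least one sequence")
        if len(set(self.ids)) != len(self.ids):
            dupes = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise AlignmentFormatError(f"duplicate sequence ids: {dupes}")
        length = len(self.rows[0])
        for seq_id, row in zip(self.ids, self.rows):
            if len(row) != length:
                raise AlignmentFormatError(
                    f"ragged alignment: sequence {seq_id!r} has length "
                    f"{len(row)}, expected {length}"
                )

    @property
    def n_sequences(self) -> int:
        return len(self.rows)

    @property
    def length(self) -> int:
        return len(self.rows[0])

    def column(self, j: int) -> str:
        return "".join(row[j] for row in self.rows)


@dataclass(frozen=True)
class ColumnCounts:
    """Residue counts for one alignment column (the n_i and N of H)."""

    n: dict[str, int]
    n_gap: int
    n_nonstandard: int

    @property
    def n_rows(self) -> int:
        return sum(self.n.values()) + self.n_gap + self.n_nonstandard

    @property
    def n_effective(self) -> int:
        """Number of standard amino-acid observations in the column."""
        return sum(self.n.values())

    def top_residue(self) -> tuple[str, int]:
        """Most frequent amino acid and its count; ('-', 0) if all-gap."""
        if self.n_effective == 0:
            return "-", 0
        # ties broken by fixed alphabet order for determinism
        best = max(AA_ORDER, key=lambda a: self.n.get(a, 0))
        return best, self.n[best]


@dataclass
class EntropyProfile:
    """Per-column entropies (bits) with the counts that produced them."""

    H: list[float]
    counts: list[ColumnCounts]
    cap: float = DEFAULT_CAP
    undefined_columns: list[int] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.H)

    def conserved_mask(self, cap: float | None = None) -> list[bool]:
        """Flags: True where H is defined and strictly below the cap."""
        c = self.cap if cap is None else cap
        return [math.isfinite(h) and h < c for h in self.H]


# ---------------------------------------------------------------------------
# Alignment input
# ---------------------------------------------------------------------------

def read_alignment(path: str | Path) -> MultipleAlignment:
    """Read an aligned FASTA file.

    Rows are uppercased and ``.`` gaps normalised to ``-``.  Ragged records,
    duplicate ids and empty files are rejected.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentFormatError(f"no FASTA records in {path}")
    ids = tuple(rec.id for rec in records)
    rows = tuple(str(rec.seq).upper().replace(".", "-") for rec in records)
    return MultipleAlignment(ids=ids, rows=rows)


def alignment_from_rows(
    rows: Iterable[str], ids: Iterable[str] | None = None
) -> MultipleAlignment:
    """Build an alignment from in-memory rows (uppercased, '.'->'-')."""
    rows = tuple(str(r).upper().replace(".", "-") for r in rows)
    if ids is None:
        ids = tuple(f"seq{i + 1}" for i in range(len(rows)))
    return MultipleAlignment(ids=tuple(ids), rows=rows)


# ---------------------------------------------------------------------------
# Entropy
# ---------------------------------------------------------------------------

def count_column(column: str) -> ColumnCounts:
    """Tally amino acids, gaps and nonstandard codes for one column."""
    n = {a: 0 for a in AA_ORDER}
    n_gap = 0
    n_non = 0
    for ch in column:
        if ch in n:
            n[ch] += 1
        elif ch in GAP_CHARS:
            n_gap += 1
        elif ch in NONSTANDARD:
            n_non += 1
        else:
            raise AlignmentFormatError(f"unrecognised residue code {ch!r}")
    return ColumnCounts(n=n, n_gap=n_gap, n_nonstandard=n_non)


def column_entropy(
    counts: ColumnCounts,
    gap_mode: Literal["exclude", "total"] = "exclude",
) -> float:
    """Shannon entropy (bits) of one column.

    Returns NaN (never silently 0) when no standard amino acid is present.
    Under ``gap_mode="exclude"`` the result lies in [0, log2 20].
    """
    n_eff = counts.n_effective
    if n_eff == 0:
        return UNDEFINED_ENTROPY
    N = counts.n_rows if gap_mode == "total" else n_eff
    h = 0.0
    for a in AA_ORDER:
        ni = counts.n[a]
        if ni:
            p = ni / N
            h -= p * math.log2(p)
    return h


def entropy_profile(
    aln: MultipleAlignment,
    cap: float = DEFAULT_CAP,
    gap_mode: Literal["exclude", "total"] = "exclude",
) -> EntropyProfile:
    """Per-column entropy profile of an alignment.

    All-gap columns are flagged in ``undefined_columns`` and carry NaN;
    errors never propagate as exceptions from individual columns.
    """
    H: list[float] = []
    all_counts: list[ColumnCounts] = []
    undefined: list[int] = []
    for j in range(aln.length):
        counts = count_column(aln.column(j))
        h = column_entropy(counts, gap_mode=gap_mode)
        if not math.isfinite(h):
            undefined.append(j)
        H.append(h)
        all_counts.append(counts)
    return EntropyProfile(H=H, counts=all_counts, cap=cap, undefined_columns=undefined)


def majority_column_entropy(p: float) -> float:
    """H (bits) of a column with majority fraction ``p`` and the remaining
    mass uniform over the other 19 amino acids."""
    if not (1.0 / N_AA <= p <= 1.0):
        raise ValueError(f"majority fraction must lie in [1/20, 1], got {p}")
    h = 0.0
    if p > 0:
        h -= p * math.log2(p)
    rest = (1.0 - p) / (N_AA - 1)
    if rest > 0:
        h -= (N_AA - 1) * rest * math.log2(rest)
    return h


def identity_for_entropy(h_target: float) -> float:
    """Majority fraction p solving H(p, rest uniform over 19) = h_target.

    The inverse of :func:`majority_column_entropy` on p in [1/20, 1], found
    by bracketed root-finding on the monotone branch above the uniform point.
    H = 0.3 gives p ~ 0.97 — the calibration behind the display cap.
    """
    if not (0.0 <= h_target <= MAX_ENTROPY_BITS + 1e-12):
        raise ValueError(
            f"entropy target must lie in [0, log2 20 = {MAX_ENTROPY_BITS:.4f}], "
            f"got {h_target}"
        )
    if h_target == 0.0:
        return 1.0
    if h_target >= MAX_ENTROPY_BITS:
        return 1.0 / N_AA
    # H(p) decreases monotonically from log2 20 at p=1/20 to 0 at p=1.
    p = brentq(lambda p: majority_column_entropy(p) - h_target, 1.0 / N_AA, 1.0,
               xtol=1e-12)
    return float(p)


def write_profile_tsv(
    profile: EntropyProfile, path: str | Path, cap: float | None = None
) -> None:
    """Write the per-column profile as TSV.

    Columns: 1-based index, H (bits, 4 decimals; 'NA' if undefined), N
    (effective count), top residue, top fraction, conserved flag at cap.
    """
    c = profile.cap if cap is None else cap
    lines = ["column\tH_bits\tN\ttop_residue\ttop_fraction\tconserved"]
    for j, (h, counts) in enumerate(zip(profile.H, profile.counts), start=1):
        top_res, top_n = counts.top_residue()
        n_eff = counts.n_effective
        if math.isfinite(h):
            h_str = f"{h:.4f}"
            flag = "1" if h < c else "0"
            frac = f"{top_n / n_eff:.4f}"
        else:
            h_str, flag, frac = "NA", "0", "NA"
        lines.append(f"{j}\t{h_str}\t{n_eff}\t{top_res}\t{frac}\t{flag}")
    Path(path).write_text("\n".join(lines) + "\n")


def empirical_column_frequencies(aln: MultipleAlignment) -> np.ndarray:
    """length x 20 matrix of per-column amino-acid frequencies (gap-excluded)."""
    freqs = np.zeros((aln.length, N_AA))
    for j in range(aln.length):
        counts = count_column(aln.column(j))
        n_eff = counts.n_effective
        if n_eff:
            freqs[j] = [counts.n[a] / n_eff for a in AA_ORDER]
    return freqs
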