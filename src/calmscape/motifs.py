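"""Position-specific scoring models and repeated split-motif scanning.

Scaffolding proteins of the red algal phycobilisome carry 2–5 copies of a
three-part, split sequence motif (a CALM domain): three conserved segments
separated by variable-length spacers.  A shorter tandem motif (a 37-residue
glycine/proline-rich N-terminal repeat) occurs in a subset of the family.

Rather than de novo discovery, this module builds position-specific scoring
matrices (PSSMs) from a seed alignment of known motif instances and scans
target sequences with them.  Log-odds scores use a background-distributed
pseudocount ``q``:

    score[c][a] = log2( (n_ca + q·b_a) / ((N + q)·b_a) )

where ``n_ca`` counts residue ``a`` in seed column ``c``, ``N`` is the number
of seed instances and ``b_a`` the background frequency.  Split motifs are
assembled from per-segment hits by dynamic programming over spacer-length
constraints, maximising total score; copy number per protein follows from
greedy non-overlapping selection of assembled hits.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .alphabet import AA_INDEX, AA_ORDER, N_AA


class MotifInputError(ValueError):
    """Raised for ragged seed instances or invalid model parameters."""


@dataclass
class Pssm:
    """Log-odds scoring matrix (bits), width x 20."""

    log_odds: np.ndarray
    pseudocount: float
    background: np.ndarray

    def __post_init__(self) -> None:
        self.log_odds = np.asarray(self.log_odds, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.log_odds.shape[1] != N_AA:
            raise MotifInputError("log-odds matrix must have 20 columns")
        if not math.isclose(float(self.background.sum()), 1.0, abs_tol=1e-9):
            raise MotifInputError("background frequencies must sum to 1")
        if not np.all(np.isfinite(self.log_odds)):
            raise MotifInputError("non-finite log-odds entries")

    @property
    def width(self) -> int:
        return self.log_odds.shape[0]

    @property
    def max_score(self) -> float:
        """Best achievable score (sum of per-column maxima)."""
        return float(self.log_odds.max(axis=1).sum())

    def score_window(self, window: str) -> float:
        """Score one window; positions with nonstandard residues add 0."""
        s = 0.0
        for c, ch in enumerate(window):
            idx = AA_INDEX.get(ch)
            if idx is not None:
                s += self.log_odds[c, idx]
        return s

    def consensus(self) -> str:
        return "".join(AA_ORDER[i] for i in self.log_odds.argmax(axis=1))


@dataclass
class SplitMotifModel:
    """Three segment PSSMs with inter-segment spacer length ranges."""

    segments: list[Pssm]
    spacer_ranges: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if len(self.segments) != 3:
            raise MotifInputError("split motif requires exactly 3 segments")
        if len(self.spacer_ranges) != 2:
            raise MotifInputError("split motif requires exactly 2 spacer ranges")
        for lo, hi in self.spacer_ranges:
            if lo > hi or lo < 0:
                raise MotifInputError(f"invalid spacer range ({lo}, {hi})")


@dataclass
class MotifHit:
    """A scored placement of a motif (or assembled split motif)."""

    sequence_id: str
    offsets: list[int]                 # 0-based segment starts
    spacers: list[int]
    score: float                       # bits, total
    segment_scores: list[float] = field(default_factory=list)

    @property
    def start(self) -> int:
        return self.offsets[0]

    def end(self, model_widths: Sequence[int]) -> int:
        """One-past-last residue index covered by the hit."""
        return self.offsets[-1] + model_widths[-1]


UNIFORM_BACKGROUND = np.full(N_AA, 1.0 / N_AA)


def build_pssm(
    seed_instances: Sequence[str],
    pseudocount: float = 1.0,
    background: np.ndarray | None = None,
) -> Pssm:
    """Build a log-odds PSSM from ungapped, equal-length seed instances."""
    if len(seed_instances) < 2:
        raise MotifInputError("need at least 2 seed instances")
    width = len(seed_instances[0])
    for s in seed_instances:
        if len(s) != width:
            raise MotifInputError("ragged seed instances")
        if "-" in s or "." in s:
            raise MotifInputError("seed instances must be ungapped")
    bg = UNIFORM_BACKGROUND if background is None else np.asarray(background, float)
    counts = np.zeros((width, N_AA))
    for s in seed_instances:
        for c, ch in enumerate(s.upper()):
            idx = AA_INDEX.get(ch)
            if idx is not None:
                counts[c, idx] += 1
    N = len(seed_instances)
    log_odds = np.log2((counts + pseudocount * bg) / ((N + pseudocount) * bg))
    return Pssm(log_odds=log_odds, pseudocount=pseudocount, background=bg)


def background_from_sequences(sequences: Sequence[str]) -> np.ndarray:
    """Amino-acid frequencies over a sequence set (pseudocount 1 per AA)."""
    counts = np.ones(N_AA)
    for s in sequences:
        for ch in s.upper():
            idx = AA_INDEX.get(ch)
            if idx is not None:
                counts[idx] += 1
    return counts / counts.sum()


def _prune_overlaps(hits: list[MotifHit], span_of: dict[int, tuple[int, int]]
                    ) -> list[MotifHit]:
    """Greedy best-score-first (ties leftmost) non-overlap selection."""
    order = sorted(range(len(hits)), key=lambda i: (-hits[i].score,
                                                    hits[i].offsets[0]))
    chosen: list[int] = []
    for i in order:
        s_i, e_i = span_of[i]
        if all(e_i <= span_of[j][0] or s_i >= span_of[j][1] for j in chosen):
            chosen.append(i)
    return [hits[i] for i in sorted(chosen, key=lambda i: hits[i].offsets[0])]


def scan(
    pssm: Pssm,
    sequence: str,
    score_threshold: float,
    sequence_id: str = "seq",
) -> list[MotifHit]:
    """All non-overlapping windows scoring at or above the threshold.

    Windows are scored at every offset; overlapping candidates are pruned
    best-score-first with ties going to the leftmost window.  Sequences
    shorter than the motif width yield no hits.
    """
    seq = sequence.upper()
    w = pssm.width
    raw: list[MotifHit] = []
    for off in range(len(seq) - w + 1):
        s = pssm.score_window(seq[off:off + w])
        if s >= score_threshold:
            raw.append(MotifHit(sequence_id=sequence_id, offsets=[off],
                                spacers=[], score=s, segment_scores=[s]))
    spans = {i: (h.offsets[0], h.offsets[0] + w) for i, h in enumerate(raw)}
    return _prune_overlaps(raw, spans)


def default_threshold(pssm: Pssm, fraction: float = 0.6) -> float:
    """Scale-free per-segment threshold: a fraction of the maximum score."""
    return fraction * pssm.max_score


def calibrate_threshold(
    pssm: Pssm,
    null_sequences: Sequence[str],
    margin: float = 1.0,
) -> float:
    """Empirical null calibration of a scan threshold.

    Scores every window of motif-free ``null_sequences`` and returns the
    best null score plus ``margin`` bits, so a scan at the returned
    threshold produces no hits on background alike the calibration set.
    """
    best = -math.inf
    w = pssm.width
    for seq in null_sequences:
        s = seq.upper()
        for off in range(len(s) - w + 1):
            best = max(best, pssm.score_window(s[off:off + w]))
    if not math.isfinite(best):
        raise MotifInputError("null sequences shorter than the motif width")
    return best + margin


def scan_split(
    model: SplitMotifModel,
    sequence: str,
    thresholds: Sequence[float] | None = None,
    sequence_id: str = "seq",
) -> list[MotifHit]:
    """Scan for assembled three-segment split motifs.

    Segment hits above their thresholds are assembled left to right by
    dynamic programming: triples whose two spacer lengths fall inside the
    model's ranges, maximising total score.  Assembled triples are pruned to
    a non-overlapping set (best score first, ties leftmost).
    """
    if thresholds is None:
        thresholds = [default_threshold(p) for p in model.segments]
    seq = sequence.upper()
    widths = [p.width for p in model.segments]

    # candidate placements per segment: (offset, score)
    seg_hits: list[list[tuple[int, float]]] = []
    for pssm, thr in zip(model.segments, thresholds):
        cands = [
            (off, pssm.score_window(seq[off:off + pssm.width]))
            for off in range(len(seq) - pssm.width + 1)
        ]
        seg_hits.append([(o, s) for o, s in cands if s >= thr])

    # assemble triples under spacer constraints, best total score per start
    triples: list[MotifHit] = []
    (lo1, hi1), (lo2, hi2) = model.spacer_ranges
    hits2_by_off = {o: s for o, s in seg_hits[1]}
    hits3_by_off = {o: s for o, s in seg_hits[2]}
    for o1, s1 in seg_hits[0]:
        best: MotifHit | None = None
        for sp1 in range(lo1, hi1 + 1):
            o2 = o1 + widths[0] + sp1
            if o2 not in hits2_by_off:
                continue
            s2 = hits2_by_off[o2]
            for sp2 in range(lo2, hi2 + 1):
                o3 = o2 + widths[1] + sp2
                if o3 not in hits3_by_off:
                    continue
                s3 = hits3_by_off[o3]
                total = s1 + s2 + s3
                if best is None or total > best.score:
                    best = MotifHit(
                        sequence_id=sequence_id,
                        offsets=[o1, o2, o3],
                        spacers=[sp1, sp2],
                        score=total,
                        segment_scores=[s1, s2, s3],
                    )
        if best is not None:
            triples.append(best)

    spans = {i: (h.offsets[0], h.offsets[2] + widths[2])
             for i, h in enumerate(triples)}
    return _prune_overlaps(triples, spans)


def repeat_architecture(
    hits: Sequence[MotifHit],
    sequence_length: int,
    widths: Sequence[int],
    domain_name: str = "CALM",
) -> dict:
    """Summarise the repeat architecture of one sequence.

    Returns the domain string (e.g. ``CALM×3``) and 1-based inclusive
    start/end spans per hit, sorted by offset.  Overlapping hits violate the
    scanner's postcondition and raise ``RuntimeError``.
    """
    ordered = sorted(hits, key=lambda h: h.start)
    spans: list[tuple[int, int]] = []
    for h in ordered:
        start_1 = h.start + 1
        end_1 = h.end(widths)
        if end_1 > sequence_length:
            raise RuntimeError(f"hit extends past sequence end ({end_1} > "
                               f"{sequence_length})")
        spans.append((start_1, end_1))
    for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
        if s2 <= e1:
            raise RuntimeError("overlapping hits passed to repeat_architecture")
    return {
        "architecture": f"{domain_name}×{len(spans)}" if spans else "",
        "n_copies": len(spans),
        "spans": spans,
    }


def split_model_from_placements(
    sequences: dict[str, str],
    placements: dict[str, list[dict]],
    segment_widths: Sequence[int],
    spacer_ranges: Sequence[tuple[int, int]],
    pseudocount: float = 1.0,
) -> SplitMotifModel:
    """Build a split-motif model from recorded instance placements.

    Mirrors the seed-alignment route: each recorded copy contributes its
    three segment substrings as seed instances for the corresponding PSSM.
    """
    seg_instances: list[list[str]] = [[], [], []]
    for seq_id, places in placements.items():
        seq = sequences[seq_id]
        for p in places:
            for k, off in enumerate(p["offsets"]):
                seg_instances[k].append(seq[off:off + segment_widths[k]])
    segments = [build_pssm(inst, pseudocount=pseudocount)
                for inst in seg_instances]
    return SplitMotifModel(segments=segments,
                           spacer_ranges=[tuple(r) for r in spacer_ranges])


# ---------------------------------------------------------------------------
# Model persistence
# ---------------------------------------------------------------------------

def save_model(model: Pssm | SplitMotifModel, path: str | Path) -> None:
    """Persist a PSSM or split-motif model as JSON."""
    def pssm_dict(p: Pssm) -> dict:
        return {
            "log_odds": p.log_odds.tolist(),
            "pseudocount": p.pseudocount,
            "background": p.background.tolist(),
        }

    if isinstance(model, Pssm):
        obj = {"kind": "pssm", **pssm_dict(model)}
    else:
        obj = {
            "kind": "split",
            "segments": [pssm_dict(p) for p in model.segments],
            "spacer_ranges": [list(r) for r in model.spacer_ranges],
        }
    Path(path).write_text(json.dumps(obj, indent=1))


def load_model(path: str | Path) -> Pssm | SplitMotifModel:
    obj = json.loads(Path(path).read_text())

    def make_pssm(d: dict) -> Pssm:
        return Pssm(log_odds=np.array(d["log_odds"]),
                    pseudocount=d["pseudocount"],
                    background=np.array(d["background"]))

    if obj["kind"] == "pssm":
        return make_pssm(obj)
    return SplitMotifModel(
        segments=[make_pssm(d) for d in obj["segments"]],
        spacer_ranges=[tuple(r) for r in obj["spacer_ranges"]],
    )
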