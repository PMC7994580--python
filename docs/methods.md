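# Methods

This note documents the models, conventions and numerical choices behind
each stage of the pipeline, what the synthetic generators do and do not
emulate, and the design decisions taken where more than one defensible
convention exists.

## Per-site conservation entropy

Sequence variability at alignment column *j* is the Shannon entropy in
bits over the 20 standard amino acids,
H<sub>j</sub> = −Σ (n<sub>ij</sub>/N) log₂ (n<sub>ij</sub>/N).
Reference points: H = 0 for an invariant column; log₂ 20 ≈ 4.3219 bits for
a uniform column; and, under the "majority residue at fraction *p*, rest
uniform over the other 19" family, H(0.97) ≈ 0.322 bits. The inverse map
`identity_for_entropy` solves H(p) = H* by bracketed root-finding (Brent,
xtol 1e−12) on p ∈ [1/20, 1], where H(p) is strictly decreasing; H = 0.3
gives p = 0.9723, i.e. the "strictly conserved" display cap of 0.3 bits
corresponds to ~97 % identity. The cap uses a strict inequality
(H < cap).

**Gap convention.** Columns of real alignments contain gaps and
nonstandard codes (B, Z, X, U, O, J). By default N = Σ n<sub>i</sub>
counts amino acids only, so the frequencies form a proper distribution
and H is a true entropy in [0, log₂ 20]. The literal convention
(N = number of rows, `gap_mode="total"`) is available; it deflates
frequencies in gapped columns and is provided for compatibility with
pipelines that count every row. All-gap columns yield NaN and are
reported in `undefined_columns` — never silently zero.

## Surface painting

Entropies are written into the B-factor field of every atom of the
corresponding residue (rounded to 2 decimals, the PDB field precision);
viewers colouring by B-factor then show conservation on the molecular
surface. Residues without an alignment column carry the sentinel 99.99,
the largest value printable in the %6.2f field, so they are visually
distinct from conserved (H ≈ 0) sites and are excluded from conserved/
variable classification. Column↔residue correspondence is either
user-supplied or derived by global alignment (Biopython
`PairwiseAligner`, match 2 / mismatch −1 / open −5 / extend −0.5) of the
chain's one-letter sequence against a chosen alignment row; gaps on
either side leave residues unmapped. Author residue numbering
(res_seq + insertion code) is preserved throughout; alternate locations
resolve to the first conformer; only PDB model 1 is read.

## Superposition and outlier rejection

The optimal rigid transform is the Kabsch construction: SVD of the
cross-covariance of the centred point sets with the determinant sign
corrected, so the result is always a proper rotation even for
near-reflective inputs. Degenerate (collinear) geometries and fewer than
3 pairs raise errors. The test suite verifies the fit against an
independent quaternion characteristic-polynomial oracle (largest
eigenvalue of Horn's 4×4 key matrix) to 1e−8 on random instances.

Iterative refinement repeats {fit; reject pairs with deviation
> `reject_factor` × current RMSD} until no rejection, fewer than 3 pairs
would remain, or `max_cycles` is reached (defaults 2.0 and 5, the common
defaults of refinement-with-rejection superposition tools). Two numerical
safeguards matter in practice:

* a floor on the rejection cutoff (`min_cutoff`, default 0.01 Å) so that
  essentially exact fits — where the RMSD is at coordinate-rounding
  level — never shed pairs on numerical noise;
* an optional residue-granular mode (`reject_unit="residue"`): the
  deviation of a residue is the RMS over its atoms and whole residues are
  rejected together. Atom-level rejection trims the upper tail of the
  coordinate-noise distribution (for Gaussian noise, each atom exceeds
  2×RMSD with probability ≈ 0.0075 per cycle), so on clean-but-noisy
  pairs it discards a few perfectly ordinary atoms along with true
  outliers. Pooling the 4 backbone atoms of a residue drops that
  false-rejection probability to ~3×10⁻⁶ while genuinely displaced
  residues remain far above any cutoff; this mode is used when outliers
  are to be identified residue-wise. The default remains atom-level,
  matching the conventional pairwise rule.

Atom selections: backbone (N, CA, C, O; default — retained-atom counts of
published comparisons are consistent with ~4 atoms per residue), CA-only
and all-atom.

**Structure-based sequence alignment.** After applying the transform,
residues are paired greedily by increasing Cα distance (ties broken by
lower reference residue index), each residue used once, pairs beyond
`pair_cutoff` (default 4.0 Å) discarded, and crossings forbidden so
sequence order is preserved; unpaired residues appear against gaps. A
dynamic-programming pairing would optimise a global objective instead;
greedy order-preserving pairing was chosen for determinism and adequacy
on homologous globular domains.

## Surface area, interfaces and patches

SASA follows Shrake–Rupley: each atom's sphere is expanded by the probe
radius (1.4 Å) and sampled with a deterministic Fibonacci (golden-spiral)
point set, default 960 points; the accessible fraction is the fraction of
points not strictly inside any neighbouring expanded sphere. Strict
inequality makes coincident-sphere cases deterministic (a point exactly
on a neighbour's surface counts accessible), and it is what makes the
far-separation additivity property exact rather than approximate. Radii:
C 1.70, N 1.55, O 1.52, S 1.80, H 1.20, P 1.80, fallback 1.80 Å;
hydrogens are ignored by default since experimental models usually lack
them. The suite cross-checks totals against an independent Shrake–Rupley
implementation (biotite) within 2 % and against the closed-form isolated
sphere within 1 %. Fibonacci sampling converges smoothly on protein-like
geometry (<0.5 % change when doubling the point count on a backbone
chain); highly symmetric lattice arrangements can show larger
point-count sensitivity because many sample points lie near sphere-
intersection circles simultaneously.

BSA of a two-chain complex is (SASA(A) + SASA(B) − SASA(AB))/2; values
below 1e−9 Å² are snapped to zero (pure float cancellation). Interface
residues lose more than ΔSASA = 1.0 Ų (configurable) on association; the
hydrophobic fraction over interface residues of both chains uses the
ɸ = {A,V,L,I,M,F,W,C,Y} scheme with aromatic subset Ω = {Y,F,W}
(Kyte–Doolittle > 0 available as an alternative). Hydrophobic patches are
connected components (union–find) of exposed hydrophobic residues —
relative SASA above 0.05 of the Gly-X-Gly extended-tripeptide maxima —
under a minimum inter-atom distance ≤ 6 Å adjacency, reported with summed
SASA, largest first.

## Split-motif models

Motif models are position-specific scoring matrices with log-odds
score[c][a] = log₂((n<sub>ca</sub> + q·b<sub>a</sub>) /
((N + q)·b<sub>a</sub>)), pseudocount q = 1 distributed by the background
b (uniform by default, optionally estimated from the scanned set).
Positions with nonstandard residues contribute 0 bits. Scanning reports
all windows at or above a threshold, pruned to non-overlapping hits
best-score-first with ties to the leftmost window. A split motif is three
PSSMs with two spacer-length ranges; triples are assembled left-to-right
maximising total score subject to the spacer gates, then pruned for
overlap the same way. Copy number and 1-based domain spans per protein
come from `repeat_architecture` (e.g. `CALM×3`).

Thresholds: the scale-free default is 60 % of each segment's maximum
achievable score; for quantitative recovery runs thresholds are
calibrated on motif-free null sequences (best null window score plus a
1-bit margin), which empirically yields ≥ 95 % recovery of planted copies
at conservation 0.9 with zero false positives. This seed-PSSM-scan
procedure replaces de novo motif discovery (expectation–maximisation
services); discovery itself is out of scope.

## Synthetic data

The generators provide ground truth for every stage. Defaults mirror the
study conditions of the analyses: alignments of 83 sequences with 97 %
column identity (the conservation calibration point), Gaussian coordinate
noise of 0.1 Å with 10 Å planted outlier displacements for superposition,
a 1.4 Å probe with hydrophobic planar interfaces for surface analysis,
and 2–5 planted copies of a three-segment split motif at conservation
0.9. Specifics:

* **Alignments** — per column, a uniformly drawn majority residue appears
  with the specified identity fraction, the rest uniform over the other
  19; gaps are independent at `gap_rate`. Columns are independent: no
  phylogenetic correlation, no realistic amino-acid composition. Passing
  tests therefore validate the entropy arithmetic and calibration, not
  robustness to tree-structured redundancy (real alignments may need
  sequence weighting, which is deliberately out of scope).
* **Structure pairs** — a 3.8 Å-spaced Cα random walk with rigid local
  N/CA/C/O frames; B = R·A + t + noise, with chosen residues displaced
  by the outlier distance. Geometry is protein-like in spacing only; no
  side chains, no excluded volume.
* **Complexes** — two square lattices of single-carbon "residues" (LEU or
  SER) facing across a planar gap. This isolates the BSA/ΔSASA/
  classification bookkeeping; it does not model shape complementarity.
* **Motif sets** — background residues uniform over the alphabet with
  planted consensus copies mutated per position at the conservation rate;
  spacers drawn uniformly from their ranges, slack distributed
  multinomially around the copies. Real proteomes have biased
  composition, which would raise null scores somewhat; the calibration
  procedure (nulls drawn from the same background as the target set)
  transfers unchanged.

Every generator consumes one fresh `numpy` RNG stream seeded from its
spec; identical seeds give byte-identical outputs.

## Problem sizes

Quantitative suites run at: 200 random instances (≤ 50 points) for the
Kabsch-vs-quaternion comparison; 20 seeded 50-residue pairs for outlier
recovery; 2000-sequence alignments for the Monte-Carlo entropy check
(tolerance 0.05 bits); 32-atom complexes at 1920 sphere points for the
reference-SASA comparison; and 18-sequence motif sets (8 training / 10
held-out) per copy number for recovery. These sizes give stable
statistics while keeping the full pipeline rerunnable in seconds.

## Known limitations

* PDB fixed-column format only; mmCIF and multi-model ensembles are not
  supported (model 1 is read with a warning).
* Initial superposition correspondence comes from residue order or
  sequence alignment; sequence-independent structural seeding is out of
  scope.
* No sequence weighting in entropy; no E-value statistics for motif hits;
  no electrostatics or binding-energy terms in the surface analysis.
* The extended comparison against deposited phycobilisome and cryptophyte
  structures requires those coordinate files locally; the `superpose` CLI
  performs it when given the files, but no test depends on downloads.
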