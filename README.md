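# calmscape

Structural-bioinformatics toolkit for characterising **cryptophyte-α-like
(CALM) domains** and their binding surfaces in red algal phycobilisomes —
the scaffolding proteins (CaRSPs) that stabilise "lone" phycoerythrin β
subunits the way the cryptophyte α subunit does.

It is aimed at people analysing phycobiliprotein structures and sequence
families, but every stage is generic: it applies to any protein family
where you want conservation painted on a surface, domains superposed and
compared, interfaces quantified, or repeated split motifs counted.

The package implements four analyses plus a seeded synthetic-data layer so
that the entire pipeline runs, and is tested, without any external
downloads:

1. **Conservation mapping.** Per-site sequence variability of a protein
   multiple sequence alignment as Shannon entropy in bits,

   H<sub>j</sub> = − Σ<sub>i=1..20</sub> (n<sub>ij</sub>/N<sub>j</sub>) log₂ (n<sub>ij</sub>/N<sub>j</sub>),

   where n<sub>ij</sub> counts amino acid *i* in column *j*. H = 0 marks an
   invariant site and log₂ 20 ≈ 4.32 bits a maximally variable one; a site
   with a ~97 % majority residue (rest uniform) sits at H ≈ 0.3 bits, the
   default cap for "strictly conserved". Entropies are written into the
   B-factor field of a PDB file so any molecular viewer colours the
   surface by conservation.
2. **Structural superposition.** Kabsch (SVD) least-squares rigid fitting
   with iterative outlier rejection (drop pairs deviating more than
   `reject_factor` × current RMSD, refit, repeat), reporting
   "RMSD *x* Å over *n* atoms", plus a structure-based sequence alignment
   derived from Cα proximity after superposition.
3. **Binding-surface analysis.** Shrake–Rupley solvent-accessible surface
   area (Fibonacci sphere sampling), buried surface area
   BSA = (SASA(A) + SASA(B) − SASA(AB))/2, interface residues by ΔSASA,
   hydrophobic fraction under a ɸ = {A,V,L,I,M,F,W,C,Y} / Ω = {Y,F,W}
   scheme, and connected hydrophobic surface patches.
4. **Split-motif scanning.** Position-specific scoring matrices (log-odds
   with background-distributed pseudocounts) built from seed instances,
   scanning for three-segment split motifs with spacer-length constraints
   (the CALM repeat architecture, 2–5 copies per scaffold) and for single
   tandem motifs such as the 37-residue GP-rich repeat.

## Worked example

```python
import calmscape as cs

# 1. the entropy <-> identity calibration used for surface colouring
cs.majority_column_entropy(0.97)   # 0.322 bits
cs.identity_for_entropy(0.3)       # 0.9723 -> "H = 0.3 is ~97% identity"

# 2. superpose a noisy structure pair with two planted 10 Å outliers
spec = cs.StructurePairSpec(n_residues=50, rotation_axis=(0.3, 0.4, 0.8),
                            rotation_angle=1.1, translation=(5, -3, 2),
                            noise_sd=0.1, n_outliers=2,
                            outlier_displacement=10.0, seed=1)
a, b, truth = cs.generate_structure_pair(spec)
corr, ca, cb = cs.correspondence_from_residues(a, b, "A", "A", "backbone")
res = cs.iterative_superpose(corr, ca, cb, reject_unit="residue")
# -> RMSD 0.182 Å over 192 atoms (2 cycles)
# -> rejected residues [18, 31] == truth["outlier_residues"]

# 3. interface of a synthetic all-hydrophobic two-chain complex
model, _ = cs.generate_complex(cs.ComplexSpec(chain_sizes=(16, 16),
                                              interface_spacing=4.0, seed=3))
rep = cs.interface_bsa(model, "A", "B")
# -> BSA 281.8 Å², hydrophobic fraction 1.00
```

The RMSD line reads like the output of interactive superposition tools:
0.182 Å is the residual coordinate noise over the 192 retained backbone
atoms after the two genuinely displaced residues were rejected — exactly
the planted ground truth. The buried area quantifies the planar contact of
the synthetic complex; the hydrophobic fraction of 1.0 reflects the fully
hydrophobic planted interface.

The same stages are available as shell commands (`calmscape simulate`,
`entropy`, `entropy-map`, `superpose`, `interface`, `patches`,
`motif-build`, `motif-scan`); every run writes a `manifest.json` with
parameters, seed and input hashes, and reruns are byte-identical.

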