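# Methods

This note documents the models, parameter choices and numerical
conventions behind `lrrpockets`, and what the synthetic study conditions
do and do not establish about real data.

## The inference problem

A peptide family (here patterned on the SCOOPs: 13–15 residue mature
peptides cut from divergent precursors, sharing an SxS/SxT motif at mature
positions 5 and 7) is perceived by an LRR receptor kinase. Candidate
homologues of both partners are mined comparatively; the receptor clade's
ectodomain alignment is projected onto its repeat architecture to reveal
conserved surface patches; predicted complex structures are filtered by
interface confidence and their contacts are read off geometrically. The
pipeline's claim is structural-evolutionary concordance: the residues
predicted to bind the motif lie inside the conserved patch.

## Synthetic study conditions

`simulate.SimConfig` fixes the conditions every test and driver runs
under. Defaults:

| parameter | default | meaning |
| --- | --- | --- |
| `n_species` | 37 | receptor homologues in the family (clade size) |
| `n_repeats` | 24 | LRR units per ectodomain (the curation criterion) |
| `tree_depth` | 0.4 | root-to-tip depth, substitutions/site |
| `background_rate` | 6.0 | relative rate of exposed non-patch sites |
| `internal_rate` | 1.0 | relative rate of buried variable sites |
| `patch_rate` | 0.02 | relative rate inside the planted patch |
| `patch_cells` | repeats 9–12 × all 8 exposed offsets | planted conserved band |
| `n_clusters` / `peptide_species` | 10 / 8 | precursor families × species |
| `mature_length` | 13 | mature window (13–15 supported) |
| `mature_divergence` | 0.2 | per-site divergence inside the mature window |
| `flank_divergence` | 0.35 | per-site divergence of propeptide/tail |
| `planted_contacts` | (246,5) (268,5) (292,7) (294,7) (316,7) | toy pocket truth |
| `n_confident_models` / `n_decoy_models` | 12 / 3 | toy ensemble composition |

The canonical LRR unit is the 24-residue framework
`LxxLxLxxLxLxxNxLxGxIPxxx` (anchors fixed, `x` variable); solvent-exposed
offsets default to the eight variable positions of the concave-face
segment, `(4, 6, 7, 9, 11, 12, 14, 16)`. With a 20-residue N-cap this
places receptor residues 246/268 and 292/294/316 — the pocket residues the
toy complexes plant — on distinct exposed grid cells in repeats 9–12.

Receptor families evolve by per-site independent replacement (no indels,
so alignments are gap-free and curation is exact) along a Kingman-style
random coalescent tree rescaled to `tree_depth`. Exposed non-patch sites
evolve fast enough to approach compositional saturation: this is the
diversifying-selection regime RCM presumes, and it is what creates the
yellow-vs-blue contrast between the planted band and the background.
Consequences worth knowing: overall leaf-to-leaf identity (~0.6–0.9
depending on tree shape) is below what a real receptor clade shows,
because the simulation exaggerates surface divergence to make the planted
signal unambiguous at 37 sequences; and phylogenetic correlation still
leaves occasional background columns split between two clade-specific
residues, which a per-column entropy score rates as moderately conserved
(a 50/50 column scores `1 − 1/log2 20 ≈ 0.77`). The 5×5 regional
smoothing absorbs these.

The planted patch is a full-width band across the exposed face of four
consecutive repeats rather than an island with free columns on both
sides. This is deliberate: with the center-weighted kernel, a cell just
outside a laterally-bounded patch sits in a window nearly as rich in
patch cells as a patch corner does, and edge truncation renormalises it
upward, so no background contrast makes an island patch exactly
recoverable at the default quantile. A band — the binding-canyon geometry
of the motivating receptor — has no lateral boundary, and recovery is
then stable (top-quantile cells ⊇ patch, Jaccard ≈ 0.82, across seeds).

Precursor families share a per-family consensus; mature windows diverge
at 0.2 per site (motif positions invariant), flanks at 0.35. Flank
divergence sits deliberately between the mature divergence and full
randomness: high enough that the mature window is the most conserved
stretch (so profile-based window selection is well-posed), low enough
that family members remain recognisably homologous over their full
length (so clustering can recover the planted partition). A fraction
(default 0.2) of families carries SxT instead of SxS.

Toy complexes are geometric, not physical: receptor pseudo-residues
(N, CA, C, O, CB and one polar side-chain atom) on a solenoid of radius
16 Å, the peptide extended along the axis at 4.6 Å per residue, and each
planted contact realised by placing the receptor residue's polar atom
2.9 Å from the peptide residue's polar atom. The generator verifies after
placement that every planted pair is within the hydrogen-bond cutoff and
every non-planted pair exceeds the 4.0 Å contact cutoff by ≥ 0.5 Å, and
rejects infeasible requests (e.g. one receptor residue in two contacts).
Confident ensemble members are coordinate-jittered replicates
(σ = 0.05 Å) with ipTM drawn in 0.85–0.95; decoys carry unrelated
contacts and ipTM 0.45–0.70.

What passing tests do **not** show about real data: robustness to
alignment gaps and indel evolution, to mis-annotated gene models, to
profile-HMM-grade remote homology, or to the noisy side-chain geometry of
real predicted complexes. The generators are clean by construction; the
pipeline's thresholds are defaults to be recalibrated on real inputs.

## Numerical and algorithmic choices

**Alignments and E-values.** All pairwise alignments (local links,
clustering identity, global similarity) use BLOSUM62 with affine gaps
11/1 through biopython's `PairwiseAligner`; ties follow its deterministic
first-alignment rule. E-values use fixed Karlin–Altschul parameters for
that scheme (λ = 0.267, K = 0.041) with search space m·n; parity with any
specific BLAST release is out of scope.

**Clustering identity.** An edge requires a significant local alignment
(E < 1e-3) *and* identity ≥ 0.45, where identity divides identities by
max(alignment length, 20). Both guards exist because optimal local
alignments between unrelated ~50-residue proteins are short (4–8 columns)
and often near-perfect; without them single-linkage chains unrelated
families together. Cluster numbering is by smallest member id.

**Mature-window selection.** Within a family alignment, candidate
windows must have their fixed motif positions (S at 5, S/T at 7 by
default) conserved in ≥ 90% of rows; among candidates the window with
maximal summed per-column information wins (smallest start on ties). The
motif anchor is essential: at eight members per family, information
estimates alone are noisy enough to shift the window by ±1 column.

**PSSM.** Position frequencies `(counts + α·background)/(n + α)` with
α = 1 and a Robinson–Robinson background; log-odds in bits; with α = 0,
unobserved residues receive a finite −30-bit floor so profiles stay
finite. Scanning is a sliding log-odds sum; hits sort by score then
(id, offset).

**Repeat detection.** Greedy left-to-right scan; a 24-residue window is a
unit when ≤ 2 of its 10 framework anchors mismatch; matched windows never
overlap. Curation keeps candidates whose count equals the criterion
(default 24) and, when an alignment row is supplied, rejects rows with a
gap column whose flanking residues are not inside one repeat segment
(`gap_outside_repeats`). Every rejection carries a machine-readable
reason, and kept ∪ rejected partitions the input.

**Neighbor joining.** Canonical Saitou–Nei with the Q-criterion; ties
broken by the lexicographically smallest taxon pair; negative branch
lengths clamped to zero with a logged warning. Rooting for clade
extraction splits the outgroup's edge at its midpoint, so the root
separates outgroup from ingroup cleanly; the extracted clade is the MRCA
subtree of the seeds. NJ stands in for a maximum-likelihood phylogeny
because downstream stages consume only clade membership, never branch
support.

**RCM.** Per-column conservation is normalised Shannon entropy
(pseudocount-compatible; gaps excluded from counts, gap fraction reported
separately); a BLOSUM62 mean-pairwise alternative ships behind
`statistic="blosum"`. The regional kernel is `1/(1 + Chebyshev ring)` —
center 1, ring one 1/2, ring two 1/3 — applied as a convolution of the
raw grid divided by a convolution of ones, which implements
truncate-and-renormalise edge handling exactly (edge scores remain means
of real cells, never of padding). The kernel and column statistic are
pluggable because the published form of the original mapping method does
not pin either down.

**Confidence filters.** Both ipTM thresholds are strict: 0.84 (AFM
scheme) and 0.8/0.6 (AF3 scheme) demote boundary values. Models without
a sidecar score are loaded, flagged, and rejected by the filter.

**Hydrogen bonds.** N/O–N/O pairs within 3.5 Å; the donor angle
(antecedent–donor–acceptor ≥ 120°) is checked for whichever orientation
has its antecedent heavy atom present, and skipped when absent —
predicted models may lack hydrogens and side-chain completeness, so the
check degrades gracefully to distance-only.

**Enrichment.** Observed statistic is the mean *regional* (smoothed)
conservation of the contact cells — the quantity the conservation maps
display — against `N_perm` uniform draws of equal-size cell sets without
replacement; `p = (1 + #{null ≥ obs})/(1 + N_perm)` never returns zero.
The null is unstratified by design (the claim contrasts contact cells
against the ectodomain surface at large); a row-stratified variant would
be the natural extension for receptors with strong per-repeat rate
gradients. The test is this package's formalization of a qualitative
claim and is labelled as such in every report.

## Problem sizes

Default test and driver scale: 37 receptors × 616 residues, 10 precursor
families × 8 species + 20 decoys, 8 species' gene tables, 15 complex
models of ~630 residues, permutation tests at N_perm = 199–999 and the
calibration experiment at 200 repetitions. The full test suite runs in
well under a minute of compute-heavy work plus alignment overhead.

## Known limitations

* No indel evolution, hence no test coverage for gapped repeat regions;
  the curation gap rule is exercised only on constructed alignments.
* The PSSM is an explicit simplification of a profile HMM — no
  position-specific indel states, no E-value calibration for scans.
* Toy complex geometry is pseudo-atomic; hydrogen-bond detection on real
  models should be validated against a dedicated tool before use in
  anger.
* Percent-similarity bands, clade sizes and enrichment magnitudes
  produced by the drivers describe the synthetic conditions, not any
  real receptor family.
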