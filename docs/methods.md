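# Methods

This note documents the models implemented in novocomp, the defaults and
why they were chosen, the numerical details that affect results, what the
synthetic-data generator does and does not emulate, and the known limits
of each stage.

## Genome signature (ρ\* and δ\*)

For a genome *f*, counting runs over every replicon's forward strand and
its reverse complement (strand symmetrisation), never across a replicon
junction or the forward/reverse seam; dinucleotide windows containing an
ambiguous base are skipped, and mononucleotide frequencies are taken over
all unambiguous bases. The relative abundance of dinucleotide XY is
ρ\*<sub>XY</sub> = f\*<sub>XY</sub>/(f\*<sub>X</sub>f\*<sub>Y</sub>), which is 1
under mononucleotide independence; symmetrisation forces
ρ\*<sub>XY</sub> = ρ\*<sub>revcomp(XY)</sub> exactly. Genome dissimilarity is
the average absolute difference δ\*(f,g) = (1/16)Σ|ρ\*<sub>f</sub> −
ρ\*<sub>g</sub>|, reported ×1000 by convention; it is 1/16 of an L1 distance
and therefore a metric. Degenerate IUPAC bases other than N are normalised
to N at parse time because the statistics are defined over {A,C,G,T}.

Representation classes use the empirical ranges: below 0.55 extreme
under-representation, 0.55–0.78 under, 0.78–1.23 normal, 1.23–1.30 over,
above 1.30 extreme over-representation. Exact boundary values are assigned
to the lower class (the ranges are quoted with strict inequalities).

Plasmids are included in the genome-wide profile by default; a
`chromosome_only` flag restricts to labelled chromosomes.

## Homology search, AAI

The search primitive is all-vs-all local alignment (Smith–Waterman,
BLOSUM62, affine gaps open 11 / extend 1) via Biopython's C aligner.
Percent identity is identities over aligned columns including internal
gaps (the BLAST convention). E-values use Karlin–Altschul statistics with
the published gapped BLOSUM62(11,1) parameters λ = 0.267, K = 0.041 on an
m·n search space (n = total subject proteome length); these constants are
module-level and recorded in run manifests. Non-amino-acid characters are
masked to X with a warning.

AAI is the unweighted mean identity over reciprocal best hits: (a,b) is
kept iff b is a's top-scoring hit and vice versa, ties broken by higher
identity then lexicographic subject id, so the pairing — and hence
AAI(a,b) = AAI(b,a) — is deterministic. Defaults follow the conventional
AAI protocol: identity ≥ 30 %, alignment covering ≥ 70 % of the *shorter*
sequence, E ≤ 1e-6. One-way best-hit averaging is available behind a flag;
RBH is the default because it is the standard orthology proxy.

## Pan-genome partition

Orthologous groups are connected components of the union of per-pair RBH
graphs at identity ≥ 65 %, aligned columns ≥ 70 % of the *longer* sequence
(the stricter reading of "70 % of protein sequence length"; a flag switches
to shorter), E ≤ 1e-10. When a query has several candidate partners at
exactly tied score, the tie is broken by conservation of gene order: the
candidate whose flanking ±3 genes share more provisional best-hit partners
with the query's flanks wins. This deliberately simplifies the full
weighted score-ratio + gene-order scheme of dedicated pan-genome tools:
the contract here is the partition at the stated cutoffs, keeping the
gene-order idea only where it decides anything (paralog resolution). On
draft inputs without gene order the tie-break degrades to score only, with
a logged notice.

Every protein lands in exactly one cluster (unmatched proteins become
singleton clusters), so Venn-cell counts over genome subsets sum to the
total cluster count. Singletons are clusters of size one; for genomes with
labelled replicons the fraction of singletons on plasmids is reported
(integer-rounded), and is flagged not-computable for drafts. Connected
components can chain clusters transitively; this is accepted as standard
behaviour at these stringencies.

## Trait screens

Screens retain the best passing reference hit per query at identity ≥ 30 %
and E ≤ 1e-6; an empty result is a meaningful negative (the Nqr sodium
pump screen is used that way: its absence, with an ectoine cassette
present, is the organic-osmolyte signature of marine adaptation).

* **LuxI triad** — the candidate is globally aligned to a designated
  reference synthase and the residues in the columns of reference
  positions 24/28/34 must be R/F/W; a gap in any of those columns fails.
  The numbering frame is the shipped reference synthase and is
  configurable, since triad positions are only meaningful relative to a
  stated reference.
* **LuxR solo** — a LuxR-screen hit with no LuxI-screen hit within ±5
  genes on the same replicon.
* **Rieske spacing** — first regex match of C-x-H-x(13..25)?-C-x-x-H
  (non-greedy); the gap bounds bracket both the canonical 17 and the
  variant 19 with margin; extra matches are logged, the first is
  reported.
* **Ectoine cassette** — complete iff at least one hit to each of
  EctA/EctB/EctC lies within a single 20 kb window on one replicon
  (the minimal covering span is reported).
* **pI** — net charge Z(pH) by Henderson–Hasselbalch over the termini and
  D,E,C,Y,H,K,R side chains with the EMBOSS pKa set (N-term 8.6, C-term
  3.6, C 8.5, D 3.9, E 4.1, H 6.5, K 10.8, R 12.5, Y 10.1); pI is the
  bisection root on [0,14] to 0.001. Z is strictly decreasing in pH, so
  the root is unique; the termini always ionise, so every non-empty
  sequence has a pI. Published tools differ in their pKa tables by about
  ±0.1 pH unit, which is the tolerance to use when comparing medians
  across tools. X residues carry no charge.

### Reference sets

The shipped sets under `src/novocomp/data/` are deterministic *synthetic
stand-ins* (generated by `novocomp.refsets`, fixed seed, `synthetic` in
every filename): reviewed-database sequences are not redistributable
here. They carry the diagnostic features the screens test — the triad in
the LuxI family, a canonical 17-spacing Rieske site in the dioxygenase
family, a 162-residue EctA — so that screen/verdict logic is fully
exercised; matching *real* proteomes requires swapping in user-supplied
FASTA sets, which every screen accepts.

## Distance phylogenomics

On pre-aligned protein FASTA (alignment construction is out of scope):
p is the mismatch fraction over columns ungapped in both rows (pairwise
deletion), and d = −ln(1 − p) is the Poisson-corrected distance;
saturated pairs (p ≥ 1) raise and are excluded. Neighbor joining follows
Saitou–Nei with Q-matrix joins; negative branch estimates are clamped to
zero. Tied Q values are detected with a relative tolerance of 1e-10 —
mathematically equal Q values can differ in the last floating-point ulp,
which would otherwise defeat the documented taxon-order tie-break — and
resolved toward the lexicographically smallest member taxon, making the
topology deterministic. Bootstrap resamples alignment columns with
replacement, rebuilds distance + NJ per replicate, and maps the
percentage of replicates containing each bipartition onto the full-data
tree (not a majority-rule consensus); replicates where any pair saturates
are dropped from the denominator. A single seed governs all resampling.

The end-to-end pipeline has no alignment, so its tree uses the same
Poisson/NJ machinery on d(a,b) = −ln(AAI(a,b)/100) — the mean RBH
mismatch fraction — with support from resampling the per-pair RBH
identity lists. This is a pragmatic whole-proteome distance, not a
substitute for the alignment-based route when one exists.

## Synthetic worlds

Nucleotide replicons are first-order Markov chains started at their
stationary distribution, so the expected ρ\* of every genome follows in
closed form from π and the transition matrix (symmetrised with the
reverse-complement chain). Proteomes are ortholog families: each family
member is independently mutated from a common ancestor at per-site rate
s = 1 − √t, giving expected pairwise identity ≈ t (plus a negligible
convergent-substitution term); replacements are BLOSUM62-weighted and
there are no indels. Markers are planted with controlled properties and
exact coordinates; CDS translations are written directly into GenBank
features, decoupling nucleotide from protein content the way the analyses
themselves are decoupled.

The default world has six genomes shaped like the motivating study:
24 core families at 85 % identity, a marine pair with 12 unique-core
families at 90 % plus an ectABC cassette (at 90 %, so the cassette genes
join the pair's unique core), five LuxI candidates across four genomes,
a LuxR solo and plasmid-borne singletons on a complete multi-replicon
genome, and Rieske spacings 17 and 19. Proteomes are 32–55 proteins per
genome — real genomes have thousands of CDS; the scale-down keeps
all-vs-all alignment within a single-CPU test budget and does not change
what any stage computes, only the sampling noise around planted values.

What a green test does *not* establish: the generator has no indels, no
rearrangements, no tree-structured divergence (all family members are
equidistant from the ancestor, so synthetic AAI is nearly flat across
pairs and the pipeline tree's internal supports are honestly low — pair
structure shows instead in δ\* and the unique-core partition), no
gene-content evolution, and no correlation between nucleotide composition
and protein composition (synthetic proteome pI medians sit near 7 rather
than the acidic medians typical of real proteomes). Reproducing the
published numbers for the real six genomes requires downloading the
deposited accessions and running the same pipeline; the offline suite
checks the machinery against analytic and planted truth instead.

## Determinism

Every stochastic step takes an explicit seed: scenario generation derives
per-genome streams from the scenario seed via CRC32 of the genome id (not
Python's salted `hash`), and identical spec + seed yields byte-identical
GenBank/FASTA/JSON output. Pipeline reruns with the same config and seed
produce identical bundles.
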