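# Methods

This note documents the models, conventions and deliberate design choices
behind the package, in the spirit of a methods appendix: what each
component assumes, which parameters matter, and what the tests do and do
not demonstrate.

## Pairwise alignment kernel

Global (Needleman–Wunsch) and local (Smith–Waterman) alignment use the
Gotoh three-state recurrence with affine gap costs. A gap of length L costs
`gap_open + L·gap_extend` (the BLAST convention: the first gapped position
costs open+extend, each further position extend). Defaults:

| parameter | nucleotide | protein |
|---|---|---|
| substitution | match +5 / mismatch −4 | BLOSUM62 |
| gap_open | 10 | 11 |
| gap_extend | 0.5 | 1 |

These are BLAST-style community defaults; the literature that uses
AGIOS-type statistics does not publish its alignment parameters, so every
cross-study comparison of absolute AGIOS values carries an
implementation tolerance of this kind. All parameters are configurable.

Numerical/determinism choices:

* Traceback tie-break: diagonal > up (gap in the second sequence) > left,
  and the match state is preferred over gap states, so output alignments
  are unique and tests can assert exact strings.
* `N` scores as a mismatch against every base **including N**, and an N–N
  column never counts toward identity — conservative on draft genomes.
* Terminal gaps are penalized (true global alignment); a semi-global
  variant (`free_end_gaps=True`) is exposed but not used by default.
* Percent identity defaults to matches over **all alignment columns**;
  `ungapped_columns` and `shorter_seq` denominators are provided because
  published identity values rarely state their denominator, and the choice
  moves values by whole percentage points on gappy alignments.
* The dynamic-programming fill is numba-JIT-compiled; the first call in a
  process pays a one-off compilation cost of a few seconds.

Correctness is established two independent ways: exhaustive enumeration of
every alignment path on small inputs (all sequence pairs over {A,C} up to
length 4, plus fixed-seed samples at lengths 5–8 — the full sweep to
length 8 is combinatorially explosive for a path-enumeration oracle, so
sampling covers the longer lengths), and score agreement with Biopython's
`PairwiseAligner` on random nucleotide and protein pairs.

## Orthology (reciprocal best hits)

Candidate pairs must share ≥ 2 distinct protein 5-mers (a deterministic
replacement for BLAST seeding that makes all-vs-all comparison of a few
thousand genes feasible on one core), are scored by Smith–Waterman on
proteins, and survive if score ≥ the scheme's 25-residue exact-match
equivalent, identity ≥ 25 %, and coverage ≥ 50 % of the shorter protein.
Best hits tie-break on score, then identity, then lexicographic subject id.
A pair is orthologous iff each member is the other's best hit; the mapping
is one-to-one. Co-ortholog groups (Proteinortho's algebraic-connectivity
clustering) are deliberately out of scope — a known fidelity gap relative
to the original workflow, acceptable because pair counts, not groups, feed
the downstream statistic. Genes flagged at extraction (length not a
multiple of 3, internal stop) are excluded from orthology by default, as
draft-genome annotations commonly contain pseudogene fragments.

## AGIOS

Orthology runs on proteins; identity is then computed on the corresponding
nucleotide ORFs with Needleman–Wunsch. This two-alphabet flow is the
defining feature of the statistic and is fixed. The mean is unweighted
across ortholog pairs (no length weighting, no identity floor); table
output truncates to 2 decimals. AGIOS is symmetric by construction (each
unordered pair is computed once), and self-comparison is exactly 100.00
with one ortholog per gene.

## 16S identity and the species boundary

Identity is global-alignment percent identity (default scheme and
denominator), reported to 1 decimal. The subject is tried on both strands
and the better orientation kept, since public 16S deposits vary in
orientation. The decision rule: top-hit identity **strictly below** 98.7 %
→ `candidate_new_species`; identity equal to the threshold is not novel.
The threshold is a parameter (`--threshold`). The genus-level identity
range sometimes quoted alongside such analyses is annotation, not part of
the rule.

## Distance phylogeny

Distances from a consumed (not constructed) MSA under p-distance (default),
Jukes–Cantor or Kimura-2-parameter, with pairwise deletion of gapped
columns — the common default of desktop phylogeny software. Building the
MSA itself is out of scope. Neighbor-joining is the standard Saitou–Nei
Q-criterion agglomeration; ties in Q break on the smallest index pair,
negative branch-length estimates are clamped to zero. On additive matrices
NJ provably recovers the generating tree; the tests verify exact recovery
(patristic distances equal to the input, which for positive-length binary
trees pins down topology and lengths jointly) on 100 random 4–8-taxon
trees.

Bootstrap: alignment columns are resampled with replacement per replicate,
NJ is run per replicate, and bipartition frequencies (integer percent)
decorate a strict-majority (> 50 %) consensus. Zero-length internal edges
are collapsed in each replicate before counting, so data with no signal
yields an unresolved star rather than spuriously supported splits that
would otherwise arise from deterministic tie-breaking on all-zero
distance matrices. Trees are unrooted; rooting on a named outgroup leaf is
a display option. Tree containers, newick round-trips and the consensus
operation use dendropy.

## Genome statistics and COG tables

* G+C: numerator counts G and C only; denominator is **total** assembly
  length including N. Reported rounded to 1 decimal (the one rounded
  quantity, matching how G+C is conventionally printed).
* Coding density: union of coding intervals per contig (overlapping and
  nested genes counted once), truncated to 2 decimals.
* All other table percentages truncate (never round) to 2 decimals —
  reproducing published table values such as 135/2,003 → 6.73 requires
  truncation.
* COG assignments are *input* (gene → category letters); searching against
  the COG database needs external references and is outside the package
  boundary. Percentages use the protein-coding gene count as denominator.
  Published genome tables are not always internally consistent about this
  denominator (a genome-summary table may count genes assigned to COGs
  differently from the COG table's own "not in COGs" row, and may print a
  total-gene count whose companion percentages imply a slightly different
  total); both conventions are available and each output labels its
  denominator.
* Coordinates are 0-based half-open in memory and 1-based inclusive in the
  annotation TSVs (converted at the I/O boundary).

## Synthetic data generator

The simulator provides the ground truth every other module is tested
against. The ancestor is a single contig of `n_genes` ORFs (ATG start,
random stop, internal stops purged, lengths ≈ N(mean, mean/6) rounded to
codons, ≥ 33 bp) with random 50–150 bp spacers, at a target G+C hit within
±2 points for assemblies ≥ 50 kb. Evolution applies, per retained gene:

* **Substitution**: each site mutates with probability p to one of the
  three *other* bases uniformly, so expected per-site identity is exactly
  1 − p — the closed form used for parameter recovery (`expected_identity`).
  No transition/transversion bias by default.
* **Indels**: Poisson(`indel_rate`) per gene, lengths exponential with the
  configured mean, rounded to multiples of 3 (frame-preserving) by default;
  a frameshift mode exercises the pseudogene-flagging path.
* **Gene loss** with probability `gene_loss_p`; **gene gain** appends novel
  random ORFs.
* Mutated start/stop codons are repaired (re-imposed) by default so gene
  counts stay stable for counting tests; repairs touch ≤ 2 codons per gene
  and bias mean identity by ≈ (6/L)·p·100 points (≈ 0.03 at p = 0.05,
  L = 900), far below the ±1-point recovery tolerance. A strict mode flags
  instead of repairing.

All randomness flows from one `numpy` generator seeded by `seed`; identical
parameters give byte-identical output.

What the simulator does **not** emulate: codon-usage and amino-acid
composition realism, rate heterogeneity across sites and genes, paralogy
and gene families, recombination, rearrangement, contig fragmentation and
assembly gaps. Passing parameter-recovery tests therefore demonstrates the
pipeline's internal consistency under a clean substitution model, not
accuracy on real draft genomes, where annotation errors and paralogs
degrade RBH precision.

## Scale of the bundled checks

The acceptance script and tests use 100 genes × ~900 bp × 5 seeds per
substitution level for AGIOS recovery (≈ 30 s), 100 random additive
matrices for NJ, 100 bootstrap replicates, and enumeration-oracle sweeps up
to sequence length 8. These sizes were chosen as the smallest at which the
binomial noise of the recovery checks sits comfortably inside their
tolerances (per-gene identity at p = 0.05, L = 900 has σ ≈ 0.7 points, so
the mean over 500 genes has σ ≈ 0.03).

## Known limitations

* Reproducing published AGIOS/16S values for real genomes (e.g. the
  *Collinsella* comparisons that motivate the worked layouts) requires
  downloading the deposited assemblies; with unstated upstream alignment
  and orthology parameters, printed AGIOS values are reproducible only to
  within a few percentage points. No bundled test depends on downloads.
* One-to-one RBH underestimates shared gene content in the presence of
  recent paralogs.
* Bootstrap supports depend on the distance model and gap treatment; only
  property-level behavior (determinism, clean-signal support, star on no
  signal) is asserted.
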