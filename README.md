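# taxogenomics

Genome-sequence components of taxono-genomic bacterial species description —
the strategy that circumscribes a new species by combining 16S rRNA
phylogeny with whole-genome comparison instead of wet-lab DNA–DNA
hybridization. The package is aimed at microbial taxonomists and
bioinformaticians who have an annotated draft genome of a candidate isolate
and want reproducible, scriptable versions of the standard computational
steps:

* **AGIOS** (Average Genomic Identity Of gene Sequences): orthologous genes
  between two genomes are detected by reciprocal best hits (RBH) on the
  *protein* sequences, the corresponding *nucleotide* ORFs are globally
  aligned, and AGIOS is the unweighted mean percent identity

  AGIOS(A, B) = (1/|O|) · Σ_{(x,y) ∈ O} 100 · m(x,y) / L(x,y)

  over the ortholog set O, with m the number of identical columns and L the
  alignment length. Matrices over genome sets use the conventional layout:
  gene counts on the diagonal, shared-ortholog counts below, AGIOS above.
* **16S rRNA identity** against the 98.7 % species boundary: a top-hit
  identity strictly below the threshold flags a candidate new species.
* **Distance phylogeny**: p-distance / Jukes–Cantor / Kimura-2-parameter
  distances from an existing MSA, Saitou–Nei neighbor-joining, column
  bootstrap with majority-rule consensus, newick output.
* **Genome and COG statistics tables**: G+C content, coding density (union
  of coding intervals), COG functional-category profiles with the
  truncation conventions used in published genome descriptions.
* **A synthetic genome-pair simulator** (ancestor → evolved derivative with
  per-site substitutions, indels, gene loss/gain and a ground-truth
  ortholog table), so the whole pipeline is testable without downloads.

The pairwise alignment kernel (Needleman–Wunsch and Smith–Waterman with
affine gaps, Gotoh recurrence, numba-accelerated) is implemented in the
package and validated against exhaustive enumeration oracles and
Biopython's `PairwiseAligner`.

## Worked example

Simulate a 15-gene ancestor genome and a derivative evolved at per-site
substitution probability 0.05, then compute AGIOS between the pair:

```bash
taxgen simulate --n-genes 15 --mean-gene-length 300 --gc 0.6 \
    --sub-p 0.05 --seed 11 --out sim
taxgen agios --genomes sim/ancestor.fna,sim/derived.fna \
    --annotations sim/ancestor.tsv,sim/derived.tsv --out agios.tsv
cat agios.tsv
```

```
        ancestor  derived
ancestor   15     95.35
derived    15     15
```

Read this like a published ortholog/identity table: each genome has 15
protein-coding genes (diagonal), the two genomes share 15 orthologous genes
(below the diagonal), and the mean nucleotide identity of the globally
aligned ortholog pairs is 95.35 % (above the diagonal) — close to the
theoretical expectation 100·(1−0.05) = 95 % for this substitution level,
with finite-sample scatter. `taxgen stats` on the same ancestor prints the
genome report (size 5,685 bp, G+C 61.0 %, coding density 73.45 %, 15
genes); `taxgen rrna-identity`, `taxgen njtree` and `taxgen cog-table`
expose the remaining stages. Every command writes a JSON manifest next to
its output so runs can be reproduced byte-for-byte.

The same operations are available as a library:

```python
from taxogenomics import EvolutionParams, agios_pair, synthetic_pair

anc, der, truth = synthetic_pair(100, EvolutionParams(substitution_p=0.05, seed=11))
res = agios_pair(anc, der)
print(res.n_orthologs, res.mean_2dp)   # 100 94.96
```

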