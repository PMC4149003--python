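"""AGIOS — Average Genomic Identity Of gene Sequences.

For a pair of annotated genomes, orthologous genes are detected by
reciprocal best hits on the PROTEIN sequences, the corresponding
NUCLEOTIDE sequences are then globally aligned (Needleman-Wunsch), and
AGIOS is the unweighted arithmetic mean of the per-pair percent
identities. The two-alphabet flow (orthology on proteins, identity on
nucleotides) is deliberate and fixed.

Matrices over genome sets follow the conventional layout: gene counts on
the diagonal, shared ortholog counts in the lower triangle, AGIOS
percentages (truncated to 2 decimals) in the upper triangle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from ._format import truncate
from .align import DNA_SCHEME, ScoringScheme, needleman_wunsch, percent_identity
from .orthology import OrthologyParams, reciprocal_best_hits
from .seqio import GeneRecord

__all__ = ["AgiosPairResult", "AgiosMatrix", "agios_pair", "agios_matrix"]


@dataclass
class AgiosPairResult:
    genome_a_id: str
    genome_b_id: str
    n_orthologs: int
    mean_identity_percent: float | None  # None when no orthologs were found
    per_pair_identities: list[float] = field(default_factory=list)

    @property
    def mean_2dp(self) -> float | None:
        """Mean identity truncated to 2 decimals (table convention)."""
        if self.mean_identity_percent is None:
            return None
        return truncate(self.mean_identity_percent, 2)


@dataclass
class AgiosMatrix:
    genome_ids: list[str]
    gene_counts: dict[str, int]
    pair_results: dict[tuple[str, str], AgiosPairResult]

    def ortholog_count(self, a: str, b: str) -> int:
        return self._pair(a, b).n_orthologs

    def agios(self, a: str, b: str) -> float | None:
        return self._pair(a, b).mean_2dp

    def _pair(self, a: str, b: str) -> AgiosPairResult:
        key = (a, b) if (a, b) in self.pair_results else (b, a)
        return self.pair_results[key]

    def to_frame(self) -> pd.DataFrame:
        """Square table: diagonal gene counts, counts below, AGIOS above."""
        ids = self.genome_ids
        data = []
        for i, gi in enumerate(ids):
            row = []
            for j, gj in enumerate(ids):
                if i == j:
                    row.append(str(self.gene_counts[gi]))
                elif i > j:
                    row.append(str(self.ortholog_count(gi, gj)))
                else:
                    v = self.agios(gi, gj)
                    row.append("NA" if v is None else f"{v:.2f}")
            data.append(row)
        return pd.DataFrame(data, index=ids, columns=ids)

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for (a, b), res in sorted(self.pair_results.items()):
            rows.append((a, b, res.n_orthologs, res.mean_2dp))
        return pd.DataFrame(rows, columns=["genome_a", "genome_b", "n_orthologs", "agios"])


def agios_pair(
    genes_a: Sequence[GeneRecord],
    genes_b: Sequence[GeneRecord],
    ortho_params: OrthologyParams = OrthologyParams(),
    scheme: ScoringScheme = DNA_SCHEME,
    identity_mode: str = "all_columns",
) -> AgiosPairResult:
    """AGIOS for one genome pair.

    Genes flagged at extraction (frameshift/internal stop) are excluded from
    both orthology and the average unless the params say otherwise. A pair
    of genomes with zero surviving orthologs yields n_orthologs == 0 and an
    undefined (None) mean rather than an error.
    """
    genes_a = list(genes_a)
    genes_b = list(genes_b)
    gid_a = genes_a[0].genome_id if genes_a else "A"
    gid_b = genes_b[0].genome_id if genes_b else "B"
    omap = reciprocal_best_hits(genes_a, genes_b, ortho_params)
    nt_a = {g.gene_id: g.nt_seq for g in genes_a}
    nt_b = {g.gene_id: g.nt_seq for g in genes_b}
    idents: list[float] = []
    for ga, gb in omap.pairs:
        aln = needleman_wunsch(nt_a[ga], nt_b[gb], scheme)
        idents.append(percent_identity(aln, identity_mode))
    mean = sum(idents) / len(idents) if idents else None
    return AgiosPairResult(gid_a, gid_b, len(idents), mean, idents)


def agios_matrix(
    genomes: Sequence[tuple[str, Sequence[GeneRecord]]],
    ortho_params: OrthologyParams = OrthologyParams(),
    scheme: ScoringScheme = DNA_SCHEME,
    identity_mode: str = "all_columns",
) -> AgiosMatrix:
    """All-pairs AGIOS over >=2 annotated genomes (each pair computed once)."""
    if len(genomes) < 2:
        raise ValueError("agios_matrix requires at least two genomes")
    ids = [gid for gid, _ in genomes]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate genome ids")
    usable = {
        gid: [g for g in genes if not g.flagged or ortho_params.include_flagged]
        for gid, genes in genomes
    }
    gene_counts = {gid: len(usable[gid]) for gid in ids}
    results: dict[tuple[str, str], AgiosPairResult] = {}
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            a, b = ids[i], ids[j]
            res = agios_pair(usable[a], usable[b], ortho_params, scheme, identity_mode)
            res.genome_a_id, res.genome_b_id = a, b
            results[(a, b)] = res
    return AgiosMatrix(list(ids), gene_counts, results)
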