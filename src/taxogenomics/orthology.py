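"""Reciprocal-best-hit (RBH) orthology between two annotated genomes.

Orthologous pairs are detected on PROTEIN sequences: candidate pairs are
seeded by shared k-mers (a deterministic stand-in for BLAST seeding that
makes all-vs-all comparison of a few thousand genes feasible), scored by
Smith-Waterman, filtered on score/identity/coverage, and a pair (x, y) is
called orthologous iff y is x's best hit and x is y's best hit. The mapping
is one-to-one; co-ortholog groups are out of scope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .align import PROTEIN_SCHEME, AlignmentResult, ScoringScheme, smith_waterman
from .seqio import GeneRecord

__all__ = [
    "OrthologyParams",
    "SimilarityHit",
    "OrthologMap",
    "candidate_hits",
    "best_hit_table",
    "reciprocal_best_hits",
]


@dataclass(frozen=True)
class OrthologyParams:
    """Thresholds for candidate generation and hit filtering.

    Defaults follow common RBH practice: >=25% identity over the local
    alignment, >=50% coverage of the shorter protein, and a minimum score
    equivalent to a 25-residue exact match under the scoring scheme. The
    k-mer prefilter requires >=2 shared 5-mers between the two proteins.
    """

    kmer_size: int = 5
    min_shared_kmers: int = 2
    min_identity: float = 25.0
    min_coverage: float = 50.0
    min_score: float | None = None  # None -> 25 * scheme.exact_match_unit()
    include_flagged: bool = False

    def resolved_min_score(self, scheme: ScoringScheme) -> float:
        if self.min_score is not None:
            return self.min_score
        return 25.0 * scheme.exact_match_unit()


@dataclass
class SimilarityHit:
    query_id: str
    subject_id: str
    score: float
    identity_percent: float
    coverage_percent: float


@dataclass
class OrthologMap:
    genome_a_id: str
    genome_b_id: str
    pairs: list[tuple[str, str]]

    def __post_init__(self) -> None:
        a_ids = [a for a, _ in self.pairs]
        b_ids = [b for _, b in self.pairs]
        if len(set(a_ids)) != len(a_ids) or len(set(b_ids)) != len(b_ids):
            raise ValueError("ortholog map must be one-to-one")

    def __len__(self) -> int:
        return len(self.pairs)

    def swapped(self) -> "OrthologMap":
        return OrthologMap(self.genome_b_id, self.genome_a_id, [(b, a) for a, b in self.pairs])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.pairs, columns=["gene_id_a", "gene_id_b"])


def _proteins(genes: Iterable, include_flagged: bool) -> list[tuple[str, str]]:
    """Normalize a gene collection to (gene_id, aa_seq) pairs."""
    out = []
    for g in genes:
        if isinstance(g, GeneRecord):
            if g.flagged and not include_flagged:
                continue
            if not g.aa_seq:
                continue
            out.append((g.gene_id, g.aa_seq))
        else:
            gid, aa = g
            out.append((gid, aa))
    return out


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def coverage_percent(aln: AlignmentResult, len_a: int, len_b: int) -> float:
    """Aligned fraction of the shorter protein, in percent."""
    shorter = min(len_a, len_b)
    if shorter == 0:
        return 0.0
    covered = (aln.a_end - aln.a_start) if len_a <= len_b else (aln.b_end - aln.b_start)
    return 100.0 * covered / shorter


def candidate_hits(
    genes_a: Iterable,
    genes_b: Iterable,
    params: OrthologyParams = OrthologyParams(),
    scheme: ScoringScheme = PROTEIN_SCHEME,
) -> list[SimilarityHit]:
    """Score k-mer-seeded candidate pairs by Smith-Waterman and filter.

    Returns surviving hits for the directed comparison A -> B (scores are
    symmetric, so the same list serves B -> A with roles swapped).
    """
    prot_a = _proteins(genes_a, params.include_flagged)
    prot_b = _proteins(genes_b, params.include_flagged)
    if not prot_a or not prot_b:
        warnings.warn("empty gene set in orthology comparison", stacklevel=2)
        return []
    k = params.kmer_size
    index: dict[str, list[int]] = {}
    kmers_b: list[set[str]] = []
    for jb, (gid_b, aa_b) in enumerate(prot_b):
        if len(aa_b) < k:
            warnings.warn(f"protein {gid_b!r} shorter than k={k}; skipped", stacklevel=2)
            kmers_b.append(set())
            continue
        km = _kmers(aa_b, k)
        kmers_b.append(km)
        for w in km:
            index.setdefault(w, []).append(jb)
    min_score = params.resolved_min_score(scheme)
    hits: list[SimilarityHit] = []
    for gid_a, aa_a in prot_a:
        if len(aa_a) < k:
            warnings.warn(f"protein {gid_a!r} shorter than k={k}; skipped", stacklevel=2)
            continue
        shared: dict[int, int] = {}
        for w in _kmers(aa_a, k):
            for jb in index.get(w, ()):
                shared[jb] = shared.get(jb, 0) + 1
        for jb, n_shared in shared.items():
            if n_shared < params.min_shared_kmers:
                continue
            gid_b, aa_b = prot_b[jb]
            aln = smith_waterman(aa_a, aa_b, scheme)
            if aln.n_columns == 0:
                continue
            ident = aln.identity_percent or 0.0
            cov = coverage_percent(aln, len(aa_a), len(aa_b))
            if aln.score < min_score or ident < params.min_identity or cov < params.min_coverage:
                continue
            hits.append(SimilarityHit(gid_a, gid_b, aln.score, ident, cov))
    return hits


def best_hit_table(hits: Sequence[SimilarityHit]) -> dict[str, SimilarityHit]:
    """Best subject per query: highest score, then highest identity, then
    lexicographically smallest subject id."""
    best: dict[str, SimilarityHit] = {}
    for h in hits:
        cur = best.get(h.query_id)
        if cur is None:
            best[h.query_id] = h
            continue
        key_new = (h.score, h.identity_percent, _lex_inv(h.subject_id))
        key_cur = (cur.score, cur.identity_percent, _lex_inv(cur.subject_id))
        if key_new > key_cur:
            best[h.query_id] = h
    return best


class _lex_inv:
    """Ordering helper: smaller string compares as larger (for max-based ties)."""

    __slots__ = ("s",)

    def __init__(self, s: str):
        self.s = s

    def __lt__(self, other: "_lex_inv") -> bool:
        return self.s > other.s

    def __gt__(self, other: "_lex_inv") -> bool:
        return self.s < other.s

    def __eq__(self, other: object) -> bool:
        return isinstance(other, _lex_inv) and self.s == other.s


def reciprocal_best_hits(
    genes_a: Iterable,
    genes_b: Iterable,
    params: OrthologyParams = OrthologyParams(),
    scheme: ScoringScheme = PROTEIN_SCHEME,
    genome_a_id: str = "A",
    genome_b_id: str = "B",
) -> OrthologMap:
    """One-to-one ortholog pairs by reciprocal best hit on proteins."""
    genes_a = list(genes_a)
    genes_b = list(genes_b)
    if genes_a and isinstance(genes_a[0], GeneRecord):
        genome_a_id = genes_a[0].genome_id
    if genes_b and isinstance(genes_b[0], GeneRecord):
        genome_b_id = genes_b[0].genome_id
    hits_ab = candidate_hits(genes_a, genes_b, params, scheme)
    hits_ba = [SimilarityHit(h.subject_id, h.query_id, h.score, h.identity_percent, h.coverage_percent) for h in hits_ab]
    best_ab = best_hit_table(hits_ab)
    best_ba = best_hit_table(hits_ba)
    pairs = []
    for qa, hit in sorted(best_ab.items()):
        back = best_ba.get(hit.subject_id)
        if back is not None and back.subject_id == qa:
            pairs.append((qa, hit.subject_id))
    return OrthologMap(genome_a_id, genome_b_id, pairs)


def hits_to_frame(hits: Sequence[SimilarityHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [(h.query_id, h.subject_id, h.score, h.identity_percent, h.coverage_percent) for h in hits],
        columns=["query", "subject", "score", "identity", "coverage"],
    )
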