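"""Synthetic ancestor genomes and evolved derivatives with known truth.

The generator builds a single-contig genome of valid ORFs (ATG start, stop
end, no internal stop, target G+C) separated by random spacers, then evolves
it: per-site substitution with probability p (replacement by one of the
three OTHER bases uniformly, so expected per-site identity is exactly
1 - p), optional frame-preserving indels, gene loss and naive gene gain.
Every run is fully determined by the seed. The ground-truth ortholog table
(ancestor gene -> derived gene or lost, plus gained genes) is returned so
orthology and AGIOS can be scored against truth.

Mutated start/stop codons are repaired (re-imposed) by default so gene
counts stay stable for counting tests; a strict mode flags instead. Codon
repairs touch at most a few sites per gene and shift mean identity by well
under the tolerance of the parameter-recovery checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .seqio import ANNOTATION_COLUMNS, GeneRecord, GenomeRecord, extract_genes

BASES = np.array(list("ACGT"))
STOPS = ("TAA", "TAG", "TGA")

__all__ = [
    "EvolutionParams",
    "TruthTable",
    "generate_ancestor",
    "evolve",
    "expected_identity",
    "synthetic_pair",
]


@dataclass(frozen=True)
class EvolutionParams:
    substitution_p: float = 0.0
    indel_rate: float = 0.0  # expected indels per gene
    indel_length_mean: float = 9.0  # bases; multiples of 3 when frame-preserving
    gene_loss_p: float = 0.0
    gene_gain_n: int = 0
    seed: int = 0
    frame_preserving: bool = True
    repair: bool = True  # re-impose start/stop and purge internal stops

    def __post_init__(self) -> None:
        if not 0.0 <= self.substitution_p < 1.0:
            raise ValueError("substitution_p must be in [0, 1)")
        if not 0.0 <= self.gene_loss_p <= 1.0:
            raise ValueError("gene_loss_p must be a probability")
        if self.indel_rate < 0 or self.indel_length_mean <= 0 or self.gene_gain_n < 0:
            raise ValueError("invalid indel/gain parameters")


@dataclass
class TruthTable:
    """Ground-truth ortholog mapping between ancestor and derived genome."""

    rows: list[tuple[str, str | None]]  # (ancestor_gene_id, derived_gene_id or None if lost)
    gained: list[str] = field(default_factory=list)

    def ortholog_pairs(self) -> set[tuple[str, str]]:
        return {(a, d) for a, d in self.rows if d is not None}

    def lost(self) -> list[str]:
        return [a for a, d in self.rows if d is None]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            [(a, d if d is not None else "lost") for a, d in self.rows],
            columns=["ancestor_gene_id", "derived_gene_id"],
        )
        gained = pd.DataFrame(
            [("gained", g) for g in self.gained], columns=["ancestor_gene_id", "derived_gene_id"]
        )
        return pd.concat([df, gained], ignore_index=True)


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T
    return BASES[rng.choice(4, size=length, p=p)]


def _purge_internal_stops(body: np.ndarray) -> np.ndarray:
    """Replace the third base of any stop codon with C (TAC/TGC are sense)."""
    for i in range(0, len(body) - len(body) % 3, 3):
        codon = "".join(body[i : i + 3])
        if codon in STOPS:
            body[i + 2] = "C"
    return body


def _make_orf(rng: np.random.Generator, length: int, gc: float) -> str:
    body = _random_seq(rng, length - 6, gc)
    body = _purge_internal_stops(body)
    stop = STOPS[rng.integers(0, len(STOPS))]
    return "ATG" + "".join(body) + stop


def generate_ancestor(
    n_genes: int,
    mean_gene_length: int = 900,
    gc_target: float = 0.5,
    seed: int = 0,
    genome_id: str = "ancestor",
) -> tuple[GenomeRecord, pd.DataFrame]:
    """A single-contig genome of n_genes valid ORFs plus random spacers.

    Gene lengths are drawn around ``mean_gene_length`` (multiples of 3, >=33
    bp); genes are placed on random strands; coordinates are returned as an
    annotation table (0-based half-open in memory).
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if mean_gene_length < 33 or mean_gene_length % 3 != 0:
        raise ValueError("mean_gene_length must be a multiple of 3 and >= 33")
    if not 0.0 < gc_target < 1.0:
        raise ValueError("gc_target must be a fraction in (0, 1)")
    rng = np.random.default_rng(seed)
    parts: list[str] = []
    ann_rows = []
    pos = 0
    for i in range(n_genes):
        spacer = "".join(_random_seq(rng, int(rng.integers(50, 151)), gc_target))
        parts.append(spacer)
        pos += len(spacer)
        length = int(np.clip(rng.normal(mean_gene_length, mean_gene_length / 6), 33, None))
        length -= length % 3
        orf = _make_orf(rng, length, gc_target)
        strand = "+" if rng.random() < 0.5 else "-"
        placed = orf if strand == "+" else str(Seq(orf).reverse_complement())
        parts.append(placed)
        ann_rows.append(("contig_1", pos, pos + length, strand, f"g{i + 1:04d}"))
        pos += length
    parts.append("".join(_random_seq(rng, int(rng.integers(50, 151)), gc_target)))
    genome = GenomeRecord(genome_id, [("contig_1", "".join(parts))])
    annotations = pd.DataFrame(ann_rows, columns=ANNOTATION_COLUMNS)
    return genome, annotations


def _mutate(rng: np.random.Generator, seq: str, p: float) -> np.ndarray:
    arr = np.array(list(seq))
    if p <= 0:
        return arr
    mask = rng.random(len(arr)) < p
    n_mut = int(mask.sum())
    if n_mut:
        # replace each hit site by one of the three OTHER bases, uniformly
        idx = {b: k for k, b in enumerate(BASES)}
        cur = np.array([idx[b] for b in arr[mask]])
        shift = rng.integers(1, 4, size=n_mut)
        arr[mask] = BASES[(cur + shift) % 4]
    return arr


def _apply_indels(rng: np.random.Generator, arr: np.ndarray, params: EvolutionParams) -> np.ndarray:
    n_indels = rng.poisson(params.indel_rate)
    for _ in range(n_indels):
        if params.frame_preserving:
            length = 3 * max(1, int(round(rng.exponential(params.indel_length_mean / 3))))
        else:
            length = max(1, int(round(rng.exponential(params.indel_length_mean))))
        body_lo, body_hi = 3, len(arr) - 3  # keep start/stop codons intact
        if body_hi - body_lo < 3:
            continue
        if rng.random() < 0.5:  # insertion
            at = int(rng.integers(body_lo, body_hi + 1))
            gc_here = float(np.isin(arr, list("GC")).mean())
            ins = _random_seq(rng, length, gc_here)
            arr = np.concatenate([arr[:at], ins, arr[at:]])
        else:  # deletion
            length = min(length, body_hi - body_lo - 3)
            if length < 1:
                continue
            at = int(rng.integers(body_lo, body_hi - length + 1))
            arr = np.concatenate([arr[:at], arr[at + length :]])
    return arr


def _repair(arr: np.ndarray) -> np.ndarray:
    arr[0:3] = list("ATG")
    if "".join(arr[-3:]) not in STOPS:
        arr[-3:] = list("TAA")
    if len(arr) % 3 == 0:
        arr[3:-3] = _purge_internal_stops(arr[3:-3])
    return arr


def evolve(
    ancestor_genes: Sequence[GeneRecord],
    params: EvolutionParams,
    genome_id: str = "derived",
) -> tuple[GenomeRecord, pd.DataFrame, TruthTable]:
    """Evolve a gene set into a derived genome plus ground-truth table.

    Each retained gene is substituted site-wise and (optionally) hit by
    indels; lost genes are dropped; ``gene_gain_n`` novel ORFs are appended.
    The derived genome is reassembled with fresh random spacers — spacers
    are non-coding and carry no truth information.
    """
    rng = np.random.default_rng(params.seed)
    gc_pool = "".join(g.nt_seq for g in ancestor_genes)
    gc_anc = (gc_pool.count("G") + gc_pool.count("C")) / max(1, len(gc_pool))
    rows: list[tuple[str, str | None]] = []
    derived: list[tuple[str, str, str]] = []  # (gene_id, strand, orf)
    for g in ancestor_genes:
        if rng.random() < params.gene_loss_p:
            rows.append((g.gene_id, None))
            continue
        arr = _mutate(rng, g.nt_seq, params.substitution_p)
        if params.indel_rate > 0:
            arr = _apply_indels(rng, arr, params)
        if params.repair:
            arr = _repair(arr)
        did = f"d_{g.gene_id}"
        rows.append((g.gene_id, did))
        derived.append((did, g.strand, "".join(arr)))
    gained: list[str] = []
    mean_len = int(np.mean([g.end - g.start for g in ancestor_genes])) if ancestor_genes else 900
    mean_len -= mean_len % 3
    for i in range(params.gene_gain_n):
        length = max(33, mean_len)
        gid = f"gain{i + 1:03d}"
        gained.append(gid)
        strand = "+" if rng.random() < 0.5 else "-"
        derived.append((gid, strand, _make_orf(rng, length, gc_anc)))
    parts: list[str] = []
    ann_rows = []
    pos = 0
    for gid, strand, orf in derived:
        spacer = "".join(_random_seq(rng, int(rng.integers(50, 151)), gc_anc))
        parts.append(spacer)
        pos += len(spacer)
        placed = orf if strand == "+" else str(Seq(orf).reverse_complement())
        parts.append(placed)
        ann_rows.append(("contig_1", pos, pos + len(orf), strand, gid))
        pos += len(orf)
    parts.append("".join(_random_seq(rng, int(rng.integers(50, 151)), gc_anc)))
    genome = GenomeRecord(genome_id, [("contig_1", "".join(parts))])
    annotations = pd.DataFrame(ann_rows, columns=ANNOTATION_COLUMNS)
    return genome, annotations, TruthTable(rows, gained)


def expected_identity(params: EvolutionParams) -> float:
    """Closed-form expected percent identity, 100 * (1 - p); substitutions only."""
    if params.indel_rate > 0:
        raise ValueError("expected_identity has no closed form with indels enabled")
    return 100.0 * (1.0 - params.substitution_p)


def synthetic_pair(
    n_genes: int,
    params: EvolutionParams,
    mean_gene_length: int = 900,
    gc_target: float = 0.5,
) -> tuple[list[GeneRecord], list[GeneRecord], TruthTable]:
    """Convenience: ancestor genes, derived genes and truth table in one call."""
    genome, ann = generate_ancestor(
        n_genes, mean_gene_length, gc_target, seed=params.seed, genome_id="ancestor"
    )
    anc_genes = extract_genes(genome, ann)
    dgenome, dann, truth = evolve(anc_genes, params)
    der_genes = extract_genes(dgenome, dann)
    return anc_genes, der_genes, truth
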