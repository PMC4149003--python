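"""Sequence/annotation I/O, gene extraction and genome-level statistics.

Coordinates are 0-based half-open internally; the GFF-flavoured annotation
TSV read/written here uses 1-based inclusive coordinates (converted at the
I/O boundary). The only ambiguity code accepted in genomic sequence is N;
other IUPAC codes are rejected at parse time so the alignment scoring
contract stays simple.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

from ._format import round_percent_1dp, truncate_percent

DNA_ALPHABET = set("ACGTN")
PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYXBZJUO*")

ANNOTATION_COLUMNS = ["seqid", "start", "end", "strand", "gene_id"]


class SequenceFormatError(ValueError):
    """Raised for malformed FASTA/annotation input."""


@dataclass
class GenomeRecord:
    """A named, ordered set of contigs (uppercase DNA over A,C,G,T,N)."""

    genome_id: str
    contigs: list[tuple[str, str]]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        norm = []
        for cid, seq in self.contigs:
            if cid in seen:
                raise SequenceFormatError(f"duplicate contig id {cid!r} in genome {self.genome_id!r}")
            seen.add(cid)
            seq = seq.upper()
            if not seq:
                raise SequenceFormatError(f"empty sequence for contig {cid!r}")
            bad = set(seq) - DNA_ALPHABET
            if bad:
                raise SequenceFormatError(
                    f"contig {cid!r}: illegal characters {sorted(bad)} (only A,C,G,T,N accepted)"
                )
            norm.append((cid, seq))
        self.contigs = norm

    @property
    def size_bp(self) -> int:
        return sum(len(s) for _, s in self.contigs)

    def contig(self, contig_id: str) -> str:
        for cid, seq in self.contigs:
            if cid == contig_id:
                return seq
        raise KeyError(f"unknown contig {contig_id!r} in genome {self.genome_id!r}")


@dataclass
class GeneRecord:
    """A located, stranded coding gene with nucleotide and protein sequence.

    start/end are 0-based half-open on the forward strand. ``frame_ok`` is
    False when the length is not a multiple of 3; ``internal_stop`` is True
    when translation contains a stop before the terminal codon. Flagged
    genes are retained but excluded from protein-level orthology by default
    (draft annotations commonly contain pseudogene fragments).
    """

    gene_id: str
    genome_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    nt_seq: str
    aa_seq: str = ""
    frame_ok: bool = True
    internal_stop: bool = False

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene {self.gene_id!r}: strand must be '+' or '-'")
        if not (0 <= self.start < self.end):
            raise ValueError(f"gene {self.gene_id!r}: require 0 <= start < end")
        if len(self.nt_seq) != self.end - self.start:
            raise ValueError(f"gene {self.gene_id!r}: nt_seq length != end - start")

    @property
    def flagged(self) -> bool:
        return (not self.frame_ok) or self.internal_stop


@dataclass
class GenomeStats:
    genome_id: str
    genome_size_bp: int
    gc_bp: int
    gc_percent: float
    coding_bp: int
    coding_percent: float
    n_genes: int

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("Genome size (bp)", self.genome_size_bp, ""),
            ("DNA G+C content (bp)", self.gc_bp, f"{self.gc_percent:.1f}"),
            ("DNA coding region (bp)", self.coding_bp, f"{self.coding_percent:.2f}"),
            ("Protein-coding genes", self.n_genes, ""),
        ]
        return pd.DataFrame(rows, columns=["Attribute", "Value", "% of total"])


def read_fasta(path: str | Path, alphabet: str = "dna") -> list[tuple[str, str]]:
    """Read a FASTA file into (id, uppercased sequence) pairs.

    Wrapped lines are concatenated; duplicate ids and illegal characters
    are reported with the offending record id.
    """
    allowed = DNA_ALPHABET if alphabet == "dna" else PROTEIN_ALPHABET
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if rec.id in seen:
            raise SequenceFormatError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        if not seq:
            raise SequenceFormatError(f"{path}: record {rec.id!r} has empty sequence")
        bad = set(seq) - allowed
        if bad:
            raise SequenceFormatError(f"{path}: record {rec.id!r} has illegal characters {sorted(bad)}")
        records.append((rec.id, seq))
    if not records:
        raise SequenceFormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_genome(path: str | Path, genome_id: str | None = None) -> GenomeRecord:
    gid = genome_id if genome_id is not None else Path(path).stem
    return GenomeRecord(gid, read_fasta(path, alphabet="dna"))


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read a GFF-flavoured annotation TSV (1-based inclusive) to 0-based half-open."""
    df = pd.read_csv(path, sep="\t", dtype={"seqid": str, "gene_id": str})
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise SequenceFormatError(f"{path}: annotation table missing columns {sorted(missing)}")
    df = df[ANNOTATION_COLUMNS].copy()
    df["start"] = df["start"].astype(int) - 1  # to 0-based half-open
    df["end"] = df["end"].astype(int)
    return df


def write_annotations(df: pd.DataFrame, path: str | Path) -> None:
    """Write annotations (0-based half-open in memory) as 1-based inclusive TSV."""
    out = df[ANNOTATION_COLUMNS].copy()
    out["start"] = out["start"].astype(int) + 1
    out.to_csv(path, sep="\t", index=False)


def translate(nt: str, table: int = 11) -> str:
    """Translate a coding sequence under the bacterial genetic code.

    The terminal stop is stripped; internal stops are kept as '*' in the
    returned string so callers can flag the gene. Length must be >= 3 and a
    multiple of 3.
    """
    nt = nt.upper()
    if len(nt) < 3:
        raise ValueError("coding sequence shorter than one codon")
    if len(nt) % 3 != 0:
        raise ValueError("coding sequence length not divisible by 3")
    aa = str(Seq(nt).translate(table=table))
    if aa.endswith("*"):
        aa = aa[:-1]
    return aa


def extract_genes(genome: GenomeRecord, annotations: pd.DataFrame) -> list[GeneRecord]:
    """Slice annotated genes out of a genome and translate them.

    Minus-strand genes are reverse-complemented before translation. Genes
    whose length is not a multiple of 3, or whose translation contains an
    internal stop, are returned with warning flags set rather than dropped.
    """
    genes: list[GeneRecord] = []
    for row in annotations.itertuples(index=False):
        try:
            contig_seq = genome.contig(row.seqid)
        except KeyError as exc:
            raise SequenceFormatError(f"gene {row.gene_id!r}: {exc.args[0]}") from None
        start, end = int(row.start), int(row.end)
        if not (0 <= start < end <= len(contig_seq)):
            raise SequenceFormatError(
                f"gene {row.gene_id!r}: coordinates [{start},{end}) outside contig "
                f"{row.seqid!r} of length {len(contig_seq)}"
            )
        nt = contig_seq[start:end]
        if row.strand == "-":
            nt = str(Seq(nt).reverse_complement())
        frame_ok = len(nt) % 3 == 0
        aa = ""
        internal_stop = False
        if frame_ok and len(nt) >= 3:
            aa = translate(nt)
            if "*" in aa:
                internal_stop = True
        if not frame_ok or internal_stop:
            warnings.warn(
                f"gene {row.gene_id!r} flagged (frame_ok={frame_ok}, internal_stop={internal_stop})",
                stacklevel=2,
            )
        genes.append(
            GeneRecord(
                gene_id=str(row.gene_id),
                genome_id=genome.genome_id,
                contig_id=str(row.seqid),
                start=start,
                end=end,
                strand=str(row.strand),
                nt_seq=nt,
                aa_seq=aa,
                frame_ok=frame_ok,
                internal_stop=internal_stop,
            )
        )
    return genes


def gc_content(genome: GenomeRecord) -> tuple[int, int, float]:
    """(gc_bp, genome_size_bp, gc_percent rounded to 1 decimal).

    The denominator is total assembly length including N; only G and C
    count in the numerator.
    """
    gc = sum(s.count("G") + s.count("C") for _, s in genome.contigs)
    size = genome.size_bp
    return gc, size, round_percent_1dp(gc, size)


def coding_density(genome: GenomeRecord, genes: Sequence[GeneRecord]) -> tuple[int, float]:
    """(coding_bp, coding_percent truncated to 2 decimals).

    coding_bp is the length of the union of coding intervals per contig, so
    overlapping or nested genes are counted once.
    """
    by_contig: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        by_contig.setdefault(g.contig_id, []).append((g.start, g.end))
    coding = 0
    for intervals in by_contig.values():
        intervals.sort()
        cur_s, cur_e = intervals[0]
        for s, e in intervals[1:]:
            if s > cur_e:
                coding += cur_e - cur_s
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        coding += cur_e - cur_s
    size = genome.size_bp
    pct = truncate_percent(coding, size) if coding else 0.0
    return coding, pct


def genome_report(genome: GenomeRecord, genes: Sequence[GeneRecord]) -> GenomeStats:
    gc_bp, size, gc_pct = gc_content(genome)
    coding_bp, coding_pct = coding_density(genome, genes) if genes else (0, 0.0)
    return GenomeStats(
        genome_id=genome.genome_id,
        genome_size_bp=size,
        gc_bp=gc_bp,
        gc_percent=gc_pct,
        coding_bp=coding_bp,
        coding_percent=coding_pct,
        n_genes=len(genes),
    )
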