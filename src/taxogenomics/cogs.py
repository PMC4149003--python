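"""COG functional-category tabulation and cross-genome profile comparison.

Gene -> category assignments are INPUT (a TSV of gene_id and comma-separated
category letters); searching proteins against the COG database is outside
this package's boundary. Percentages follow the genome-table convention:
denominator = protein-coding gene count, values truncated (not rounded) to
two decimals. A gene may carry several categories (each increments its
category count); ``not_in_cogs`` counts genes with no category at all.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from ._format import truncate_percent

# fixed 25-letter vocabulary and its conventional table order
COG_CATEGORIES: list[tuple[str, str]] = [
    ("J", "Translation"),
    ("A", "RNA processing and modification"),
    ("K", "Transcription"),
    ("L", "Replication, recombination and repair"),
    ("B", "Chromatin structure and dynamics"),
    ("D", "Cell cycle control, mitosis and meiosis"),
    ("Y", "Nuclear structure"),
    ("V", "Defense mechanisms"),
    ("T", "Signal transduction mechanisms"),
    ("M", "Cell wall/membrane biogenesis"),
    ("N", "Cell motility"),
    ("Z", "Cytoskeleton"),
    ("W", "Extracellular structures"),
    ("U", "Intracellular trafficking and secretion"),
    ("O", "Posttranslational modification, protein turnover, chaperones"),
    ("C", "Energy production and conversion"),
    ("G", "Carbohydrate transport and metabolism"),
    ("E", "Amino acid transport and metabolism"),
    ("F", "Nucleotide transport and metabolism"),
    ("H", "Coenzyme transport and metabolism"),
    ("I", "Lipid transport and metabolism"),
    ("P", "Inorganic ion transport and metabolism"),
    ("Q", "Secondary metabolites biosynthesis, transport and catabolism"),
    ("R", "General function prediction only"),
    ("S", "Function unknown"),
]
COG_LETTERS = [c for c, _ in COG_CATEGORIES]
_LETTER_SET = set(COG_LETTERS)
NOT_IN_COGS = "-"


@dataclass
class CogProfile:
    genome_id: str
    counts: dict[str, int]  # per category letter
    not_in_cogs: int
    denominator: int  # protein-coding gene count

    def percent(self, letter: str) -> float:
        if letter == NOT_IN_COGS:
            return truncate_percent(self.not_in_cogs, self.denominator)
        return truncate_percent(self.counts.get(letter, 0), self.denominator)

    def to_frame(self) -> pd.DataFrame:
        """Table with columns Code, Value, % of total, Description."""
        rows = [
            (c, self.counts.get(c, 0), f"{self.percent(c):.2f}", desc)
            for c, desc in COG_CATEGORIES
        ]
        rows.append((NOT_IN_COGS, self.not_in_cogs, f"{self.percent(NOT_IN_COGS):.2f}", "Not in COGs"))
        return pd.DataFrame(rows, columns=["Code", "Value", "% of total", "Description"])


def read_assignments(path: str | Path) -> pd.DataFrame:
    """Read a gene_id -> categories TSV (categories comma-separated, may be empty)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if not {"gene_id", "categories"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns gene_id, categories")
    return df[["gene_id", "categories"]]


def profile(assignments: pd.DataFrame, n_protein_coding: int, genome_id: str = "genome") -> CogProfile:
    """Per-category counts and percentages for one genome.

    ``assignments`` has columns gene_id and categories (comma-separated
    letters, empty for unassigned). Multi-category genes increment every
    category they carry; not_in_cogs = n_protein_coding - genes with >=1
    category.
    """
    gene_ids = assignments["gene_id"].tolist()
    if len(set(gene_ids)) != len(gene_ids):
        raise ValueError("duplicate gene_id in COG assignment table")
    if n_protein_coding < len(gene_ids):
        raise ValueError("n_protein_coding smaller than number of assigned genes")
    counts = {c: 0 for c in COG_LETTERS}
    n_assigned = 0
    for _, row in assignments.iterrows():
        letters = [x.strip() for x in str(row["categories"]).split(",") if x.strip()]
        bad = set(letters) - _LETTER_SET
        if bad:
            raise ValueError(f"gene {row['gene_id']!r}: unknown COG category {sorted(bad)}")
        if letters:
            n_assigned += 1
        for c in letters:
            counts[c] += 1
    return CogProfile(
        genome_id=genome_id,
        counts=counts,
        not_in_cogs=n_protein_coding - n_assigned,
        denominator=n_protein_coding,
    )


def compare_profiles(profiles: Sequence[CogProfile]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(wide, long) category x genome tables in the fixed category order.

    Wide: one row per category (plus '-'), one count column per genome.
    Long: genome_id, code, count, percent — convenient for plotting.
    """
    if len(profiles) < 2:
        raise ValueError("compare_profiles requires at least two profiles")
    order = COG_LETTERS + [NOT_IN_COGS]
    wide = pd.DataFrame({"Code": order})
    long_rows = []
    for p in profiles:
        col = [p.counts.get(c, 0) if c != NOT_IN_COGS else p.not_in_cogs for c in order]
        wide[p.genome_id] = col
        for c, v in zip(order, col):
            long_rows.append((p.genome_id, c, v, p.percent(c)))
    long = pd.DataFrame(long_rows, columns=["genome_id", "code", "count", "percent"])
    return wide, long
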