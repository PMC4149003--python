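"""16S rRNA identity and the species-delineation decision rule.

Two 16S sequences are globally aligned and their percent identity compared
with the conventional species boundary of 98.7%: a top-hit identity
strictly below the threshold makes the isolate a candidate new species
(without resorting to DNA-DNA hybridization); identity at or above it does
not. Deposited 16S sequences vary in orientation, so both strands of the
subject are tried and the higher identity kept.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd
from Bio.Seq import Seq

from .align import DNA_SCHEME, ScoringScheme, needleman_wunsch, percent_identity

SPECIES_THRESHOLD = 98.7

__all__ = ["IdentityVerdict", "identity_16s", "best_match", "SPECIES_THRESHOLD"]


@dataclass
class IdentityVerdict:
    query_id: str
    subject_id: str
    identity_percent: float
    threshold_percent: float = SPECIES_THRESHOLD

    @property
    def verdict(self) -> str:
        # novelty requires identity strictly below the threshold
        if self.identity_percent < self.threshold_percent:
            return "candidate_new_species"
        return "same_species_range"


def identity_16s(
    a: str,
    b: str,
    scheme: ScoringScheme = DNA_SCHEME,
    identity_mode: str = "all_columns",
) -> float:
    """Global-alignment percent identity of two 16S sequences, 1 decimal.

    The subject is tried in both orientations and the higher identity is
    reported.
    """
    best = None
    for subject in (b, str(Seq(b).reverse_complement())):
        aln = needleman_wunsch(a, subject, scheme)
        ident = percent_identity(aln, identity_mode)
        if best is None or ident > best:
            best = ident
    return round(best, 1)


def best_match(
    query: tuple[str, str],
    references: Sequence[tuple[str, str]],
    threshold: float = SPECIES_THRESHOLD,
    scheme: ScoringScheme = DNA_SCHEME,
    identity_mode: str = "all_columns",
) -> tuple[pd.DataFrame, IdentityVerdict]:
    """Rank references by identity to the query; verdict on the top hit.

    Returns (ranking, verdict) where the ranking is a DataFrame sorted by
    descending identity (ties broken by subject id for stability).
    """
    if not references:
        raise ValueError("best_match requires at least one reference sequence")
    qid, qseq = query
    rows = [(rid, identity_16s(qseq, rseq, scheme, identity_mode)) for rid, rseq in references]
    ranking = (
        pd.DataFrame(rows, columns=["subject", "identity"])
        .sort_values(["identity", "subject"], ascending=[False, True], kind="mergesort")
        .reset_index(drop=True)
    )
    top = ranking.iloc[0]
    verdict = IdentityVerdict(qid, str(top["subject"]), float(top["identity"]), threshold)
    return ranking, verdict
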