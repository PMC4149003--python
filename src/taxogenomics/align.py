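"""Pairwise global (Needleman-Wunsch/Gotoh) and local (Smith-Waterman)
alignment with affine gap costs.

This is the computational kernel behind the AGIOS statistic and 16S
identity. Conventions, chosen once and used everywhere:

* A gap of length L costs ``gap_open + L * gap_extend`` (BLAST convention);
  both costs are non-negative numbers subtracted from the score.
* Default nucleotide scheme: match +5, mismatch -4, open 10, extend 0.5.
  Default protein scheme: BLOSUM62, open 11, extend 1.
* N scores as a mismatch against everything, including N, and never counts
  as an identity match — conservative on draft genomes.
* Terminal gaps are penalized (true global alignment); a free-end-gaps
  (semi-global) variant is available via ``free_end_gaps=True``.
* Traceback tie-break: diagonal > up (gap in b) > left (gap in a), and
  match state preferred over gap states, so output is deterministic.

The dynamic programming inner loops are JIT-compiled with numba; the code
is plain Python and still runs (slowly) if compilation is unavailable.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

try:
    from numba import njit
except ImportError:  # pragma: no cover - numba is a declared dependency
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap


NT_LETTERS = "ACGTN"
_NEG = -1e30
# traceback states
_M, _IX, _IY = 0, 1, 2
_EDGE = 3  # free-end start marker


class AlignmentError(ValueError):
    """Raised for invalid alignment inputs."""


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution scores and affine gap costs.

    ``alphabet`` is 'nucleotide' or 'protein'. For proteins either a named
    substitution matrix (``matrix='BLOSUM62'``) or match/mismatch scores may
    be used. ``gap_open``/``gap_extend`` are non-negative costs with
    gap_extend <= gap_open.
    """

    alphabet: str = "nucleotide"
    match: float = 5.0
    mismatch: float = -4.0
    matrix: str | None = None
    gap_open: float = 10.0
    gap_extend: float = 0.5

    def __post_init__(self) -> None:
        if self.alphabet not in {"nucleotide", "protein"}:
            raise AlignmentError(f"unknown alphabet {self.alphabet!r}")
        if self.gap_open < 0 or self.gap_extend < 0:
            raise AlignmentError("gap costs must be non-negative")
        if self.gap_extend > self.gap_open:
            raise AlignmentError("gap_extend must not exceed gap_open")
        if self.matrix is None and not self.match > self.mismatch:
            raise AlignmentError("match score must exceed mismatch score")

    def exact_match_unit(self) -> float:
        """Score of one exactly matching position (mean diagonal for matrices)."""
        letters, S = _scoring_arrays(self)
        if self.matrix is None:
            return float(self.match)
        diag = [S[i, i] for i, c in enumerate(letters) if c not in "BZX*"]
        return float(np.mean(diag))


DNA_SCHEME = ScoringScheme()
PROTEIN_SCHEME = ScoringScheme(alphabet="protein", matrix="BLOSUM62", gap_open=11.0, gap_extend=1.0)


@lru_cache(maxsize=8)
def _scoring_arrays_cached(key: tuple) -> tuple[str, np.ndarray]:
    alphabet, match, mismatch, matrix = key
    if alphabet == "nucleotide":
        letters = NT_LETTERS
        k = len(letters)
        S = np.full((k, k), float(mismatch))
        for i, c in enumerate(letters):
            if c != "N":
                S[i, i] = float(match)
        return letters, S
    if matrix is not None:
        from Bio.Align import substitution_matrices

        m = substitution_matrices.load(matrix)
        letters = str(m.alphabet)
        return letters, np.asarray(m, dtype=float)
    letters = "ACDEFGHIKLMNPQRSTVWYX"
    k = len(letters)
    S = np.full((k, k), float(mismatch))
    for i, c in enumerate(letters):
        if c != "X":
            S[i, i] = float(match)
    return letters, S


def _scoring_arrays(scheme: ScoringScheme) -> tuple[str, np.ndarray]:
    return _scoring_arrays_cached((scheme.alphabet, scheme.match, scheme.mismatch, scheme.matrix))


def _encode(seq: str, letters: str, scheme: ScoringScheme) -> np.ndarray:
    idx = {c: i for i, c in enumerate(letters)}
    try:
        return np.array([idx[c] for c in seq.upper()], dtype=np.int64)
    except KeyError:
        bad = sorted(set(seq.upper()) - set(letters))
        raise AlignmentError(
            f"characters {bad} not in the {scheme.alphabet} alphabet {letters!r} "
            "(mixed alphabets or unsupported ambiguity codes?)"
        ) from None


@dataclass
class AlignmentResult:
    """An aligned pair with score and identity bookkeeping.

    ``identity_percent`` is over all alignment columns (the default identity
    mode); use :func:`percent_identity` for other denominators. For local
    alignments the a_/b_ coordinates give the aligned region (0-based
    half-open); for global alignments they span the full inputs.
    """

    aligned_a: str
    aligned_b: str
    score: float
    n_match: int
    n_columns: int
    n_gap_columns: int
    identity_percent: float | None
    a_start: int = 0
    a_end: int = 0
    b_start: int = 0
    b_end: int = 0

    @property
    def len_a(self) -> int:
        return len(self.aligned_a) - self.aligned_a.count("-")

    @property
    def len_b(self) -> int:
        return len(self.aligned_b) - self.aligned_b.count("-")


def _summarize(aligned_a: str, aligned_b: str, score: float, scheme: ScoringScheme, **coords) -> AlignmentResult:
    ambiguous = "N" if scheme.alphabet == "nucleotide" else ""
    n_cols = len(aligned_a)
    n_match = 0
    n_gap = 0
    for x, y in zip(aligned_a, aligned_b):
        if x == "-" or y == "-":
            n_gap += 1
        elif x == y and x != ambiguous:
            n_match += 1
    ident = 100.0 * n_match / n_cols if n_cols else None
    return AlignmentResult(aligned_a, aligned_b, float(score), n_match, n_cols, n_gap, ident, **coords)


def percent_identity(aln: AlignmentResult, mode: str = "all_columns") -> float:
    """Percent identity of an alignment under a chosen denominator.

    all_columns: matches / alignment columns (default). ungapped_columns:
    gap columns excluded from the denominator. shorter_seq: matches / length
    of the shorter input.
    """
    if aln.n_columns == 0:
        raise AlignmentError("percent identity undefined for a zero-length alignment")
    if mode == "all_columns":
        return 100.0 * aln.n_match / aln.n_columns
    if mode == "ungapped_columns":
        ungapped = aln.n_columns - aln.n_gap_columns
        if ungapped == 0:
            raise AlignmentError("no ungapped columns in alignment")
        return 100.0 * aln.n_match / ungapped
    if mode == "shorter_seq":
        return 100.0 * aln.n_match / min(aln.len_a, aln.len_b)
    raise AlignmentError(f"unknown identity mode {mode!r}")


@njit(cache=True)
def _nw_fill(a, b, S, go, ge, free_ends, M, Ix, Iy, pM, pIx, pIy):  # pragma: no cover - jitted
    n = a.shape[0]
    m = b.shape[0]
    M[0, 0] = 0.0
    pM[0, 0] = _EDGE
    for i in range(1, n + 1):
        Ix[i, 0] = -(go + i * ge)
        pIx[i, 0] = 0 if i == 1 else 1
        if free_ends:
            M[i, 0] = 0.0
            pM[i, 0] = _EDGE
    for j in range(1, m + 1):
        Iy[0, j] = -(go + j * ge)
        pIy[0, j] = 0 if j == 1 else 1
        if free_ends:
            M[0, j] = 0.0
            pM[0, j] = _EDGE
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = S[ai, b[j - 1]]
            # match/mismatch state: tie-break M > Ix > Iy
            best = M[i - 1, j - 1]
            p = 0
            if Ix[i - 1, j - 1] > best:
                best = Ix[i - 1, j - 1]
                p = 1
            if Iy[i - 1, j - 1] > best:
                best = Iy[i - 1, j - 1]
                p = 2
            M[i, j] = best + s
            pM[i, j] = p
            # gap in b (consume a_i, "up")
            op = M[i - 1, j] - go - ge
            ex = Ix[i - 1, j] - ge
            if op >= ex:
                Ix[i, j] = op
                pIx[i, j] = 0
            else:
                Ix[i, j] = ex
                pIx[i, j] = 1
            # gap in a (consume b_j, "left")
            op = M[i, j - 1] - go - ge
            ex = Iy[i, j - 1] - ge
            if op >= ex:
                Iy[i, j] = op
                pIy[i, j] = 0
            else:
                Iy[i, j] = ex
                pIy[i, j] = 1


@njit(cache=True)
def _sw_fill(a, b, S, go, ge, H, Ix, Iy, pH, pIx, pIy):  # pragma: no cover - jitted
    n = a.shape[0]
    m = b.shape[0]
    best = 0.0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            op = H[i - 1, j] - go - ge
            ex = Ix[i - 1, j] - ge
            if op >= ex:
                Ix[i, j] = op
                pIx[i, j] = 0
            else:
                Ix[i, j] = ex
                pIx[i, j] = 1
            op = H[i, j - 1] - go - ge
            ex = Iy[i, j - 1] - ge
            if op >= ex:
                Iy[i, j] = op
                pIy[i, j] = 0
            else:
                Iy[i, j] = ex
                pIy[i, j] = 1
            d = H[i - 1, j - 1] + S[ai, b[j - 1]]
            # tie-break: diagonal > up > left > stop
            h = 0.0
            p = 0
            if d > h:
                h = d
                p = 1
            if Ix[i, j] > h:
                h = Ix[i, j]
                p = 2
            if Iy[i, j] > h:
                h = Iy[i, j]
                p = 3
            H[i, j] = h
            pH[i, j] = p
            if h > best:
                best = h
                bi = i
                bj = j
    return best, bi, bj


def _alloc(n: int, m: int, init: float):
    V = np.full((n + 1, m + 1), init)
    P = np.zeros((n + 1, m + 1), dtype=np.uint8)
    return V, P


def needleman_wunsch(
    a: str,
    b: str,
    scheme: ScoringScheme = DNA_SCHEME,
    free_end_gaps: bool = False,
) -> AlignmentResult:
    """Optimal global alignment under affine gap costs (Gotoh recurrence).

    With ``free_end_gaps=True`` terminal gaps are unpenalized (semi-global);
    the default is a true end-to-end global alignment.
    """
    if not a or not b:
        raise AlignmentError("cannot align empty sequences")
    letters, S = _scoring_arrays(scheme)
    ea, eb = _encode(a, letters, scheme), _encode(b, letters, scheme)
    n, m = len(ea), len(eb)
    go, ge = float(scheme.gap_open), float(scheme.gap_extend)
    M, pM = _alloc(n, m, _NEG)
    Ix, pIx = _alloc(n, m, _NEG)
    Iy, pIy = _alloc(n, m, _NEG)
    _nw_fill(ea, eb, S, go, ge, free_end_gaps, M, Ix, Iy, pM, pIx, pIy)

    if free_end_gaps:
        end_i, end_j, state, score = n, m, _M, _NEG
        for st, V in ((_M, M), (_IX, Ix), (_IY, Iy)):
            if V[n, m] > score:
                score, end_i, end_j, state = V[n, m], n, m, st
        for j in range(m, -1, -1):
            for st, V in ((_M, M), (_IX, Ix), (_IY, Iy)):
                if V[n, j] > score:
                    score, end_i, end_j, state = V[n, j], n, j, st
        for i in range(n, -1, -1):
            for st, V in ((_M, M), (_IX, Ix), (_IY, Iy)):
                if V[i, m] > score:
                    score, end_i, end_j, state = V[i, m], i, m, st
    else:
        end_i, end_j = n, m
        score, state = M[n, m], _M
        if Ix[n, m] > score:
            score, state = Ix[n, m], _IX
        if Iy[n, m] > score:
            score, state = Iy[n, m], _IY

    out_a: list[str] = []
    out_b: list[str] = []
    # trailing unaligned tails (semi-global only)
    for i in range(n, end_i, -1):
        out_a.append(a[i - 1])
        out_b.append("-")
    for j in range(m, end_j, -1):
        out_a.append("-")
        out_b.append(b[j - 1])
    i, j = end_i, end_j
    while i > 0 or j > 0:
        if state == _M:
            p = pM[i, j]
            if p == _EDGE:
                break
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i -= 1
            j -= 1
            state = p
        elif state == _IX:
            out_a.append(a[i - 1])
            out_b.append("-")
            state = _M if pIx[i, j] == 0 else _IX
            i -= 1
        else:
            out_a.append("-")
            out_b.append(b[j - 1])
            state = _M if pIy[i, j] == 0 else _IY
            j -= 1
    # leading unaligned heads (semi-global only)
    for k in range(i, 0, -1):
        out_a.append(a[k - 1])
        out_b.append("-")
    for k in range(j, 0, -1):
        out_a.append("-")
        out_b.append(b[k - 1])
    return _summarize(
        "".join(reversed(out_a)),
        "".join(reversed(out_b)),
        score,
        scheme,
        a_start=0,
        a_end=n,
        b_start=0,
        b_end=m,
    )


def smith_waterman(a: str, b: str, scheme: ScoringScheme = PROTEIN_SCHEME) -> AlignmentResult:
    """Best local alignment; the empty alignment (score 0) is allowed."""
    if not a or not b:
        raise AlignmentError("cannot align empty sequences")
    letters, S = _scoring_arrays(scheme)
    ea, eb = _encode(a, letters, scheme), _encode(b, letters, scheme)
    n, m = len(ea), len(eb)
    go, ge = float(scheme.gap_open), float(scheme.gap_extend)
    H, pH = _alloc(n, m, 0.0)
    Ix, pIx = _alloc(n, m, _NEG)
    Iy, pIy = _alloc(n, m, _NEG)
    best, bi, bj = _sw_fill(ea, eb, S, go, ge, H, Ix, Iy, pH, pIx, pIy)
    if best <= 0.0:
        return AlignmentResult("", "", 0.0, 0, 0, 0, None)
    out_a: list[str] = []
    out_b: list[str] = []
    i, j, state = bi, bj, _M
    while True:
        if state == _M:
            p = pH[i, j]
            if p == 0:
                break
            if p == 1:
                out_a.append(a[i - 1])
                out_b.append(b[j - 1])
                i -= 1
                j -= 1
            elif p == 2:
                state = _IX
            else:
                state = _IY
        elif state == _IX:
            out_a.append(a[i - 1])
            out_b.append("-")
            state = _M if pIx[i, j] == 0 else _IX
            i -= 1
        else:
            out_a.append("-")
            out_b.append(b[j - 1])
            state = _M if pIy[i, j] == 0 else _IY
            j -= 1
    return _summarize(
        "".join(reversed(out_a)),
        "".join(reversed(out_b)),
        best,
        scheme,
        a_start=i,
        a_end=bi,
        b_start=j,
        b_end=bj,
    )
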