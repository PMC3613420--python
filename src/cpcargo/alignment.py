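"""Global pairwise alignment and N-terminal extension detection.

A candidate chloroplast protein that carries an extra N-terminal stretch
relative to its non-plastid homologues is taken as evidence of a cleavable
transit peptide. The original analysis judged this from multiple alignments
by eye; here the criterion is made algorithmic: align the candidate globally
against each homologue, count the query residues that precede the first
column in which both sequences have residues, and take the minimum over
homologues as the conservative overhang. An overhang of at least
``min_length`` residues (default 20, a typical lower bound for plant transit
peptides) calls an extension.

The aligner is Needleman-Wunsch with affine gaps (Gotoh's three-state
recursion). A gap of length L costs ``gap_open + (L - 1) * gap_extend``, end
gaps included. Traceback ties are broken deterministically: diagonal
(substitution) over up (gap in the subject) over left (gap in the query).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence, Tuple

import numpy as np
from Bio.Align import substitution_matrices

from .errors import AlignmentError

DEFAULT_MATRIX = "BLOSUM62"
DEFAULT_GAP_OPEN = 10.0
DEFAULT_GAP_EXTEND = 1.0

NEG_INF = float("-inf")

# state codes for the traceback
_M, _X, _Y = 0, 1, 2  # diagonal, up (gap in subject), left (gap in query)


@dataclass(frozen=True)
class Alignment:
    """A global alignment of query against subject ('-' marks gaps)."""

    query_aligned: str
    subject_aligned: str
    score: float
    substitution_name: str
    gap_open: float
    gap_extend: float

    def __post_init__(self):
        if len(self.query_aligned) != len(self.subject_aligned):
            raise ValueError("aligned strings differ in length")

    @property
    def query(self) -> str:
        return self.query_aligned.replace("-", "")

    @property
    def subject(self) -> str:
        return self.subject_aligned.replace("-", "")

    def columns(self):
        return zip(self.query_aligned, self.subject_aligned)


@lru_cache(maxsize=None)
def _load_matrix(name: str):
    try:
        return substitution_matrices.load(name)
    except FileNotFoundError:
        available = ", ".join(substitution_matrices.load())
        raise AlignmentError(
            f"unknown substitution matrix {name!r}; available: {available}"
        ) from None


def _check_sequence(seq: str, alphabet: str, name: str) -> None:
    if not seq:
        raise AlignmentError(f"{name}: empty sequence")
    bad = set(seq) - set(alphabet)
    if bad:
        raise AlignmentError(
            f"{name}: letters {sorted(bad)} not covered by the substitution matrix"
        )


def global_align(
    a: str,
    b: str,
    substitution: str = DEFAULT_MATRIX,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> Alignment:
    """Optimal global alignment of *a* (query) and *b* (subject)."""
    matrix = _load_matrix(substitution)
    _check_sequence(a, matrix.alphabet, "query")
    _check_sequence(b, matrix.alphabet, "subject")
    if gap_open < 0 or gap_extend < 0:
        raise AlignmentError("gap penalties must be non-negative")

    n, m = len(a), len(b)
    # Three layers: M (a[i] aligned to b[j]), X (a[i] over a gap), Y (gap over b[j]).
    M = np.full((n + 1, m + 1), NEG_INF)
    X = np.full((n + 1, m + 1), NEG_INF)
    Y = np.full((n + 1, m + 1), NEG_INF)
    ptr = np.zeros((3, n + 1, m + 1), dtype=np.int8)

    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -(gap_open + (i - 1) * gap_extend)
        ptr[_X, i, 0] = _M if i == 1 else _X
    for j in range(1, m + 1):
        Y[0, j] = -(gap_open + (j - 1) * gap_extend)
        ptr[_Y, 0, j] = _M if j == 1 else _Y

    def best(options):
        # options: sequence of (score, state) in preference order M, X, Y
        top_score, top_state = options[0]
        for score, state in options[1:]:
            if score > top_score:
                top_score, top_state = score, state
        return top_score, top_state

    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = matrix[ai, b[j - 1]]
            M[i, j], ptr[_M, i, j] = best(
                [(M[i - 1, j - 1] + s, _M), (X[i - 1, j - 1] + s, _X), (Y[i - 1, j - 1] + s, _Y)]
            )
            X[i, j], ptr[_X, i, j] = best(
                [(M[i - 1, j] - gap_open, _M), (X[i - 1, j] - gap_extend, _X), (Y[i - 1, j] - gap_open, _Y)]
            )
            Y[i, j], ptr[_Y, i, j] = best(
                [(M[i, j - 1] - gap_open, _M), (X[i, j - 1] - gap_open, _X), (Y[i, j - 1] - gap_extend, _Y)]
            )

    score, state = best([(M[n, m], _M), (X[n, m], _X), (Y[n, m], _Y)])

    qa, sa = [], []
    i, j = n, m
    while i > 0 or j > 0:
        prev = ptr[state, i, j]
        if state == _M:
            qa.append(a[i - 1])
            sa.append(b[j - 1])
            i -= 1
            j -= 1
        elif state == _X:
            qa.append(a[i - 1])
            sa.append("-")
            i -= 1
        else:
            qa.append("-")
            sa.append(b[j - 1])
            j -= 1
        state = prev

    return Alignment(
        query_aligned="".join(reversed(qa)),
        subject_aligned="".join(reversed(sa)),
        score=float(score),
        substitution_name=substitution,
        gap_open=gap_open,
        gap_extend=gap_extend,
    )


def nterm_overhang(
    query: str,
    homologues: Sequence[str],
    substitution: str = DEFAULT_MATRIX,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> int:
    """Minimum, over homologues, of the query's unpaired N-terminal length.

    For each homologue the query is globally aligned and the number of query
    residues before the first column where both sequences carry residues is
    counted; the minimum over homologues is the conservative overhang.
    """
    if not homologues:
        raise ValueError("at least one homologue is required")
    overhangs = []
    for hom in homologues:
        aln = global_align(query, hom, substitution, gap_open, gap_extend)
        count = 0
        for qc, sc in aln.columns():
            if qc != "-" and sc != "-":
                break
            if qc != "-":
                count += 1
        overhangs.append(count)
    return min(overhangs)


#: Minimum overhang (residues) that calls a transit-peptide-like extension.
DEFAULT_MIN_EXTENSION = 20


def call_extension(overhang: int, min_length: int = DEFAULT_MIN_EXTENSION) -> bool:
    """True iff *overhang* reaches *min_length* (inclusive)."""
    if overhang < 0:
        raise ValueError("overhang must be non-negative")
    return overhang >= min_length
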