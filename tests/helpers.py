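"""Independent oracles used to cross-check the implementation.

These deliberately avoid the code paths they verify: the motif oracle walks
element-by-element with explicit repeat enumeration (the scanner compiles to
window regex full-matches), and the alignment oracle enumerates every global
alignment outright.
"""

from itertools import product

from cpcargo.patterns import AMINO_ACIDS, VALID_SEQUENCE_LETTERS


def brute_force_matches(sequence, pattern):
    """All (start, end) pairs (1-based inclusive) where *pattern* matches."""
    n = len(sequence)
    elements = pattern.elements

    def letter_ok(element, ch):
        if element.residues is None:
            return ch in VALID_SEQUENCE_LETTERS
        if ch not in AMINO_ACIDS:
            return False  # ambiguity letters never satisfy residue classes
        if element.negated:
            return ch not in element.residues
        return ch in element.residues

    found = set()

    def walk(pos, ei, start):
        if ei == len(elements):
            found.add((start, pos - 1))
            return
        e = elements[ei]
        for reps in range(e.min_repeat, e.max_repeat + 1):
            if pos + reps - 1 > n:
                break
            if all(letter_ok(e, sequence[p - 1]) for p in range(pos, pos + reps)):
                walk(pos + reps, ei + 1, start)
            else:
                break  # a longer repeat includes the failing position

    starts = [1] if pattern.n_anchor else range(1, n + 1)
    for start in starts:
        walk(start, 0, start)
    if pattern.c_anchor:
        found = {(s, e) for s, e in found if e == n}
    return sorted(found)


def score_columns(columns, matrix, gap_open, gap_extend):
    """Score one explicit alignment: substitution sums minus affine gap costs,
    with a gap of length L costing gap_open + (L - 1) * gap_extend."""
    total = 0.0
    in_gap_q = in_gap_s = False
    for qc, sc in columns:
        if qc != "-" and sc != "-":
            total += matrix[qc, sc]
            in_gap_q = in_gap_s = False
        elif qc == "-":
            total -= gap_extend if in_gap_q else gap_open
            in_gap_q, in_gap_s = True, False
        else:
            total -= gap_extend if in_gap_s else gap_open
            in_gap_s, in_gap_q = True, False
    return total


def enumerate_best_score(a, b, matrix, gap_open, gap_extend):
    """Optimal global score by exhaustive enumeration (tiny sequences only)."""
    best = float("-inf")

    def rec(i, j, columns):
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, score_columns(columns, matrix, gap_open, gap_extend))
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, columns + [(a[i], b[j])])
        if i < len(a):
            rec(i + 1, j, columns + [(a[i], "-")])
        if j < len(b):
            rec(i, j + 1, columns + [("-", b[j])])

    rec(0, 0, [])
    return best
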