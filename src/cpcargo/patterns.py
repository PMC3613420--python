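"""Prosite-style sorting-signal patterns and the motif scanner.

The vesicle-cargo screen rests on five short, hand-built signal patterns
written in a subset of Prosite notation:

* ``diacidic``       ``[DE]-x-[DE]``      — C-terminal coat-binding signal of
  transmembrane cargo (DxE-type ER-export signal transferred to plastids).
* ``dihydrophobic``  ``[FY](2)``          — alternative C-terminal signal.
* ``basic``          ``[RK]-x(0,1)-[RK]`` — di/mono-basic N-terminal signal
  proximal to the first membrane span.
* ``ilv``            ``I-x(2)-L-x(9)-V``  — internal signal of soluble cargo.
* ``dilysine``       ``K-x(0,1)-K-x(2)``  — receptor coat-binding signal.

Supported syntax: single residue letters, ``[..]`` residue classes, ``{..}``
negated classes, the wildcard ``x``, repeat qualifiers ``(n)`` / ``(n,m)``,
optional ``-`` element separators, and the anchors ``<`` (match must start at
residue 1) and ``>`` (match must end at the final residue).

Coordinates are 1-based and inclusive at both ends throughout the package,
matching the Prosite / biological convention.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Iterator, Mapping, Optional, Tuple

from .errors import PatternSyntaxError, SequenceError

#: The 20 standard amino-acid letters.
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Ambiguity/rare letters tolerated in sequences. They are matched only by
#: wildcards, never by residue classes: a class asserts a chemical identity
#: that an ambiguous letter does not support.
AMBIGUITY_LETTERS = frozenset("XBZU")

VALID_SEQUENCE_LETTERS = AMINO_ACIDS | AMBIGUITY_LETTERS

_WILDCARD_CHARCLASS = "[" + "".join(sorted(VALID_SEQUENCE_LETTERS)) + "]"


@dataclass(frozen=True)
class PatternElement:
    """One element of a motif pattern.

    ``residues is None`` denotes the wildcard ``x``. ``negated`` marks a
    ``{..}`` class (the listed residues are excluded). ``min_repeat`` /
    ``max_repeat`` give the span of consecutive sequence positions the
    element may consume.
    """

    residues: Optional[frozenset] = None
    negated: bool = False
    min_repeat: int = 1
    max_repeat: int = 1

    def __post_init__(self):
        if self.min_repeat < 0 or self.min_repeat > self.max_repeat:
            raise ValueError(
                f"invalid repeat range ({self.min_repeat},{self.max_repeat})"
            )
        if self.residues is not None:
            if not self.residues:
                raise ValueError("empty residue class")
            bad = set(self.residues) - AMINO_ACIDS
            if bad:
                raise ValueError(f"non-standard residues in class: {sorted(bad)}")

    @property
    def is_wildcard(self) -> bool:
        return self.residues is None

    def render(self) -> str:
        if self.is_wildcard:
            core = "x"
        elif self.negated:
            core = "{" + "".join(sorted(self.residues)) + "}"
        elif len(self.residues) == 1:
            core = next(iter(self.residues))
        else:
            core = "[" + "".join(sorted(self.residues)) + "]"
        if (self.min_repeat, self.max_repeat) == (1, 1):
            return core
        if self.min_repeat == self.max_repeat:
            return f"{core}({self.min_repeat})"
        return f"{core}({self.min_repeat},{self.max_repeat})"

    def char_class(self) -> str:
        """Regex character class implementing this element on one position."""
        if self.is_wildcard:
            return _WILDCARD_CHARCLASS
        if self.negated:
            allowed = AMINO_ACIDS - self.residues
            return "[" + "".join(sorted(allowed)) + "]"
        return "[" + "".join(sorted(self.residues)) + "]"


@dataclass(frozen=True)
class MotifPattern:
    """A compiled sorting-signal pattern."""

    pattern_id: str
    elements: Tuple[PatternElement, ...]
    n_anchor: bool = False
    c_anchor: bool = False

    def __post_init__(self):
        if not self.elements:
            raise ValueError("pattern has no elements")
        if self.min_span < 1:
            raise ValueError("total minimum span must be >= 1")

    @property
    def min_span(self) -> int:
        return sum(e.min_repeat for e in self.elements)

    @property
    def max_span(self) -> int:
        return sum(e.max_repeat for e in self.elements)

    def render(self) -> str:
        """Canonical pattern text; compile(render()) round-trips."""
        body = "-".join(e.render() for e in self.elements)
        return ("<" if self.n_anchor else "") + body + (">" if self.c_anchor else "")

    def _regex(self) -> re.Pattern:
        parts = []
        for e in self.elements:
            cc = e.char_class()
            if (e.min_repeat, e.max_repeat) == (1, 1):
                parts.append(cc)
            elif e.min_repeat == e.max_repeat:
                parts.append(f"{cc}{{{e.min_repeat}}}")
            else:
                parts.append(f"{cc}{{{e.min_repeat},{e.max_repeat}}}")
        return re.compile("".join(parts))


@dataclass(frozen=True)
class MotifMatch:
    """One pattern occurrence. ``start``/``end`` are 1-based inclusive."""

    pattern_id: str
    start: int
    end: int
    matched_text: str

    def __post_init__(self):
        if not (1 <= self.start <= self.end):
            raise ValueError("invalid match coordinates")
        if self.end - self.start + 1 != len(self.matched_text):
            raise ValueError("matched_text length disagrees with coordinates")

    @property
    def span(self) -> Tuple[int, int]:
        return (self.start, self.end)

    def overlaps(self, start: int, end: int) -> bool:
        return self.start <= end and start <= self.end


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------


def compile_pattern(pattern_text: str, pattern_id: Optional[str] = None) -> MotifPattern:
    """Compile Prosite-subset pattern text into a :class:`MotifPattern`.

    Raises :class:`PatternSyntaxError` naming the offending token and its
    1-based column on malformed input.
    """
    text = pattern_text.strip()
    if not text:
        raise PatternSyntaxError("empty pattern", 1)

    i = 0
    n = len(text)
    n_anchor = c_anchor = False
    if text[0] == "<":
        n_anchor = True
        i = 1
    if text.endswith(">"):
        c_anchor = True
        n = len(text) - 1
        if n <= i:
            raise PatternSyntaxError("anchor without elements", len(text))

    elements: list[PatternElement] = []

    def col(idx: int) -> int:
        return idx + 1  # 1-based columns refer to the original text

    while i < n:
        ch = text[i]
        if ch == "-":
            if not elements:
                raise PatternSyntaxError("separator before first element", col(i))
            i += 1
            continue
        if ch in "[{":
            closer = "]" if ch == "[" else "}"
            j = text.find(closer, i + 1, n)
            if j < 0:
                raise PatternSyntaxError(f"unbalanced '{ch}'", col(i))
            letters = text[i + 1 : j]
            if not letters:
                raise PatternSyntaxError("empty residue class", col(i))
            bad = set(letters) - AMINO_ACIDS
            if bad:
                raise PatternSyntaxError(
                    f"letters {sorted(bad)} are not standard amino acids", col(i + 1)
                )
            elements.append(
                PatternElement(residues=frozenset(letters), negated=(ch == "{"))
            )
            i = j + 1
        elif ch == "x":
            elements.append(PatternElement(residues=None))
            i += 1
        elif ch == "(":
            if not elements:
                raise PatternSyntaxError("repeat with no preceding element", col(i))
            j = text.find(")", i + 1, n)
            if j < 0:
                raise PatternSyntaxError("unbalanced '('", col(i))
            body = text[i + 1 : j]
            m = re.fullmatch(r"(\d+)(?:,(\d+))?", body)
            if not m:
                raise PatternSyntaxError(f"malformed repeat '({body})'", col(i))
            lo = int(m.group(1))
            hi = int(m.group(2)) if m.group(2) else lo
            if lo > hi:
                raise PatternSyntaxError(f"repeat min {lo} > max {hi}", col(i))
            prev = elements[-1]
            if (prev.min_repeat, prev.max_repeat) != (1, 1):
                raise PatternSyntaxError("element already has a repeat", col(i))
            elements[-1] = PatternElement(
                residues=prev.residues,
                negated=prev.negated,
                min_repeat=lo,
                max_repeat=hi,
            )
            i = j + 1
        elif ch in AMINO_ACIDS:
            elements.append(PatternElement(residues=frozenset(ch)))
            i += 1
        else:
            raise PatternSyntaxError(f"unexpected character {ch!r}", col(i))

    if not elements:
        raise PatternSyntaxError("pattern has no elements", 1)

    pat = MotifPattern(
        pattern_id=pattern_id or "",
        elements=tuple(elements),
        n_anchor=n_anchor,
        c_anchor=c_anchor,
    )
    if not pattern_id:
        pat = MotifPattern(
            pattern_id=pat.render(),
            elements=pat.elements,
            n_anchor=pat.n_anchor,
            c_anchor=pat.c_anchor,
        )
    return pat


# ---------------------------------------------------------------------------
# Scanning
# ---------------------------------------------------------------------------


def validate_sequence(sequence: str) -> None:
    if not sequence:
        raise SequenceError("empty sequence")
    bad = set(sequence) - VALID_SEQUENCE_LETTERS
    if bad:
        raise SequenceError(
            f"illegal sequence letters {sorted(bad)}; allowed are the 20 standard "
            "amino acids plus X, B, Z, U"
        )


def scan(
    sequence: str,
    pattern: MotifPattern,
    window: Optional[Tuple[int, int]] = None,
) -> list[MotifMatch]:
    """Return every occurrence of *pattern* in *sequence*.

    All matches are reported, overlapping ones included; variable-repeat
    wildcards enumerate every feasible span, so one start position may yield
    several matches with different ends. Output is sorted by start, then end.

    *window* restricts matches to the 1-based inclusive bounds given; anchors
    then refer to the window termini. Downstream screens deduplicate per
    protein — the scanner never does.
    """
    validate_sequence(sequence)
    L = len(sequence)
    if window is None:
        ws, we = 1, L
    else:
        ws, we = window
        if not (1 <= ws <= we <= L):
            raise ValueError(f"window {window} outside sequence of length {L}")

    sub = sequence[ws - 1 : we]
    rx = pattern._regex()
    lo, hi = pattern.min_span, pattern.max_span
    m = len(sub)

    matches: list[MotifMatch] = []
    starts: Iterator[int] = range(1) if pattern.n_anchor else range(m)
    for i in starts:
        if pattern.c_anchor:
            spans: Iterator[int] = (s for s in range(lo, hi + 1) if i + s == m)
        else:
            spans = range(lo, min(hi, m - i) + 1)
        for s in spans:
            j = i + s
            if j > m:
                break
            if rx.fullmatch(sub, i, j):
                matches.append(
                    MotifMatch(pattern.pattern_id, ws + i, ws + j - 1, sub[i:j])
                )
    return matches


# ---------------------------------------------------------------------------
# Built-in catalog
# ---------------------------------------------------------------------------

_BUILTIN_TEXTS = {
    "diacidic": "[DE]-x-[DE]",
    "dihydrophobic": "[FY](2)",
    # Printed dibasic evidence is adjacent "KK" although the signal is defined
    # with a one-residue spacer; x(0,1) covers both forms.
    "basic": "[RK]-x(0,1)-[RK]",
    "ilv": "I-x(2)-L-x(9)-V",
    "dilysine": "K-x(0,1)-K-x(2)",
}

#: Strict dibasic form with a mandatory spacer, kept available for re-analysis.
STRICT_DIBASIC = "[RK]-x-[RK]"

#: Monobasic fallback ("in some cases a monobasic signal"). Disabled by
#: default in the screens because no rule says when it applies.
MONOBASIC = "[RK]"

_CATALOG: Mapping[str, MotifPattern] = MappingProxyType(
    {pid: compile_pattern(text, pattern_id=pid) for pid, text in _BUILTIN_TEXTS.items()}
)


def builtin_patterns() -> Mapping[str, MotifPattern]:
    """Immutable catalog of the five built-in sorting-signal patterns."""
    return _CATALOG


def monobasic_pattern() -> MotifPattern:
    return compile_pattern(MONOBASIC, pattern_id="monobasic")
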