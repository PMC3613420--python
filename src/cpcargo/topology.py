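"""Region maps and positional constraints on sorting-signal matches.

A membrane protein is partitioned into labeled regions — transit peptide,
N-tail, membrane spans, inter-span loops, C-tail — and each non-membrane
region carries a side label: ``in`` faces the stroma, ``out`` the lumen or
intermembrane space. Sides alternate across consecutive membrane spans, so
the two annotated terminus orientations must be mutually consistent.

The positional rules the cargo screen enforces:

* diacidic / dihydrophobic signals must sit in a *stromal* C-tail
  (C-terminal side of the last membrane span, side ``in``);
* the di/mono-basic signal must sit in the N-tail, downstream of any transit
  peptide and proximal to the first membrane span;
* no signal may overlap the transit peptide, which is removed on import.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

from .errors import InconsistentTopologyError
from .patterns import MotifMatch
from .proteins import AnnotatedProtein, Span

#: Default N-tail proximity window (residues between a basic signal's start
#: and the first membrane span). The source rule says only "proximal"; 25 is
#: the package's recorded operational choice.
DEFAULT_NTERM_WINDOW = 25

SIDE_NA = "n/a"
SIDE_MEMBRANE = "membrane"


@dataclass(frozen=True)
class Region:
    label: str  # one of {transit, n_tail, tm, loop, c_tail}
    span: Span
    side: str  # in | out | membrane | n/a


@dataclass(frozen=True)
class RegionMap:
    regions: Tuple[Region, ...]
    length: int

    def __post_init__(self):
        pos = 1
        for r in self.regions:
            if r.span.start != pos:
                raise ValueError("regions do not tile the sequence")
            pos = r.span.end + 1
        if pos != self.length + 1:
            raise ValueError("regions do not cover the sequence")

    def _first(self, label: str) -> Optional[Region]:
        for r in self.regions:
            if r.label == label:
                return r
        return None

    @property
    def transit(self) -> Optional[Region]:
        return self._first("transit")

    @property
    def n_tail(self) -> Optional[Region]:
        return self._first("n_tail")

    @property
    def c_tail(self) -> Optional[Region]:
        return self._first("c_tail")

    @property
    def first_tm(self) -> Optional[Region]:
        return self._first("tm")


def _flip(side: str) -> str:
    return "in" if side == "out" else "out"


def build_region_map(protein: AnnotatedProtein, permissive: bool = False) -> RegionMap:
    """Partition *protein* into labeled, side-annotated regions.

    The side of the N-tail equals the annotated N-terminus orientation and
    alternates across each membrane span; the side this alternation assigns
    beyond the last span must equal the annotated C-terminus orientation.
    A contradiction raises :class:`InconsistentTopologyError` unless
    *permissive* is set, in which case the C-tail side follows the C-terminus
    annotation (the side closest to the rule being tested).
    """
    L = len(protein.record)
    regions: list[Region] = []
    pos = 1

    if protein.transit_peptide is not None:
        tp = protein.transit_peptide
        regions.append(Region("transit", tp, SIDE_NA))
        pos = tp.end + 1

    if protein.is_soluble:
        if pos <= L:
            side = protein.n_orientation or SIDE_NA
            regions.append(Region("n_tail", Span(pos, L), side))
        return RegionMap(tuple(regions), L)

    tms = protein.tm_spans
    if tms[0].start <= pos - 1 and protein.transit_peptide is not None:
        raise ValueError(f"{protein.accession}: first TM span overlaps the transit peptide")

    side = protein.n_orientation  # guaranteed set for membrane proteins
    if pos <= tms[0].start - 1:
        regions.append(Region("n_tail", Span(pos, tms[0].start - 1), side))

    for i, tm in enumerate(tms):
        regions.append(Region("tm", tm, SIDE_MEMBRANE))
        side = _flip(side)
        nxt = tms[i + 1].start if i + 1 < len(tms) else None
        if nxt is not None and tm.end + 1 <= nxt - 1:
            regions.append(Region("loop", Span(tm.end + 1, nxt - 1), side))

    if side != protein.c_orientation:
        if not permissive:
            raise InconsistentTopologyError(
                f"{protein.accession}: alternation from N={protein.n_orientation} across "
                f"{len(tms)} membrane span(s) gives C={side}, but C={protein.c_orientation} "
                "is annotated"
            )
        side = protein.c_orientation

    if tms[-1].end < L:
        regions.append(Region("c_tail", Span(tms[-1].end + 1, L), side))

    return RegionMap(tuple(regions), L)


# ---------------------------------------------------------------------------
# Match-position filters (pure predicates)
# ---------------------------------------------------------------------------


def motif_in_stromal_c_tail(
    match: MotifMatch,
    regions: RegionMap,
    max_dist_from_cterm: Optional[int] = None,
) -> bool:
    """True iff the match lies wholly in a stromal (side ``in``) C-tail and,
    if *max_dist_from_cterm* is given, ends within that many residues of the
    final residue. ``None`` means unlimited within the C-tail."""
    ct = regions.c_tail
    if ct is None or ct.side != "in":
        return False
    if not ct.span.contains_span(match.start, match.end):
        return False
    if max_dist_from_cterm is not None and regions.length - match.end > max_dist_from_cterm:
        return False
    return True


def motif_in_nterm_window(
    match: MotifMatch,
    regions: RegionMap,
    window: int = DEFAULT_NTERM_WINDOW,
) -> bool:
    """True iff the match lies wholly in the N-tail (hence after any transit
    peptide) and starts within *window* residues of the first membrane span."""
    nt = regions.n_tail
    tm = regions.first_tm
    if nt is None or tm is None:
        return False
    if not nt.span.contains_span(match.start, match.end):
        return False
    return tm.span.start - match.start <= window


def motif_outside_transit(match: MotifMatch, regions: RegionMap) -> bool:
    """True iff the match does not overlap the transit peptide."""
    tp = regions.transit
    if tp is None:
        return True
    return not match.overlaps(tp.span.start, tp.span.end)
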