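"""Cargo and receptor screens, and functional categorization of candidates.

Transmembrane cargo must carry a coat-binding signal on the correct side of
the membrane: diacidic or dihydrophobic signals in a stromal C-tail, a
di/mono-basic signal in the N-tail proximal to the first membrane span, and
never inside the transit peptide. Soluble cargo is screened for the internal
ILV signal anywhere outside the transit peptide. Receptor candidates are
recognized architecturally: a C-terminal GOLD domain that itself contains a
dilysine signal, plus a CRAL_TRIO lipid-binding domain; an N-terminal
coiled coil and the absence of membrane spans are reported as supporting
evidence, not requirements.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from .patterns import MotifMatch, builtin_patterns, monobasic_pattern, scan
from .proteins import (
    CATEGORIES,
    PHOTOSYNTHESIS_CATEGORIES,
    AnnotatedProtein,
    Span,
)
from .topology import (
    DEFAULT_NTERM_WINDOW,
    build_region_map,
    motif_in_nterm_window,
    motif_in_stromal_c_tail,
    motif_outside_transit,
)

TM_CARGO_CLASSES = ("tm_diacidic", "tm_dihydrophobic", "tm_basic")
CARGO_CLASSES = TM_CARGO_CLASSES + ("soluble_ilv",)

_CLASS_PATTERN = {
    "tm_diacidic": "diacidic",
    "tm_dihydrophobic": "dihydrophobic",
    "tm_basic": "basic",
    "soluble_ilv": "ilv",
}


@dataclass(frozen=True)
class ScreenParams:
    """Tunable thresholds of the cargo/receptor screens."""

    nterm_window: int = DEFAULT_NTERM_WINDOW
    cterm_max_dist: Optional[int] = None  # None = unlimited within the C-tail
    allow_monobasic: bool = False
    #: Fraction of the mature sequence counted as the C-terminal region for
    #: receptor architecture (and its complement as N-terminal).
    cterm_fraction: float = 0.5
    permissive_topology: bool = False


@dataclass(frozen=True)
class CargoCall:
    accession: str
    cargo_class: str
    matches: Tuple[MotifMatch, ...]
    filters_passed: Mapping[str, bool]
    verdict: bool
    #: set when the protein was screened under alternative annotated
    #: orientations because the printed topology was ambiguous
    orientation_ambiguous: bool = False

    def __post_init__(self):
        if self.cargo_class not in CARGO_CLASSES:
            raise ValueError(f"unknown cargo class {self.cargo_class!r}")
        if self.verdict and not self.matches:
            raise ValueError("verdict true requires at least one match")


@dataclass(frozen=True)
class ReceptorCall:
    accession: str
    has_gold_cterm: bool
    has_cral_trio: bool
    dilysine_in_gold: bool
    coiled_coil_nterm: bool
    lacks_tm: bool
    verdict: bool
    dilysine_matches: Tuple[MotifMatch, ...] = ()


# ---------------------------------------------------------------------------
# Transmembrane cargo
# ---------------------------------------------------------------------------


def _passing(
    matches: Sequence[MotifMatch],
    regions,
    cargo_class: str,
    params: ScreenParams,
) -> Tuple[List[MotifMatch], Dict[str, bool]]:
    outside = [m for m in matches if motif_outside_transit(m, regions)]
    filters: Dict[str, bool] = {"outside_transit": bool(outside)}
    if cargo_class in ("tm_diacidic", "tm_dihydrophobic"):
        good = [
            m
            for m in outside
            if motif_in_stromal_c_tail(m, regions, params.cterm_max_dist)
        ]
        filters["stromal_c_tail"] = bool(good)
    elif cargo_class == "tm_basic":
        good = [m for m in outside if motif_in_nterm_window(m, regions, params.nterm_window)]
        filters["nterm_window"] = bool(good)
    else:  # soluble_ilv: the transit exclusion is the only positional rule
        good = outside
    return good, filters


def screen_tm_cargo(
    protein: AnnotatedProtein, params: ScreenParams = ScreenParams()
) -> List[CargoCall]:
    """Screen a membrane protein for the three transmembrane cargo classes.

    Returns one call per class with at least one candidate match (soluble
    proteins yield an empty list). Proteins annotated with alternative
    orientations are screened under each alternative; a class verdict is true
    if any alternative admits a passing match, and such calls are flagged
    ``orientation_ambiguous``.
    """
    if protein.is_soluble:
        return []

    catalog = builtin_patterns()
    seq = protein.sequence
    ambiguous = bool(protein.alt_orientations)
    alternatives = protein.orientation_alternatives()

    calls: List[CargoCall] = []
    for cargo_class in TM_CARGO_CLASSES:
        patterns = [catalog[_CLASS_PATTERN[cargo_class]]]
        if cargo_class == "tm_basic" and params.allow_monobasic:
            patterns.append(monobasic_pattern())
        matches: List[MotifMatch] = []
        for pat in patterns:
            matches.extend(scan(seq, pat))
        matches.sort(key=lambda m: (m.start, m.end, m.pattern_id))
        if not matches:
            continue

        best_good: List[MotifMatch] = []
        best_filters: Dict[str, bool] = {}
        for n_ori, c_ori in alternatives:
            variant = replace(protein, n_orientation=n_ori, c_orientation=c_ori,
                              alt_orientations=())
            regions = build_region_map(variant, permissive=params.permissive_topology)
            good, filters = _passing(matches, regions, cargo_class, params)
            if not best_filters or (good and not best_good):
                best_good, best_filters = good, filters
            if good:
                break
        calls.append(
            CargoCall(
                accession=protein.accession,
                cargo_class=cargo_class,
                matches=tuple(matches),
                filters_passed=dict(best_filters),
                verdict=bool(best_good),
                orientation_ambiguous=ambiguous,
            )
        )
    return calls


def screen_soluble_cargo(
    protein: AnnotatedProtein, params: ScreenParams = ScreenParams()
) -> Optional[CargoCall]:
    """Screen a soluble protein for the ILV signal outside the transit peptide."""
    if not protein.is_soluble:
        return None
    catalog = builtin_patterns()
    matches = scan(protein.sequence, catalog["ilv"])
    if not matches:
        return None
    regions = build_region_map(protein)
    good, filters = _passing(matches, regions, "soluble_ilv", params)
    return CargoCall(
        accession=protein.accession,
        cargo_class="soluble_ilv",
        matches=tuple(matches),
        filters_passed=filters,
        verdict=bool(good),
    )


# ---------------------------------------------------------------------------
# Receptors
# ---------------------------------------------------------------------------


def screen_receptor(
    protein: AnnotatedProtein, params: ScreenParams = ScreenParams()
) -> ReceptorCall:
    """Architectural receptor screen.

    Required: a GOLD domain in the C-terminal part of the mature sequence
    containing at least one dilysine match, plus a CRAL_TRIO domain.
    Reported as supporting evidence: an N-terminal coiled coil and the
    absence of membrane spans. The mature sequence is everything after the
    transit peptide; its C-terminal part is the trailing ``cterm_fraction``.
    """
    L = len(protein.record)
    mature_start = (protein.transit_peptide.end + 1) if protein.transit_peptide else 1
    mature_len = L - mature_start + 1
    # first mature position that belongs to the C-terminal part
    c_start = mature_start + int(mature_len * (1.0 - params.cterm_fraction))

    gold_spans = protein.domain_spans("GOLD")
    gold_cterm = [sp for sp in gold_spans if sp.start >= c_start]
    has_gold_cterm = bool(gold_cterm)
    has_cral_trio = bool(protein.domain_spans("CRAL_TRIO"))

    dilysine = builtin_patterns()["dilysine"]
    dilysine_matches: List[MotifMatch] = []
    for sp in gold_spans:
        if len(sp) >= dilysine.min_span:
            dilysine_matches.extend(scan(protein.sequence, dilysine, window=(sp.start, sp.end)))
    in_cterm_gold = [
        m for m in dilysine_matches if any(sp.contains_span(m.start, m.end) for sp in gold_cterm)
    ]
    dilysine_in_gold = bool(dilysine_matches)

    coiled_nterm = any(sp.start < c_start for sp in protein.coiled_coil_regions)
    lacks_tm = protein.is_soluble

    verdict = has_gold_cterm and has_cral_trio and bool(in_cterm_gold)
    return ReceptorCall(
        accession=protein.accession,
        has_gold_cterm=has_gold_cterm,
        has_cral_trio=has_cral_trio,
        dilysine_in_gold=dilysine_in_gold,
        coiled_coil_nterm=coiled_nterm,
        lacks_tm=lacks_tm,
        verdict=verdict,
        dilysine_matches=tuple(dilysine_matches),
    )


# ---------------------------------------------------------------------------
# Categorization
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CategorySummary:
    counts: Mapping[str, int]
    total: int
    photosynthesis_count: int
    fractions: Mapping[str, float]
    photosynthesis_fraction: float
    uncategorized: Tuple[str, ...] = ()


def categorize(
    calls: Sequence[CargoCall], categories: Mapping[str, str]
) -> CategorySummary:
    """Count verdict-true candidates per functional category.

    Accessions are deduplicated across cargo classes before counting.
    Accessions without a category go to the ``unknown`` bucket with a
    warning — never a silent drop. The photosynthesis super-category pools
    LHC, PSII, PSI and cytochrome b6f.
    """
    accessions = sorted({c.accession for c in calls if c.verdict})
    counts: Dict[str, int] = {cat: 0 for cat in CATEGORIES}
    uncategorized: List[str] = []
    for acc in accessions:
        cat = categories.get(acc)
        if cat is None:
            uncategorized.append(acc)
            cat = "unknown"
        elif cat not in CATEGORIES:
            raise ValueError(f"{acc}: unknown category {cat!r}")
        counts[cat] += 1
    if uncategorized:
        warnings.warn(
            f"{len(uncategorized)} candidate(s) without a category bucketed as "
            f"'unknown': {', '.join(uncategorized)}",
            stacklevel=2,
        )
    total = len(accessions)
    photo = sum(counts[c] for c in PHOTOSYNTHESIS_CATEGORIES)
    fractions = {cat: (counts[cat] / total if total else 0.0) for cat in CATEGORIES}
    return CategorySummary(
        counts=counts,
        total=total,
        photosynthesis_count=photo,
        fractions=fractions,
        photosynthesis_fraction=(photo / total if total else 0.0),
        uncategorized=tuple(uncategorized),
    )
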