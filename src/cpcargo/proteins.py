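"""Annotated-protein data model and readers/writers for FASTA and TSV inputs.

Annotations (transit peptide, membrane spans, terminus orientation, domains,
coiled coils) are *inputs* here, mirroring how the screen consumes database
annotation rather than re-predicting topology. Orientation vocabulary is
``in`` (faces the stroma) / ``out`` (lumen or intermembrane side); an
annotation may carry alternative orientations (``out/in``) when the printed
topology is ambiguous, and screens evaluate each alternative.

All tables are tab-delimited with a header row, UTF-8, and ``.`` for missing
values. Coordinates are 1-based inclusive.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from Bio import SeqIO

from .errors import AnnotationError, ProteomeError
from .patterns import VALID_SEQUENCE_LETTERS

ORIENTATIONS = ("in", "out")

#: Functional-category vocabulary used by the cargo screen's summary.
CATEGORIES = (
    "LHC",
    "PSII",
    "PSI",
    "cytb6f",
    "transport",
    "thylakoid_biogenesis",
    "stress_defense",
    "protease_chaperone",
    "unknown",
)

#: Sub-categories pooled into the photosynthesis super-category.
PHOTOSYNTHESIS_CATEGORIES = ("LHC", "PSII", "PSI", "cytb6f")

MISSING = "."


@dataclass(frozen=True, order=True)
class Span:
    """1-based inclusive residue interval."""

    start: int
    end: int

    def __post_init__(self):
        if not (1 <= self.start <= self.end):
            raise ValueError(f"invalid span {self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def contains_span(self, start: int, end: int) -> bool:
        return self.start <= start and end <= self.end

    def overlaps(self, other: "Span") -> bool:
        return self.start <= other.end and other.start <= self.end

    def render(self) -> str:
        return f"{self.start}-{self.end}"

    @classmethod
    def parse(cls, text: str) -> "Span":
        m = text.split("-")
        if len(m) != 2:
            raise ValueError(f"malformed span {text!r} (expected start-end)")
        start, end = int(m[0]), int(m[1])
        if start > end:
            raise ValueError(f"span start {start} after end {end}")
        return cls(start, end)


@dataclass(frozen=True)
class ProteinRecord:
    accession: str
    sequence: str
    description: str = ""

    def __post_init__(self):
        if not self.accession:
            raise ValueError("empty accession")
        if not self.sequence:
            raise ValueError(f"{self.accession}: empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AnnotatedProtein:
    """A protein plus the topology/domain annotation the screens consume."""

    record: ProteinRecord
    transit_peptide: Optional[Span] = None
    tm_spans: Tuple[Span, ...] = ()
    n_orientation: Optional[str] = None
    c_orientation: Optional[str] = None
    domains: Tuple[Tuple[str, Span], ...] = ()
    coiled_coil_regions: Tuple[Span, ...] = ()
    #: Alternative (n, c) orientation pairs for topology-ambiguous entries.
    alt_orientations: Tuple[Tuple[str, str], ...] = ()

    def __post_init__(self):
        L = len(self.record)
        if self.transit_peptide is not None:
            if self.transit_peptide.start != 1:
                raise ValueError(f"{self.accession}: transit peptide must start at residue 1")
            if self.transit_peptide.end > L:
                raise ValueError(f"{self.accession}: transit peptide exceeds sequence")
        prev_end = 0
        for sp in self.tm_spans:
            if sp.start <= prev_end:
                raise ValueError(f"{self.accession}: TM spans must be sorted and disjoint")
            if sp.end > L:
                raise ValueError(f"{self.accession}: TM span {sp.render()} exceeds sequence")
            prev_end = sp.end
        if self.tm_spans:
            if self.n_orientation not in ORIENTATIONS or self.c_orientation not in ORIENTATIONS:
                raise ValueError(
                    f"{self.accession}: membrane protein needs both terminus orientations"
                )
        for ori in (self.n_orientation, self.c_orientation):
            if ori is not None and ori not in ORIENTATIONS:
                raise ValueError(f"{self.accession}: orientation {ori!r} not in {ORIENTATIONS}")
        for _, sp in self.domains:
            if sp.end > L:
                raise ValueError(f"{self.accession}: domain span {sp.render()} exceeds sequence")
        for sp in self.coiled_coil_regions:
            if sp.end > L:
                raise ValueError(f"{self.accession}: coiled-coil span exceeds sequence")
        for n, c in self.alt_orientations:
            if n not in ORIENTATIONS or c not in ORIENTATIONS:
                raise ValueError(f"{self.accession}: bad alternative orientation ({n},{c})")

    @property
    def accession(self) -> str:
        return self.record.accession

    @property
    def sequence(self) -> str:
        return self.record.sequence

    @property
    def is_soluble(self) -> bool:
        return not self.tm_spans

    def domain_spans(self, name: str) -> List[Span]:
        return [sp for dn, sp in self.domains if dn == name]

    def orientation_alternatives(self) -> List[Tuple[Optional[str], Optional[str]]]:
        """Primary orientation followed by any annotated alternatives."""
        return [(self.n_orientation, self.c_orientation), *self.alt_orientations]


def default_annotation(record: ProteinRecord) -> AnnotatedProtein:
    """Annotation-free wrapper: soluble, no transit peptide, no domains."""
    return AnnotatedProtein(record=record)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def load_proteome(path) -> List[ProteinRecord]:
    """Read a FASTA proteome; accession = header token before first whitespace."""
    path = Path(path)
    records: List[ProteinRecord] = []
    seen = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        accession = entry.id
        seq = str(entry.seq).upper()
        if accession in seen:
            raise ProteomeError(f"duplicate accession {accession!r}")
        if not seq:
            raise ProteomeError(f"{accession}: empty sequence")
        bad = set(seq) - VALID_SEQUENCE_LETTERS
        if bad:
            raise ProteomeError(f"{accession}: illegal residue letters {sorted(bad)}")
        seen.add(accession)
        records.append(ProteinRecord(accession, seq, entry.description))
    if not records:
        raise ProteomeError(f"no FASTA records in {path}")
    return records


def write_proteome(path, records: Sequence[ProteinRecord], width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.description if rec.description else rec.accession
            if not header.startswith(rec.accession):
                header = f"{rec.accession} {header}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Annotation TSV
# ---------------------------------------------------------------------------

ANNOTATION_COLUMNS = (
    "accession",
    "transit_end",
    "tm_spans",
    "n_orientation",
    "c_orientation",
    "domains",
    "coiled_coils",
)


def _parse_orientation_field(text: str) -> List[str]:
    return [tok.strip().lower() for tok in text.split("/")]


def load_annotations(path, proteome: Sequence[ProteinRecord]) -> Dict[str, AnnotatedProtein]:
    """Read the annotation table; validation is total.

    Every malformed row is reported with its line number in a single
    :class:`AnnotationError`; nothing is silently part-loaded.
    """
    by_acc = {r.accession: r for r in proteome}
    out: Dict[str, AnnotatedProtein] = {}
    problems: List[Tuple[int, str]] = []

    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise AnnotationError([(1, "empty annotation file")])
        missing_cols = set(ANNOTATION_COLUMNS) - set(reader.fieldnames)
        if missing_cols:
            raise AnnotationError([(1, f"missing columns {sorted(missing_cols)}")])
        for lineno, row in enumerate(reader, start=2):
            acc = (row.get("accession") or "").strip()
            try:
                out[acc] = _parse_annotation_row(row, by_acc)
            except (ValueError, KeyError) as exc:
                problems.append((lineno, f"{acc or '<no accession>'}: {exc}"))
    if problems:
        raise AnnotationError(problems)
    return out


def _parse_annotation_row(row: Mapping[str, str], by_acc: Mapping[str, ProteinRecord]) -> AnnotatedProtein:
    acc = (row["accession"] or "").strip()
    if acc not in by_acc:
        raise ValueError("accession not present in the proteome")
    record = by_acc[acc]

    def cell(name: str) -> str:
        v = (row.get(name) or "").strip()
        return "" if v == MISSING else v

    transit = None
    if cell("transit_end"):
        end = int(cell("transit_end"))
        if not (1 <= end <= len(record)):
            raise ValueError(f"transit_end {end} outside sequence (length {len(record)})")
        transit = Span(1, end)

    tm_spans: List[Span] = []
    if cell("tm_spans"):
        for tok in cell("tm_spans").split(";"):
            tm_spans.append(Span.parse(tok.strip()))

    n_alts = _parse_orientation_field(cell("n_orientation")) if cell("n_orientation") else [None]
    c_alts = _parse_orientation_field(cell("c_orientation")) if cell("c_orientation") else [None]
    if len(n_alts) != len(c_alts):
        raise ValueError("n_orientation and c_orientation list different numbers of alternatives")
    for tok in [*n_alts, *c_alts]:
        if tok is not None and tok not in ORIENTATIONS:
            raise ValueError(f"orientation token {tok!r} not in {ORIENTATIONS}")

    domains: List[Tuple[str, Span]] = []
    if cell("domains"):
        for tok in cell("domains").split(";"):
            name, _, span_text = tok.strip().partition(":")
            if not span_text:
                raise ValueError(f"malformed domain {tok!r} (expected NAME:start-end)")
            domains.append((name, Span.parse(span_text)))

    coils: List[Span] = []
    if cell("coiled_coils"):
        for tok in cell("coiled_coils").split(";"):
            coils.append(Span.parse(tok.strip()))

    return AnnotatedProtein(
        record=record,
        transit_peptide=transit,
        tm_spans=tuple(tm_spans),
        n_orientation=n_alts[0],
        c_orientation=c_alts[0],
        domains=tuple(domains),
        coiled_coil_regions=tuple(coils),
        alt_orientations=tuple(zip(n_alts[1:], c_alts[1:])),
    )


def write_annotations(path, annotations: Mapping[str, AnnotatedProtein]) -> None:
    """Inverse of :func:`load_annotations` (exact round-trip)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(ANNOTATION_COLUMNS)
        for acc in sorted(annotations):
            ap = annotations[acc]
            n_field = c_field = MISSING
            if ap.n_orientation is not None:
                n_field = "/".join([ap.n_orientation, *(n for n, _ in ap.alt_orientations)])
            if ap.c_orientation is not None:
                c_field = "/".join([ap.c_orientation, *(c for _, c in ap.alt_orientations)])
            writer.writerow(
                [
                    acc,
                    ap.transit_peptide.end if ap.transit_peptide else MISSING,
                    ";".join(sp.render() for sp in ap.tm_spans) or MISSING,
                    n_field,
                    c_field,
                    ";".join(f"{n}:{sp.render()}" for n, sp in ap.domains) or MISSING,
                    ";".join(sp.render() for sp in ap.coiled_coil_regions) or MISSING,
                ]
            )


# ---------------------------------------------------------------------------
# Category TSV
# ---------------------------------------------------------------------------


def load_categories(path) -> Dict[str, str]:
    """Read an accession → functional-category table."""
    out: Dict[str, str] = {}
    problems: List[Tuple[int, str]] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or not {"accession", "category"} <= set(reader.fieldnames):
            raise AnnotationError([(1, "category table needs columns accession, category")])
        for lineno, row in enumerate(reader, start=2):
            acc = (row["accession"] or "").strip()
            cat = (row["category"] or "").strip()
            if cat == MISSING or not cat:
                continue
            if cat not in CATEGORIES:
                problems.append((lineno, f"{acc}: unknown category {cat!r}"))
                continue
            if acc in out:
                problems.append((lineno, f"{acc}: duplicate category row"))
                continue
            out[acc] = cat
    if problems:
        raise AnnotationError(problems)
    return out


def write_categories(path, categories: Mapping[str, str]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["accession", "category"])
        for acc in sorted(categories):
            writer.writerow([acc, categories[acc]])
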