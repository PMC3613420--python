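"""Packaged reference tables of curated Arabidopsis thylakoid cargo candidates.

The package ships small transcribed tables of the published candidate sets
the screen was designed around: putative transmembrane cargo proteins with
their printed motif evidence, membrane-span counts and topologies; putative
soluble cargo proteins with their printed ILV motif strings; the curated
functional category of each candidate; and a localization-evidence table for
the vesicle-initiation / receptor candidates. These drive worked examples
and count checks without any database download.

The printed evidence is motif *strings*, not full sequences, so the fixture
screen checks pattern membership only; the positional filters need full
annotated sequences and are exercised on synthetic proteomes instead.
"""

from __future__ import annotations

import csv
from importlib import resources
from typing import Dict, List, Mapping, Tuple

from .localization import LocalizationEvidence, _parse_evidence_row
from .patterns import builtin_patterns, scan
from .proteins import CATEGORIES
from .screen import CargoCall

_SECTION_PATTERN = {"diacidic": "diacidic", "basic": "basic", "dihydrophobic": "dihydrophobic"}


def _read(name: str) -> List[Dict[str, str]]:
    ref = resources.files("cpcargo.data").joinpath(name)
    with ref.open("r", newline="") as fh:
        return list(csv.DictReader(fh, delimiter="\t"))


def reference_tm_cargo() -> List[Dict[str, str]]:
    """Transmembrane cargo candidates: accession, name, section
    (diacidic | basic | dihydrophobic), printed motif strings, membrane-span
    count and printed topology."""
    return _read("tm_cargo_reference.tsv")


def reference_soluble_cargo() -> List[Dict[str, str]]:
    """Soluble (ILV) cargo candidates with their printed 14-mer motifs."""
    return _read("soluble_cargo_reference.tsv")


def reference_categories() -> Dict[str, str]:
    """Curated accession -> functional category map for the candidates."""
    out = {}
    for row in _read("categories_reference.tsv"):
        cat = row["category"]
        if cat not in CATEGORIES:
            raise ValueError(f"fixture category {cat!r} outside vocabulary")
        out[row["accession"]] = cat
    return out


def reference_evidence() -> Dict[str, LocalizationEvidence]:
    """Localization evidence for the vesicle-initiation/receptor candidates."""
    out = {}
    for row in _read("evidence_reference.tsv"):
        acc = row["accession"]
        out[acc] = _parse_evidence_row(acc, row)
    return out


def screen_reference_motifs() -> List[CargoCall]:
    """Re-screen the printed motif strings with the compiled catalog patterns.

    Each candidate's printed motif strings are scanned with the pattern of
    its class; the verdict is true when at least one string matches. Returns
    one call per (accession, class), deduplicated downstream as usual.
    """
    catalog = builtin_patterns()
    calls: List[CargoCall] = []

    section_to_class = {
        "diacidic": "tm_diacidic",
        "basic": "tm_basic",
        "dihydrophobic": "tm_dihydrophobic",
    }
    for row in reference_tm_cargo():
        pattern = catalog[_SECTION_PATTERN[row["section"]]]
        matches = []
        for motif in row["motifs"].split(","):
            matches.extend(scan(motif, pattern))
        calls.append(
            CargoCall(
                accession=row["accession"],
                cargo_class=section_to_class[row["section"]],
                matches=tuple(matches),
                filters_passed={"pattern_match": bool(matches)},
                verdict=bool(matches),
            )
        )

    ilv = catalog["ilv"]
    for row in reference_soluble_cargo():
        matches = []
        for motif in row["motifs"].split(","):
            matches.extend(scan(motif, ilv))
        calls.append(
            CargoCall(
                accession=row["accession"],
                cargo_class="soluble_ilv",
                matches=tuple(matches),
                filters_passed={"pattern_match": bool(matches)},
                verdict=bool(matches),
            )
        )
    calls.sort(key=lambda c: (c.accession, c.cargo_class))
    return calls


def reference_section_counts() -> Dict[str, int]:
    """Distinct matching accessions per motif section of the reference tables."""
    counts = {"diacidic": set(), "basic": set(), "dihydrophobic": set(), "ilv": set()}
    for call in screen_reference_motifs():
        if not call.verdict:
            continue
        key = {
            "tm_diacidic": "diacidic",
            "tm_basic": "basic",
            "tm_dihydrophobic": "dihydrophobic",
            "soluble_ilv": "ilv",
        }[call.cargo_class]
        counts[key].add(call.accession)
    return {k: len(v) for k, v in counts.items()}
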