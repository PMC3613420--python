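"""Pipeline orchestration and deterministic report writing.

The full screen runs in the stage order of the underlying workflow: motif
screens on every protein (membrane cargo, soluble cargo, receptors), then
the localization decision tree on whatever evidence is supplied. A candidate
survives when its screen verdict is true and — if evidence was provided —
its localization verdict is accepted. Reports are TSV plus JSON with a fixed
row order (accession, then cargo class), so reruns are byte-identical.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from . import __version__
from .localization import LocalizationEvidence, LocalizationVerdict, decide_localization
from .proteins import AnnotatedProtein, ProteinRecord, default_annotation
from .screen import (
    CargoCall,
    CategorySummary,
    ReceptorCall,
    ScreenParams,
    categorize,
    screen_receptor,
    screen_soluble_cargo,
    screen_tm_cargo,
)

logger = logging.getLogger("cpcargo")


@dataclass(frozen=True)
class PipelineParams:
    screen: ScreenParams = ScreenParams()
    threshold: float = 10.0
    min_tools: int = 2

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class PipelineResult:
    cargo_calls: List[CargoCall]
    receptor_calls: List[ReceptorCall]
    verdicts: Dict[str, LocalizationVerdict]
    summary: Optional[CategorySummary]
    params: PipelineParams

    def accepted(self, accession: str) -> bool:
        """Localization gate: accept when no evidence table was supplied."""
        if not self.verdicts:
            return True
        v = self.verdicts.get(accession)
        return v is not None and v.accepted

    def candidate_calls(self) -> List[CargoCall]:
        return [c for c in self.cargo_calls if c.verdict and self.accepted(c.accession)]


def run_screens(
    records: Sequence[ProteinRecord],
    annotations: Mapping[str, AnnotatedProtein],
    params: ScreenParams = ScreenParams(),
) -> Tuple[List[CargoCall], List[ReceptorCall]]:
    """Motif + architecture screens over a proteome (deterministic order)."""
    cargo: List[CargoCall] = []
    receptors: List[ReceptorCall] = []
    for rec in sorted(records, key=lambda r: r.accession):
        ap = annotations.get(rec.accession) or default_annotation(rec)
        if ap.is_soluble:
            call = screen_soluble_cargo(ap, params)
            if call is not None:
                cargo.append(call)
        else:
            cargo.extend(screen_tm_cargo(ap, params))
        if ap.domains or ap.coiled_coil_regions:
            receptors.append(screen_receptor(ap, params))
    cargo.sort(key=lambda c: (c.accession, c.cargo_class))
    receptors.sort(key=lambda r: r.accession)
    return cargo, receptors


def run_pipeline(
    records: Sequence[ProteinRecord],
    annotations: Mapping[str, AnnotatedProtein],
    evidence: Optional[Mapping[str, LocalizationEvidence]] = None,
    categories: Optional[Mapping[str, str]] = None,
    params: PipelineParams = PipelineParams(),
) -> PipelineResult:
    logger.info(
        "cpcargo %s | config %s | %d proteins",
        __version__, params.config_hash(), len(records),
    )
    cargo, receptors = run_screens(records, annotations, params.screen)
    verdicts: Dict[str, LocalizationVerdict] = {}
    if evidence:
        for acc in sorted(evidence):
            verdicts[acc] = decide_localization(
                evidence[acc], threshold=params.threshold, min_tools=params.min_tools
            )
    result = PipelineResult(cargo, receptors, verdicts, None, params)
    if categories is not None:
        result.summary = categorize(result.candidate_calls(), categories)
    return result


# ---------------------------------------------------------------------------
# Report writing
# ---------------------------------------------------------------------------

CARGO_REPORT_COLUMNS = (
    "accession", "cargo_class", "verdict", "motifs", "match_spans",
    "filters_passed", "orientation_ambiguous", "localization_route",
    "supporting_tools", "evidence_notes",
)

RECEPTOR_REPORT_COLUMNS = (
    "accession", "verdict", "has_gold_cterm", "has_cral_trio",
    "dilysine_in_gold", "coiled_coil_nterm", "lacks_tm", "dilysine_spans",
)


def _tsv(path: Path, header: Sequence[str], rows: Sequence[Sequence]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(header)
        writer.writerows(rows)


def write_report(result: PipelineResult, outdir) -> Dict[str, Path]:
    """Write cargo/receptor/localization/summary tables plus a JSON report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, Path] = {}

    cargo_rows = []
    for c in result.cargo_calls:
        v = result.verdicts.get(c.accession)
        cargo_rows.append([
            c.accession,
            c.cargo_class,
            int(c.verdict),
            ",".join(m.matched_text for m in c.matches),
            ",".join(f"{m.start}-{m.end}" for m in c.matches),
            ";".join(f"{k}={int(b)}" for k, b in sorted(c.filters_passed.items())),
            int(c.orientation_ambiguous),
            v.route if v else ".",
            ",".join(v.supporting_tools) if v else ".",
            ";".join(v.evidence_notes) if v else ".",
        ])
    paths["cargo"] = outdir / "cargo_calls.tsv"
    _tsv(paths["cargo"], CARGO_REPORT_COLUMNS, cargo_rows)

    receptor_rows = [
        [
            r.accession, int(r.verdict), int(r.has_gold_cterm), int(r.has_cral_trio),
            int(r.dilysine_in_gold), int(r.coiled_coil_nterm), int(r.lacks_tm),
            ",".join(f"{m.start}-{m.end}" for m in r.dilysine_matches),
        ]
        for r in result.receptor_calls
    ]
    paths["receptors"] = outdir / "receptor_calls.tsv"
    _tsv(paths["receptors"], RECEPTOR_REPORT_COLUMNS, receptor_rows)

    loc_rows = [
        [acc, int(v.accepted), v.route, ",".join(v.supporting_tools), ";".join(v.evidence_notes)]
        for acc, v in sorted(result.verdicts.items())
    ]
    paths["localization"] = outdir / "localization.tsv"
    _tsv(paths["localization"], ("accession", "accepted", "route", "supporting_tools", "evidence_notes"), loc_rows)

    payload: Dict[str, object] = {
        "version": __version__,
        "config_hash": result.params.config_hash(),
        "n_cargo_calls": len(result.cargo_calls),
        "n_candidates": len({c.accession for c in result.candidate_calls()}),
        "n_receptor_hits": sum(1 for r in result.receptor_calls if r.verdict),
    }
    if result.summary is not None:
        s = result.summary
        summary_rows = [[cat, s.counts[cat], round(s.fractions[cat], 4)] for cat in s.counts]
        summary_rows.append(["photosynthesis", s.photosynthesis_count,
                             round(s.photosynthesis_fraction, 4)])
        paths["summary"] = outdir / "category_summary.tsv"
        _tsv(paths["summary"], ("category", "count", "fraction"), summary_rows)
        payload["categories"] = {
            "counts": dict(s.counts),
            "total": s.total,
            "photosynthesis_count": s.photosynthesis_count,
            "photosynthesis_fraction": round(s.photosynthesis_fraction, 4),
            "uncategorized": list(s.uncategorized),
        }
    paths["json"] = outdir / "report.json"
    with open(paths["json"], "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return paths
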