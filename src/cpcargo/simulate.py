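"""Synthetic annotated proteomes with planted sorting signals and ground truth.

The generator emulates the statistical structure the screens assume about
plant proteins: cleavable N-terminal transit peptides of 30-80 residues
drawn from a serine/threonine-enriched composition, membrane spans of 18-24
residues drawn from a hydrophobic-enriched composition, and uniform
background elsewhere. Sorting signals are planted verbatim at recorded
coordinates — either correctly placed, or as controls that each violate
exactly one positional rule (wrong region, wrong orientation / proximity,
inside the transit peptide) so that a failing filter is attributable.

To make planted-signal recovery exact *by construction*, accidental
catalog-pattern occurrences that do not overlap a planted signal are
scrubbed (rewritten with residues outside every signal class). Localization
evidence is fabricated separately with configurable noise: a true
chloroplast protein receives a reliable consensus score with probability
``1 - miscall`` and otherwise falls back on individual tool calls that
succeed with probability ``fallback_success``.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .errors import SimulationError
from .localization import LocalizationEvidence
from .patterns import AMINO_ACIDS, MotifPattern, builtin_patterns, scan
from .proteins import AnnotatedProtein, ProteinRecord, Span
from .screen import CARGO_CLASSES, TM_CARGO_CLASSES

_AA = sorted(AMINO_ACIDS)

#: Residues that belong to no catalog signal class; scrub targets and planted
#: wildcards are drawn from these so they can never complete a signal.
NEUTRAL_RESIDUES = sorted(AMINO_ACIDS - set("DEFYRKILV"))

# Average composition of plant proteins (coarse published values), offered as
# an alternative to the uniform default.
AVERAGE_COMPOSITION = {
    "A": 0.074, "C": 0.025, "D": 0.054, "E": 0.054, "F": 0.047, "G": 0.074,
    "H": 0.026, "I": 0.068, "K": 0.058, "L": 0.099, "M": 0.025, "N": 0.045,
    "P": 0.039, "Q": 0.034, "R": 0.052, "S": 0.057, "T": 0.051, "V": 0.073,
    "W": 0.013, "Y": 0.032,
}

_TM_ENRICHED = {"A": 0.10, "F": 0.12, "G": 0.07, "I": 0.16, "L": 0.22,
                "M": 0.05, "V": 0.16, "W": 0.04, "T": 0.04, "S": 0.04}
_TRANSIT_ENRICHED = {"S": 0.20, "T": 0.12, "A": 0.14, "R": 0.08, "K": 0.05,
                     "L": 0.08, "V": 0.07, "P": 0.06, "N": 0.05, "G": 0.05,
                     "M": 0.04, "Q": 0.03, "F": 0.03}

CONTROL_TYPES = ("correct", "wrong_region", "wrong_orientation", "inside_transit")


@dataclass(frozen=True)
class MotifPlan:
    """Planted-signal counts for one cargo class."""

    correct: int = 0
    wrong_region: int = 0
    wrong_orientation: int = 0
    inside_transit: int = 0

    def __post_init__(self):
        if min(self.correct, self.wrong_region, self.wrong_orientation,
               self.inside_transit) < 0:
            raise ValueError("plan counts must be non-negative")

    @property
    def total(self) -> int:
        return self.correct + self.wrong_region + self.wrong_orientation + self.inside_transit


@dataclass(frozen=True)
class ReceptorPlan:
    correct: int = 2
    gold_at_nterm: int = 1
    missing_cral_trio: int = 1

    @property
    def total(self) -> int:
        return self.correct + self.gold_at_nterm + self.missing_cral_trio


@dataclass(frozen=True)
class LocalizationNoise:
    miscall: float = 0.0
    fallback_success: float = 1.0
    ceiling: float = 20.0
    threshold: float = 10.0
    min_tools: int = 2

    def __post_init__(self):
        for p in (self.miscall, self.fallback_success):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


def _default_plans() -> Dict[str, MotifPlan]:
    return {
        "tm_diacidic": MotifPlan(correct=5, wrong_region=3, wrong_orientation=3, inside_transit=3),
        "tm_dihydrophobic": MotifPlan(correct=5, wrong_region=3, wrong_orientation=3, inside_transit=3),
        # the basic signal's rule is positional, not orientational; its
        # "wrong_orientation" control violates the proximity window instead
        "tm_basic": MotifPlan(correct=5, wrong_region=3, wrong_orientation=3, inside_transit=3),
        "soluble_ilv": MotifPlan(correct=5, inside_transit=3),
    }


@dataclass(frozen=True)
class SimulationConfig:
    n_proteins: int = 200
    fraction_chloroplast: float = 0.5
    transit_length_range: Tuple[int, int] = (30, 80)
    tm_count_distribution: Mapping[int, float] = field(
        default_factory=lambda: {0: 0.4, 1: 0.3, 2: 0.2, 3: 0.1}
    )
    tm_length_range: Tuple[int, int] = (18, 24)
    motif_plans: Mapping[str, MotifPlan] = field(default_factory=_default_plans)
    receptor_plan: ReceptorPlan = ReceptorPlan()
    background: str = "uniform"  # or "average"
    noise: LocalizationNoise = LocalizationNoise()
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.fraction_chloroplast <= 1.0:
            raise ValueError("fraction_chloroplast must lie in [0, 1]")
        for lo, hi in (self.transit_length_range, self.tm_length_range):
            if not 1 <= lo < hi:
                raise ValueError("length ranges must be non-degenerate")
        unknown = set(self.motif_plans) - set(CARGO_CLASSES)
        if unknown:
            raise ValueError(f"motif plans for unknown classes {sorted(unknown)}")
        if self.background not in ("uniform", "average"):
            raise ValueError("background must be 'uniform' or 'average'")

    @property
    def planted_protein_count(self) -> int:
        return sum(p.total for p in self.motif_plans.values()) + self.receptor_plan.total


@dataclass(frozen=True)
class PlantedMotif:
    cargo_class: str
    pattern_id: str
    span: Span
    control_type: str
    should_pass: bool


@dataclass(frozen=True)
class ProteinTruth:
    accession: str
    compartment: str  # chloroplast | other
    transit: Optional[Span]
    planted: Tuple[PlantedMotif, ...] = ()
    category: Optional[str] = None
    is_receptor: bool = False
    receptor_should_pass: bool = False


@dataclass(frozen=True)
class TruthTable:
    entries: Mapping[str, ProteinTruth]

    def should_pass(self, cargo_class: Optional[str] = None) -> Dict[str, List[PlantedMotif]]:
        out: Dict[str, List[PlantedMotif]] = {}
        for acc, t in self.entries.items():
            hits = [
                p for p in t.planted
                if p.should_pass and (cargo_class is None or p.cargo_class == cargo_class)
            ]
            if hits:
                out[acc] = hits
        return out

    def chloroplast_accessions(self) -> List[str]:
        return sorted(a for a, t in self.entries.items() if t.compartment == "chloroplast")

    def to_json(self) -> str:
        def encode(obj):
            if isinstance(obj, Span):
                return {"start": obj.start, "end": obj.end}
            return asdict(obj)

        payload = {
            acc: {
                "compartment": t.compartment,
                "transit": encode(t.transit) if t.transit else None,
                "planted": [
                    {
                        "cargo_class": p.cargo_class,
                        "pattern_id": p.pattern_id,
                        "start": p.span.start,
                        "end": p.span.end,
                        "control_type": p.control_type,
                        "should_pass": p.should_pass,
                    }
                    for p in t.planted
                ],
                "category": t.category,
                "is_receptor": t.is_receptor,
                "receptor_should_pass": t.receptor_should_pass,
            }
            for acc, t in sorted(self.entries.items())
        }
        return json.dumps(payload, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# sequence building blocks
# ---------------------------------------------------------------------------


def _freqs(table: Mapping[str, float]) -> Tuple[List[str], np.ndarray]:
    letters = sorted(table)
    probs = np.array([table[l] for l in letters], dtype=float)
    probs = probs / probs.sum()
    return letters, probs


def _draw(rng, n: int, letters: Sequence[str], probs: Optional[np.ndarray]) -> List[str]:
    idx = rng.choice(len(letters), size=n, p=probs)
    return [letters[i] for i in idx]


class _SequenceFactory:
    def __init__(self, config: SimulationConfig, rng: np.random.Generator):
        self.rng = rng
        self.config = config
        if config.background == "uniform":
            self.bg_letters, self.bg_probs = _AA, None
        else:
            self.bg_letters, self.bg_probs = _freqs(AVERAGE_COMPOSITION)
        self.tm_letters, self.tm_probs = _freqs(_TM_ENRICHED)
        self.tp_letters, self.tp_probs = _freqs(_TRANSIT_ENRICHED)

    def background(self, n: int) -> List[str]:
        return _draw(self.rng, n, self.bg_letters, self.bg_probs)

    def tm(self, n: int) -> List[str]:
        return _draw(self.rng, n, self.tm_letters, self.tm_probs)

    def transit(self, n: int) -> List[str]:
        return _draw(self.rng, n, self.tp_letters, self.tp_probs)

    def uniform_int(self, lo: int, hi: int) -> int:
        return int(self.rng.integers(lo, hi + 1))


def sample_motif_instance(pattern: MotifPattern, rng: np.random.Generator) -> str:
    """A concrete string matching *pattern*; wildcard positions use neutral
    residues so the planted string can never seed another signal class."""
    out: List[str] = []
    for e in pattern.elements:
        reps = int(rng.integers(e.min_repeat, e.max_repeat + 1))
        for _ in range(reps):
            if e.is_wildcard:
                out.append(NEUTRAL_RESIDUES[int(rng.integers(len(NEUTRAL_RESIDUES)))])
            else:
                pool = sorted(e.residues) if not e.negated else sorted(AMINO_ACIDS - e.residues)
                out.append(pool[int(rng.integers(len(pool)))])
    return "".join(out)


def _scrub(seq: List[str], planted: Sequence[Span], rng: np.random.Generator) -> None:
    """Rewrite accidental catalog-pattern matches that do not overlap any
    planted span, using neutral residues. Iterates to a fixpoint."""
    catalog = builtin_patterns()
    for _ in range(12):
        text = "".join(seq)
        dirty = False
        for pat in catalog.values():
            for m in scan(text, pat):
                if any(sp.start <= m.end and m.start <= sp.end for sp in planted):
                    continue
                targets = [
                    p for p in range(m.start - 1, m.end)
                    if not any(sp.start - 1 <= p <= sp.end - 1 for sp in planted)
                    and seq[p] not in NEUTRAL_RESIDUES
                ]
                for p in targets:
                    seq[p] = NEUTRAL_RESIDUES[int(rng.integers(len(NEUTRAL_RESIDUES)))]
                if targets:
                    dirty = True
        if not dirty:
            return
    raise SimulationError("scrubbing did not converge")  # pragma: no cover


# ---------------------------------------------------------------------------
# protein builders
# ---------------------------------------------------------------------------


def _build_tm_cargo(
    fac: _SequenceFactory,
    accession: str,
    cargo_class: str,
    control_type: str,
    rng: np.random.Generator,
) -> Tuple[ProteinRecord, AnnotatedProtein, ProteinTruth]:
    cfg = fac.config
    catalog = builtin_patterns()
    pattern = catalog[{"tm_diacidic": "diacidic",
                       "tm_dihydrophobic": "dihydrophobic",
                       "tm_basic": "basic"}[cargo_class]]
    motif = sample_motif_instance(pattern, rng)
    k = len(motif)

    tp_len = fac.uniform_int(*cfg.transit_length_range)
    tm_len = fac.uniform_int(*cfg.tm_length_range)
    c_len = fac.uniform_int(40, 90)
    window = 25  # matches the screen default recorded in topology

    if cargo_class == "tm_basic" and control_type == "wrong_orientation":
        n_len = fac.uniform_int(window + k + 10, window + k + 40)
    else:
        n_len = fac.uniform_int(30, 60)

    tm_start = tp_len + n_len + 1
    seq = (
        fac.transit(tp_len)
        + fac.background(n_len)
        + fac.tm(tm_len)
        + fac.background(c_len)
    )
    L = len(seq)

    # orientation: C-tail must face the stroma for the C-terminal signals
    if cargo_class in ("tm_diacidic", "tm_dihydrophobic"):
        n_ori, c_ori = ("out", "in") if control_type != "wrong_orientation" else ("in", "out")
    else:
        n_ori, c_ori = "in", "out"

    # placement
    if control_type == "inside_transit":
        start = fac.uniform_int(2, tp_len - k + 1)
    elif cargo_class in ("tm_diacidic", "tm_dihydrophobic"):
        if control_type == "wrong_region":
            start = fac.uniform_int(tp_len + 1, tp_len + n_len - k + 1)
        else:  # correct or wrong_orientation: in the C-tail
            start = fac.uniform_int(tm_start + tm_len, L - k + 1)
    else:  # tm_basic in the N-tail
        if control_type == "wrong_region":
            start = fac.uniform_int(tm_start + tm_len, L - k + 1)
        elif control_type == "wrong_orientation":  # proximity violation
            start = fac.uniform_int(tp_len + 1, tm_start - window - k)
        else:
            start = fac.uniform_int(max(tp_len + 1, tm_start - window), tm_start - k)

    seq[start - 1 : start - 1 + k] = list(motif)
    span = Span(start, start + k - 1)
    _scrub(seq, [span], rng)

    record = ProteinRecord(accession, "".join(seq))
    annotated = AnnotatedProtein(
        record=record,
        transit_peptide=Span(1, tp_len),
        tm_spans=(Span(tm_start, tm_start + tm_len - 1),),
        n_orientation=n_ori,
        c_orientation=c_ori,
    )
    truth = ProteinTruth(
        accession=accession,
        compartment="chloroplast",
        transit=Span(1, tp_len),
        planted=(
            PlantedMotif(cargo_class, pattern.pattern_id, span, control_type,
                         should_pass=(control_type == "correct")),
        ),
    )
    return record, annotated, truth


def _build_soluble_cargo(
    fac: _SequenceFactory,
    accession: str,
    control_type: str,
    rng: np.random.Generator,
) -> Tuple[ProteinRecord, AnnotatedProtein, ProteinTruth]:
    cfg = fac.config
    pattern = builtin_patterns()["ilv"]
    motif = sample_motif_instance(pattern, rng)
    k = len(motif)

    tp_len = fac.uniform_int(max(cfg.transit_length_range[0], k + 2), cfg.transit_length_range[1])
    mature_len = fac.uniform_int(100, 200)
    seq = fac.transit(tp_len) + fac.background(mature_len)
    L = len(seq)

    if control_type == "inside_transit":
        start = fac.uniform_int(2, tp_len - k + 1)
    else:
        start = fac.uniform_int(tp_len + 1, L - k + 1)

    seq[start - 1 : start - 1 + k] = list(motif)
    span = Span(start, start + k - 1)
    _scrub(seq, [span], rng)

    record = ProteinRecord(accession, "".join(seq))
    annotated = AnnotatedProtein(record=record, transit_peptide=Span(1, tp_len))
    truth = ProteinTruth(
        accession=accession,
        compartment="chloroplast",
        transit=Span(1, tp_len),
        planted=(
            PlantedMotif("soluble_ilv", pattern.pattern_id, span, control_type,
                         should_pass=(control_type == "correct")),
        ),
    )
    return record, annotated, truth


def _build_receptor(
    fac: _SequenceFactory,
    accession: str,
    control_type: str,  # correct | gold_at_nterm | missing_cral_trio
    rng: np.random.Generator,
) -> Tuple[ProteinRecord, AnnotatedProtein, ProteinTruth]:
    cfg = fac.config
    dilysine = builtin_patterns()["dilysine"]
    motif = sample_motif_instance(dilysine, rng)
    k = len(motif)

    tp_len = fac.uniform_int(*cfg.transit_length_range)
    mature_len = 300
    seq = fac.transit(tp_len) + fac.background(mature_len)
    L = len(seq)
    mid = tp_len + mature_len // 2

    gold_len = 90
    if control_type == "gold_at_nterm":
        gold = Span(tp_len + 5, tp_len + 4 + gold_len)
    else:
        gold = Span(L - gold_len - 5, L - 6)
    cral = Span(mid - 60, mid + 20) if control_type != "missing_cral_trio" else None
    coil = Span(tp_len + 10, tp_len + 40)

    start = fac.uniform_int(gold.start, gold.end - k + 1)
    seq[start - 1 : start - 1 + k] = list(motif)
    span = Span(start, start + k - 1)
    _scrub(seq, [span], rng)

    domains: List[Tuple[str, Span]] = [("GOLD", gold)]
    if cral is not None:
        domains.append(("CRAL_TRIO", cral))

    record = ProteinRecord(accession, "".join(seq))
    annotated = AnnotatedProtein(
        record=record,
        transit_peptide=Span(1, tp_len),
        domains=tuple(domains),
        coiled_coil_regions=(coil,),
    )
    truth = ProteinTruth(
        accession=accession,
        compartment="chloroplast",
        transit=Span(1, tp_len),
        is_receptor=True,
        receptor_should_pass=(control_type == "correct"),
    )
    return record, annotated, truth


def _build_filler(
    fac: _SequenceFactory,
    accession: str,
    chloroplast: bool,
    rng: np.random.Generator,
) -> Tuple[ProteinRecord, AnnotatedProtein, ProteinTruth]:
    cfg = fac.config
    counts, probs = zip(*sorted(cfg.tm_count_distribution.items()))
    n_tm = int(rng.choice(counts, p=np.array(probs) / sum(probs)))

    parts: List[str] = []
    tp_len = 0
    if chloroplast:
        tp_len = fac.uniform_int(*cfg.transit_length_range)
        parts.extend(fac.transit(tp_len))
    tm_spans: List[Span] = []
    parts.extend(fac.background(fac.uniform_int(30, 60)))
    for _ in range(n_tm):
        tm_len = fac.uniform_int(*cfg.tm_length_range)
        start = len(parts) + 1
        parts.extend(fac.tm(tm_len))
        tm_spans.append(Span(start, start + tm_len - 1))
        parts.extend(fac.background(fac.uniform_int(25, 60)))

    seq = parts
    _scrub(seq, [], rng)

    n_ori = c_ori = None
    if tm_spans:
        n_ori = "in" if rng.random() < 0.5 else "out"
        c_ori = n_ori if len(tm_spans) % 2 == 0 else ("in" if n_ori == "out" else "out")

    record = ProteinRecord(accession, "".join(seq))
    annotated = AnnotatedProtein(
        record=record,
        transit_peptide=Span(1, tp_len) if tp_len else None,
        tm_spans=tuple(tm_spans),
        n_orientation=n_ori,
        c_orientation=c_ori,
    )
    truth = ProteinTruth(
        accession=accession,
        compartment="chloroplast" if chloroplast else "other",
        transit=Span(1, tp_len) if tp_len else None,
    )
    return record, annotated, truth


# ---------------------------------------------------------------------------
# top-level generators
# ---------------------------------------------------------------------------

_CATEGORY_CYCLE = ("LHC", "PSII", "PSI", "cytb6f", "transport",
                   "thylakoid_biogenesis", "stress_defense", "protease_chaperone")


def generate_proteome(
    config: SimulationConfig,
) -> Tuple[List[ProteinRecord], Dict[str, AnnotatedProtein], TruthTable]:
    """Generate (records, annotations, truth) deterministically from the seed."""
    if config.planted_protein_count > config.n_proteins:
        raise SimulationError(
            f"motif plan needs {config.planted_protein_count} proteins but "
            f"n_proteins={config.n_proteins}"
        )
    rng = np.random.default_rng(config.seed)
    fac = _SequenceFactory(config, rng)

    records: List[ProteinRecord] = []
    annotations: Dict[str, AnnotatedProtein] = {}
    truths: Dict[str, ProteinTruth] = {}
    counter = 0

    def register(rec, ann, truth):
        records.append(rec)
        annotations[rec.accession] = ann
        truths[rec.accession] = truth

    def next_acc() -> str:
        nonlocal counter
        counter += 1
        return f"SYN{counter:04d}"

    for cargo_class in CARGO_CLASSES:
        plan = config.motif_plans.get(cargo_class, MotifPlan())
        for control_type in CONTROL_TYPES:
            for _ in range(getattr(plan, control_type)):
                acc = next_acc()
                if cargo_class == "soluble_ilv":
                    register(*_build_soluble_cargo(fac, acc, control_type, rng))
                else:
                    register(*_build_tm_cargo(fac, acc, cargo_class, control_type, rng))

    for control_type, count in (
        ("correct", config.receptor_plan.correct),
        ("gold_at_nterm", config.receptor_plan.gold_at_nterm),
        ("missing_cral_trio", config.receptor_plan.missing_cral_trio),
    ):
        for _ in range(count):
            register(*_build_receptor(fac, next_acc(), control_type, rng))

    n_fill = config.n_proteins - len(records)
    n_chloro_target = int(round(config.fraction_chloroplast * config.n_proteins))
    n_chloro_fill = max(0, min(n_fill, n_chloro_target - len(records)))
    for i in range(n_fill):
        register(*_build_filler(fac, next_acc(), chloroplast=(i < n_chloro_fill), rng=rng))

    # deterministic categories for true cargo candidates; fillers are unknown
    cat_i = 0
    for acc in sorted(truths):
        t = truths[acc]
        if any(p.should_pass for p in t.planted):
            truths[acc] = ProteinTruth(
                accession=t.accession, compartment=t.compartment, transit=t.transit,
                planted=t.planted, category=_CATEGORY_CYCLE[cat_i % len(_CATEGORY_CYCLE)],
                is_receptor=t.is_receptor, receptor_should_pass=t.receptor_should_pass,
            )
            cat_i += 1
        elif t.compartment == "chloroplast":
            truths[acc] = ProteinTruth(
                accession=t.accession, compartment=t.compartment, transit=t.transit,
                planted=t.planted, category="unknown",
                is_receptor=t.is_receptor, receptor_should_pass=t.receptor_should_pass,
            )

    return records, annotations, TruthTable(truths)


_TOOL_NAMES = ("ToolA", "ToolB", "ToolC", "ToolD", "ToolE", "ToolF")


def generate_localization_evidence(
    truth: TruthTable, config: SimulationConfig
) -> Dict[str, LocalizationEvidence]:
    """Fabricate per-protein localization evidence with configured noise."""
    noise = config.noise
    rng = np.random.default_rng([config.seed, 7919])
    out: Dict[str, LocalizationEvidence] = {}
    for acc in sorted(truth.entries):
        t = truth.entries[acc]
        tools: Dict[str, str] = {}
        flags: Dict[str, object] = {}
        if t.compartment == "chloroplast":
            if rng.random() >= noise.miscall:
                chl = float(rng.uniform(noise.threshold, noise.ceiling))
                n_correct = 3
            else:
                chl = float(rng.uniform(0.0, noise.threshold * 0.9))
                if rng.random() < noise.fallback_success:
                    n_correct = noise.min_tools + int(rng.integers(0, 2))
                else:
                    n_correct = int(rng.integers(0, noise.min_tools))
            scores = {"chloroplast": chl,
                      "mitochondrion": float(rng.uniform(0, 3)),
                      "secretory": float(rng.uniform(0, 3))}
            for name in _TOOL_NAMES[:n_correct]:
                tools[name] = "chloroplast"
            if rng.random() < 0.5:
                flags["proteomics_msms"] = "chloroplast"
            if rng.random() < 0.5:
                flags["chloroplast2010"] = True
        else:
            other = "mitochondrion" if rng.random() < 0.5 else "secretory"
            scores = {"chloroplast": float(rng.uniform(0.0, noise.threshold / 2)),
                      "mitochondrion": 0.0, "secretory": 0.0}
            scores[other] = float(rng.uniform(noise.threshold, noise.ceiling))
            tools[_TOOL_NAMES[0]] = other
        out[acc] = LocalizationEvidence(
            accession=acc, consensus_scores=scores, tool_calls=tools,
            experimental_flags=flags,
        )
    return out
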