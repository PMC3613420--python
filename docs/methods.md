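# Methods

## Screening model

The pipeline treats chloroplast vesicle cargo selection as a transfer of
the cytosolic COPII cargo-signal grammar, with the stroma as the analogue
of the cytosol. A candidate must satisfy three layers of evidence:

1. **Signal match.** One of five hand-built Prosite-style patterns:
   diacidic `[DE]-x-[DE]`, dihydrophobic `[FY](2)`, di/mono-basic
   `[RK]-x(0,1)-[RK]`, soluble-cargo ILV `I-x(2)-L-x(9)-V`, and receptor
   dilysine `K-x(0,1)-K-x(2)`. The dibasic signal is defined with a
   one-residue spacer in the COPII literature, but the printed candidate
   evidence is adjacent `KK`; the catalog therefore uses `x(0,1)`, and the
   strict spacer form remains available through `compile_pattern`. The
   monobasic fallback (a single `[RK]`) is off by default — no source rule
   says when it applies — and is enabled by an explicit flag.
2. **Position and topology.** Diacidic/dihydrophobic signals must lie
   wholly in a C-tail whose side is stromal; the basic signal must lie in
   the N-tail within a proximity window of the first membrane span; all
   signals must avoid the transit peptide, which is removed on import.
   Sides are assigned by alternation from the annotated N-terminus
   orientation across the membrane spans and must land on the annotated
   C-terminus orientation; a contradiction is an error unless the
   permissive flag is set, in which case the C-tail side follows the
   C-terminus annotation. Entries annotated with alternative topologies are
   screened under each alternative and flagged `orientation_ambiguous`.
3. **Localization.** The consensus decision tree accepts on a chloroplast
   consensus score ≥ threshold (default 10, inclusive), else on ≥
   `min_tools` (default 2) individual predictor calls; experimental flags
   (proteomics MS/MS, prediction-project membership, curated entries) are
   carried as notes only. Consensus scores are *inputs*; the package does
   not re-derive the external Bayesian aggregator. The `aggregate_scores`
   helper (normalized weighted mean rescaled to a ceiling) exists solely to
   fabricate coherent synthetic evidence.

Receptor candidates are recognized architecturally: a GOLD domain in the
C-terminal part of the mature sequence (default: trailing half after the
transit peptide) that itself contains a dilysine match, plus a CRAL_TRIO
domain. An N-terminal coiled coil and the absence of membrane spans are
reported as supporting evidence, not requirements, because the source
candidates exhibit but were not selected on them.

## Key parameters

| Parameter | Default | Meaning |
|---|---|---|
| `nterm_window` | 25 residues | "proximal to the membrane span" for the basic signal; the source gives no number, so this is a recorded operational choice — all tests that depend on it use synthetic truth, not published counts |
| `cterm_max_dist` | unlimited | optional cap on distance of a C-tail signal from the C-terminus (no cap is imposed by the screen's rationale) |
| consensus `threshold` | 10 | reliability cutoff of the multi-tool consensus score, inclusive |
| `min_tools` | 2 | individual predictors sufficient for the fallback route; every verdict records its supporting tools so stricter re-analyses are filters |
| `cterm_fraction` | 0.5 | fraction of the mature sequence counted as "C-terminal" for receptor architecture |
| alignment | BLOSUM62, gap open 10, extend 1 | a gap of length L costs `10 + (L-1)·1`, end gaps included; traceback ties break diagonal > up > left, making alignments deterministic |
| `min_length` (extension) | 20 residues | minimum N-terminal overhang called a transit-peptide-like extension; a typical lower bound for plant transit peptides |

Transit-peptide extension detection replaces visual inspection of multiple
alignments with a decidable criterion: global alignment against each
non-plastid homologue, counting query residues before the first column in
which both sequences carry residues, taking the minimum over homologues as
the conservative overhang.

## Synthetic data: what it emulates and what it does not

The generator emulates the structural features the screens rely on:
transit peptides of 30–80 residues (serine/threonine-enriched), membrane
spans of 18–24 residues (hydrophobic-enriched), uniform background
composition (published average composition available as an option), planted
signals at recorded coordinates, and controls that each violate exactly one
rule so a failing filter is attributable. Because the basic signal has no
orientation rule, its "wrong orientation" control instead violates the
proximity window — still a single-rule violation. Fabricated localization
evidence gives true chloroplast proteins a reliable consensus score with
probability `1 − miscall`, and otherwise enough correct tool calls with
probability `fallback_success`, so the expected acceptance rate is
`(1 − miscall) + miscall · fallback_success`.

Planted-signal recovery is made exact *by construction*: after planting,
accidental catalog-pattern occurrences that do not overlap a planted span
are rewritten with residues outside every signal class. Two consequences
follow. First, sensitivity/specificity of 1.0 on synthetic proteomes
demonstrates that the rule logic is implemented correctly — not that the
screen has perfect accuracy on real proteomes, where signal-like strings
occur by chance and annotations err. Second, scrubbing dilutes the
hydrophobic enrichment of membrane spans (the ILV pattern is rich in
hydrophobics); the spans remain annotation-defined, so topology logic is
unaffected. Real-data effects the generator does not model include
annotation error in span boundaries and topology, homology between
proteins, and compositional biases beyond single-residue frequencies.

## Numerical and design choices

* Coordinates are 1-based and inclusive everywhere (Prosite/biology
  convention); the scanner reports *all* matches, overlapping included, and
  enumerates every feasible span of variable wildcards; deduplication is
  the screens' job.
* Ambiguity letters (X, B, Z, U) are accepted in sequences but matched only
  by wildcards — a residue class asserts a chemical identity the data does
  not support. Other letters are rejected outright.
* Zero-length regions (e.g. a membrane span ending at the last residue)
  are omitted from region maps; maps always tile the sequence exactly.
* Annotation loading is total: every malformed row is reported with its
  line number in one error; there are no partial silent loads.
* The packaged curated tables carry printed motif *strings*, not full
  sequences, so the fixture screen checks pattern membership only; the
  positional filters are exercised on synthetic proteomes. One curated
  candidate (At4g01150) has no published functional category and is
  bucketed as `unknown` with a warning, which is the general behaviour for
  uncategorized candidates.
* A protein matching several signal classes is reported once per class but
  counted once in category totals; the photosynthesis super-category pools
  LHC, PSII, PSI and cytochrome b6f.
* Reports are written in a fixed row order (accession, then class), so
  reruns are byte-identical.

## Problem sizes

Property suites run at sizes chosen to be decisive yet quick: scanner
equivalence against a brute-force oracle on random sequences up to 60
residues; alignment scores against an independent aligner on pairs up to
15 residues and exhaustive alignment enumeration up to 5; planted-signal
recovery on a 500-protein proteome; localization-noise calibration on
2000 fabricated evidence records; end-to-end recovery on 100–200 protein
proteomes. The acceptance script uses the same scales.

## Known limitations

* Topology, domain and coiled-coil annotations are consumed as inputs;
  the package performs no membrane-helix, transit-peptide or domain
  prediction, and inherits any annotation error.
* The receptor screen's "C-terminal half" operationalizes a qualitative
  architectural description; candidates near the midpoint are sensitive to
  `cterm_fraction`.
* The overhang measure assumes homologues lack the extension; paralogues
  that share it mask detection, and strong N-terminal divergence can
  inflate it (mitigated by the minimum-over-homologues rule).
* Pattern matching is binary; no attempt is made to score signal strength
  or conservation.
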