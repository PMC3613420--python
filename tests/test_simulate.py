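"""Synthetic proteome generator: determinism, bookkeeping, noise calibration."""

import math

import pytest

from cpcargo.errors import SimulationError
from cpcargo.localization import decide_localization
from cpcargo.pipeline import run_screens
from cpcargo.proteins import Span
from cpcargo.simulate import (
    LocalizationNoise,
    MotifPlan,
    ProteinTruth,
    SimulationConfig,
    TruthTable,
    generate_localization_evidence,
    generate_proteome,
)


class TestGenerateProteome:
    def test_identical_seeds_give_byte_identical_output(self, small_proteome):
        config, records, annotations, truth = small_proteome
        records2, annotations2, truth2 = generate_proteome(config)
        assert [(r.accession, r.sequence) for r in records] == [
            (r.accession, r.sequence) for r in records2
        ]
        assert annotations == annotations2
        assert truth.to_json() == truth2.to_json()

    def test_motif_plan_bookkeeping(self):
        config = SimulationConfig(
            n_proteins=30,
            motif_plans={"tm_diacidic": MotifPlan(correct=10, wrong_region=2)},
            seed=3,
        )
        _, _, truth = generate_proteome(config)
        passing = [
            p for t in truth.entries.values() for p in t.planted
            if p.cargo_class == "tm_diacidic" and p.should_pass
        ]
        assert len(passing) == 10

    def test_inside_transit_controls_never_pass(self, small_proteome):
        _, _, _, truth = small_proteome
        controls = [
            p for t in truth.entries.values() for p in t.planted
            if p.control_type == "inside_transit"
        ]
        assert controls and all(not p.should_pass for p in controls)

    def test_planted_coordinates_match_emitted_sequence(self, small_proteome):
        from cpcargo.patterns import builtin_patterns, scan

        _, records, _, truth = small_proteome
        by_acc = {r.accession: r for r in records}
        pattern_for = {
            "tm_diacidic": "diacidic", "tm_dihydrophobic": "dihydrophobic",
            "tm_basic": "basic", "soluble_ilv": "ilv",
        }
        for t in truth.entries.values():
            for p in t.planted:
                seq = by_acc[t.accession].sequence
                pat = builtin_patterns()[pattern_for[p.cargo_class]]
                window = (p.span.start, p.span.end)
                assert any(m.span == (p.span.start, p.span.end) for m in scan(seq, pat, window))

    def test_infeasible_plan_raises_sizing_error(self):
        with pytest.raises(SimulationError, match="n_proteins"):
            generate_proteome(
                SimulationConfig(n_proteins=5, motif_plans={"soluble_ilv": MotifPlan(correct=50)})
            )

    def test_seed_changes_sequences_not_schema(self):
        base = SimulationConfig(n_proteins=60, seed=1)
        other = SimulationConfig(n_proteins=60, seed=2)
        r1, _, t1 = generate_proteome(base)
        r2, _, t2 = generate_proteome(other)
        assert [r.accession for r in r1] == [r.accession for r in r2]
        assert any(a.sequence != b.sequence for a, b in zip(r1, r2))
        counts1 = sorted((p.cargo_class, p.control_type)
                         for t in t1.entries.values() for p in t.planted)
        counts2 = sorted((p.cargo_class, p.control_type)
                         for t in t2.entries.values() for p in t.planted)
        assert counts1 == counts2


class TestPlantedRecovery:
    def test_perfect_sensitivity_and_control_rejection(self, small_proteome):
        _, records, annotations, truth = small_proteome
        calls, receptors = run_screens(records, annotations)
        predicted = {(c.accession, c.cargo_class) for c in calls if c.verdict}
        expected = {
            (acc, p.cargo_class)
            for acc, planted in truth.should_pass().items()
            for p in planted
        }
        assert predicted == expected  # sensitivity 1.0 and specificity 1.0
        rec_predicted = {r.accession for r in receptors if r.verdict}
        rec_expected = {a for a, t in truth.entries.items() if t.receptor_should_pass}
        assert rec_predicted == rec_expected


def _chloroplast_truth(n):
    entries = {
        f"T{i:04d}": ProteinTruth(
            accession=f"T{i:04d}", compartment="chloroplast", transit=Span(1, 40)
        )
        for i in range(n)
    }
    return TruthTable(entries)


class TestLocalizationEvidence:
    def test_noise_free_evidence_is_always_accepted(self, small_proteome):
        config, _, _, truth = small_proteome
        evidence = generate_localization_evidence(truth, config)
        for acc in truth.chloroplast_accessions():
            assert decide_localization(evidence[acc]).accepted

    def test_non_chloroplast_proteins_rejected(self, small_proteome):
        config, _, _, truth = small_proteome
        evidence = generate_localization_evidence(truth, config)
        for acc, t in truth.entries.items():
            if t.compartment != "chloroplast":
                assert not decide_localization(evidence[acc]).accepted

    def test_full_miscall_without_fallback_rejects_everything(self):
        truth = _chloroplast_truth(50)
        config = SimulationConfig(
            n_proteins=50, noise=LocalizationNoise(miscall=1.0, fallback_success=0.0), seed=4
        )
        evidence = generate_localization_evidence(truth, config)
        assert not any(decide_localization(ev).accepted for ev in evidence.values())

    def test_intermediate_noise_matches_closed_form_rate(self):
        n = 2000
        truth = _chloroplast_truth(n)
        noise = LocalizationNoise(miscall=0.3, fallback_success=0.5)
        config = SimulationConfig(n_proteins=n, noise=noise, seed=9)
        evidence = generate_localization_evidence(truth, config)
        rate = sum(decide_localization(ev).accepted for ev in evidence.values()) / n
        expected = (1 - noise.miscall) + noise.miscall * noise.fallback_success
        tolerance = 4 * math.sqrt(expected * (1 - expected) / n)
        assert abs(rate - expected) <= tolerance


class TestEndToEnd:
    def test_noise_free_pipeline_recovers_truth_exactly(self):
        config = SimulationConfig(n_proteins=100, seed=21)
        records, annotations, truth = generate_proteome(config)
        evidence = generate_localization_evidence(truth, config)
        calls, _ = run_screens(records, annotations)
        survivors = {
            c.accession
            for c in calls
            if c.verdict and decide_localization(evidence[c.accession]).accepted
        }
        assert survivors == set(truth.should_pass())
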