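"""Cargo/receptor screens and functional categorization."""

import pytest

from cpcargo.fixtures import (
    reference_categories,
    reference_section_counts,
    screen_reference_motifs,
)
from cpcargo.proteins import AnnotatedProtein, ProteinRecord, Span
from cpcargo.screen import (
    CargoCall,
    ScreenParams,
    categorize,
    screen_receptor,
    screen_soluble_cargo,
    screen_tm_cargo,
)

NEUTRAL = "GASNQTHP"  # residues outside every signal class


def neutral(n):
    return (NEUTRAL * (n // len(NEUTRAL) + 1))[:n]


def tm_protein(planted, at, length=200, transit=50, tm=(100, 120), n="out", c="in",
               alt=()):
    seq = list(neutral(length))
    seq[at - 1 : at - 1 + len(planted)] = list(planted)
    return AnnotatedProtein(
        record=ProteinRecord("P1", "".join(seq)),
        transit_peptide=Span(1, transit),
        tm_spans=(Span(*tm),),
        n_orientation=n,
        c_orientation=c,
        alt_orientations=alt,
    )


def calls_by_class(calls):
    return {c.cargo_class: c for c in calls}


class TestTmCargo:
    def test_diacidic_in_stromal_c_tail_passes(self):
        calls = calls_by_class(screen_tm_cargo(tm_protein("DID", at=180)))
        call = calls["tm_diacidic"]
        assert call.verdict and call.filters_passed["stromal_c_tail"]
        assert any(m.span == (180, 182) for m in call.matches)

    def test_diacidic_in_n_tail_fails_region_filter(self):
        calls = calls_by_class(screen_tm_cargo(tm_protein("DID", at=60)))
        call = calls["tm_diacidic"]
        assert not call.verdict
        assert call.filters_passed["outside_transit"]
        assert not call.filters_passed["stromal_c_tail"]

    def test_basic_signal_inside_transit_fails(self):
        calls = calls_by_class(screen_tm_cargo(tm_protein("KK", at=30)))
        call = calls["tm_basic"]
        assert not call.verdict and not call.filters_passed["outside_transit"]

    def test_basic_signal_proximal_to_tm_passes(self):
        calls = calls_by_class(screen_tm_cargo(tm_protein("KK", at=85)))
        assert calls["tm_basic"].verdict  # 100 - 85 = 15 <= 25

    def test_basic_signal_distal_fails_window(self):
        calls = calls_by_class(screen_tm_cargo(tm_protein("KK", at=55)))
        assert not calls["tm_basic"].verdict  # 100 - 55 = 45 > 25

    def test_dihydrophobic_orientation_rule(self):
        good = calls_by_class(screen_tm_cargo(tm_protein("FF", at=180, n="out", c="in")))
        bad = calls_by_class(screen_tm_cargo(tm_protein("FF", at=180, n="in", c="out")))
        assert good["tm_dihydrophobic"].verdict
        assert not bad["tm_dihydrophobic"].verdict

    def test_soluble_protein_yields_no_tm_calls(self):
        ap = AnnotatedProtein(record=ProteinRecord("P1", neutral(80) + "DID"))
        assert screen_tm_cargo(ap) == []

    def test_no_matching_class_no_call(self):
        calls = screen_tm_cargo(tm_protein("DID", at=180))
        assert "tm_dihydrophobic" not in calls_by_class(calls)

    def test_ambiguous_orientation_screened_under_each_alternative(self):
        ap = tm_protein("DID", at=180, n="in", c="out", alt=(("out", "in"),))
        call = calls_by_class(screen_tm_cargo(ap))["tm_diacidic"]
        assert call.verdict and call.orientation_ambiguous

    def test_monobasic_fallback_off_by_default(self):
        ap = tm_protein("K", at=85)
        assert "tm_basic" not in calls_by_class(screen_tm_cargo(ap))
        with_mono = screen_tm_cargo(ap, ScreenParams(allow_monobasic=True))
        assert calls_by_class(with_mono)["tm_basic"].verdict


class TestSolubleCargo:
    ILV = "IDALQIELSCTAGV"

    def test_ilv_after_transit_passes(self):
        seq = neutral(50) + "IVSLYPVSMATALV" + neutral(30)
        ap = AnnotatedProtein(record=ProteinRecord("P1", seq), transit_peptide=Span(1, 50))
        call = screen_soluble_cargo(ap)
        assert call is not None and call.verdict

    def test_ilv_inside_transit_yields_no_passing_call(self):
        seq = neutral(10) + self.ILV + neutral(40)
        ap = AnnotatedProtein(record=ProteinRecord("P1", seq), transit_peptide=Span(1, 30))
        call = screen_soluble_cargo(ap)
        assert call is not None and not call.verdict

    def test_bare_motif_without_annotation_passes(self):
        ap = AnnotatedProtein(record=ProteinRecord("P1", self.ILV))
        call = screen_soluble_cargo(ap)
        assert call.verdict and call.matches[0].span == (1, 14)

    def test_membrane_protein_not_screened_as_soluble(self):
        assert screen_soluble_cargo(tm_protein("DID", at=180)) is None


def receptor_protein(gold=(220, 299), cral=(100, 180), coil=(10, 40), kk_at=250,
                     tms=(), length=300):
    seq = list(neutral(length))
    seq[kk_at - 1 : kk_at + 2] = list("KSK")
    kwargs = {}
    if tms:
        kwargs = {"tm_spans": tuple(Span(*t) for t in tms),
                  "n_orientation": "in", "c_orientation": "out"}
    domains = [("GOLD", Span(*gold))]
    if cral:
        domains.append(("CRAL_TRIO", Span(*cral)))
    return AnnotatedProtein(
        record=ProteinRecord("R1", "".join(seq)),
        domains=tuple(domains),
        coiled_coil_regions=(Span(*coil),),
        **kwargs,
    )


class TestReceptor:
    def test_full_architecture_passes(self):
        # emulates a soluble SEC14-like receptor: C-terminal GOLD containing
        # a dilysine, mid-protein CRAL_TRIO, N-terminal coiled coil, no TM
        call = screen_receptor(receptor_protein())
        assert call.verdict
        assert call.has_gold_cterm and call.has_cral_trio and call.dilysine_in_gold
        assert call.coiled_coil_nterm and call.lacks_tm

    def test_gold_in_n_terminal_half_fails(self):
        call = screen_receptor(receptor_protein(gold=(20, 110), kk_at=50, coil=(120, 140)))
        assert not call.has_gold_cterm and not call.verdict

    def test_missing_cral_trio_fails(self):
        call = screen_receptor(receptor_protein(cral=None))
        assert call.dilysine_in_gold and not call.verdict

    def test_dilysine_outside_gold_fails(self):
        call = screen_receptor(receptor_protein(kk_at=150))
        assert not call.dilysine_in_gold and not call.verdict

    def test_tm_presence_is_evidence_not_requirement(self):
        call = screen_receptor(receptor_protein(tms=[(150, 170)]))
        assert not call.lacks_tm and call.verdict


class TestCategorize:
    def test_reference_candidates_reproduce_published_categories(self):
        with pytest.warns(UserWarning, match="At4g01150"):
            summary = categorize(screen_reference_motifs(), reference_categories())
        assert summary.photosynthesis_count == 14
        assert summary.counts["LHC"] == 5
        assert summary.total == 33  # one accession lacks a curated category

    def test_reference_section_counts(self):
        counts = reference_section_counts()
        assert counts["basic"] == 3
        assert counts["dihydrophobic"] == 1
        assert counts["diacidic"] == 17
        assert counts["ilv"] == 12

    def test_deduplication_across_classes(self):
        m = screen_reference_motifs()[0].matches
        calls = [
            CargoCall("P1", "tm_diacidic", m, {"f": True}, True),
            CargoCall("P1", "tm_basic", m, {"f": True}, True),
        ]
        summary = categorize(calls, {"P1": "LHC"})
        assert summary.total == 1 and summary.counts["LHC"] == 1

    def test_empty_calls_all_zero(self):
        summary = categorize([], {})
        assert summary.total == 0 and summary.photosynthesis_count == 0
        assert all(v == 0 for v in summary.counts.values())

    def test_permutation_invariance(self):
        calls = screen_reference_motifs()
        cats = reference_categories()
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = categorize(calls, cats)
            b = categorize(list(reversed(calls)), cats)
        assert a.counts == b.counts and a.total == b.total
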