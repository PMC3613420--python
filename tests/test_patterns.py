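"""Pattern compiler and motif scanner."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from cpcargo.errors import PatternSyntaxError, SequenceError
from cpcargo.patterns import (
    MotifPattern,
    PatternElement,
    builtin_patterns,
    compile_pattern,
    scan,
)
from helpers import brute_force_matches

AA = "ACDEFGHIKLMNPQRSTVWY"
sequences = st.text(alphabet=AA, min_size=1, max_size=60)


class TestCompile:
    @pytest.mark.parametrize(
        "text, n_elements, min_span, max_span",
        [
            ("I-x(2)-L-x(9)-V", 5, 14, 14),
            ("[DE]-x-[DE]", 3, 3, 3),
            ("[FY](2)", 1, 2, 2),
            ("[RK]-x(0,1)-[RK]", 3, 2, 3),
            ("K-x(0,1)-K-x(2)", 4, 4, 5),
            ("<M-x(0,5)-{P}>", 3, 2, 7),
        ],
    )
    def test_element_counts_and_spans(self, text, n_elements, min_span, max_span):
        pat = compile_pattern(text)
        assert len(pat.elements) == n_elements
        assert (pat.min_span, pat.max_span) == (min_span, max_span)

    def test_repeat_binds_to_preceding_element(self):
        pat = compile_pattern("A-x(3)-C")
        assert pat.elements[1].is_wildcard
        assert pat.elements[1].min_repeat == pat.elements[1].max_repeat == 3

    def test_anchors(self):
        pat = compile_pattern("<A-x>")
        assert pat.n_anchor and pat.c_anchor

    def test_render_round_trips_to_canonical_form(self):
        for text in ["[ED]-x-[DE]", "<I-x(2)-L>", "{PG}(2,4)-W", "K-x(0,1)-K-x(2)"]:
            pat = compile_pattern(text)
            again = compile_pattern(pat.render())
            assert again.elements == pat.elements
            assert again.render() == pat.render()
            assert (again.n_anchor, again.c_anchor) == (pat.n_anchor, pat.c_anchor)

    @pytest.mark.parametrize(
        "text, column",
        [
            ("x(", 2),        # unclosed repeat
            ("[DE", 1),       # unbalanced class
            ("[]", 1),        # empty class
            ("(2)-A", 1),     # repeat with no preceding element
            ("A-x(3,1)", 4),  # min > max
            ("A-J", 3),       # non-standard residue letter
        ],
    )
    def test_syntax_errors_carry_column(self, text, column):
        with pytest.raises(PatternSyntaxError) as err:
            compile_pattern(text)
        assert err.value.column == column

    def test_empty_residue_class_rejected_at_type_level(self):
        with pytest.raises(ValueError):
            PatternElement(residues=frozenset())


class TestScan:
    def test_catalog_has_exactly_five_patterns(self):
        assert sorted(builtin_patterns()) == [
            "basic", "diacidic", "dihydrophobic", "dilysine", "ilv",
        ]

    def test_ilv_matches_full_candidate_motif(self):
        # printed soluble-cargo motif string: an exact 14-mer ILV hit
        matches = scan("IDALQIELSCTAGV", builtin_patterns()["ilv"])
        assert [(m.start, m.end) for m in matches] == [(1, 14)]
        assert matches[0].matched_text == "IDALQIELSCTAGV"

    def test_no_acidic_residues_no_diacidic_match(self):
        assert scan("AAAA", builtin_patterns()["diacidic"]) == []

    def test_overlapping_diacidic_matches_all_reported(self):
        matches = scan("EEDEE", builtin_patterns()["diacidic"])
        assert [(m.start, m.end) for m in matches] == [(1, 3), (2, 4), (3, 5)]

    def test_adjacent_kk_matches_basic_pattern(self):
        assert [(m.start, m.end) for m in scan("KK", builtin_patterns()["basic"])] == [(1, 2)]

    def test_dilysine_with_spacer_and_tail(self):
        matches = scan("KAKLE", builtin_patterns()["dilysine"])
        assert [(m.start, m.end) for m in matches] == [(1, 5)]

    def test_matched_text_equals_sequence_slice(self):
        seq = "MDADEPE"
        for m in scan(seq, builtin_patterns()["diacidic"]):
            assert m.matched_text == seq[m.start - 1 : m.end]

    def test_window_confines_matches(self):
        seq = "DAEAAADAE"  # diacidic hits at 1-3 and 7-9
        dia = builtin_patterns()["diacidic"]
        assert [(m.start, m.end) for m in scan(seq, dia, window=(7, 9))] == [(7, 9)]
        # matches straddling either window bound are not reported
        assert scan(seq, dia, window=(2, 8)) == []
        with pytest.raises(ValueError):
            scan(seq, dia, window=(0, 5))

    def test_anchored_pattern_respects_window_termini(self):
        pat = compile_pattern("<[DE]-x-[DE]")
        assert scan("AADAE", pat) == []
        assert [(m.start, m.end) for m in scan("AADAE", pat, window=(3, 5))] == [(3, 5)]

    def test_ambiguity_letters_match_only_wildcards(self):
        dia = builtin_patterns()["diacidic"]
        assert [(m.start, m.end) for m in scan("DXE", dia)] == [(1, 3)]  # wildcard slot
        assert scan("XAE", dia) == []  # class slot refuses X
        assert scan("DBZ", dia) == []

    def test_illegal_letters_rejected(self):
        with pytest.raises(SequenceError):
            scan("MKJV", builtin_patterns()["diacidic"])


class TestScanProperties:
    @given(seq=sequences)
    def test_scanner_equals_brute_force_oracle(self, seq):
        for pat in builtin_patterns().values():
            got = [(m.start, m.end) for m in scan(seq, pat)]
            assert got == brute_force_matches(seq, pat)

    @given(seq=sequences, prefix=st.text(alphabet="GAS", min_size=1, max_size=10))
    def test_prepending_shifts_unanchored_matches(self, seq, prefix):
        dia = builtin_patterns()["diacidic"]
        base = [(m.start, m.end) for m in scan(seq, dia)]
        shifted = [(m.start - len(prefix), m.end - len(prefix)) for m in scan(prefix + seq, dia)]
        assert shifted == base  # G/A/S cannot create new diacidic hits

    @given(seq=sequences, extra=st.integers(min_value=0, max_value=4))
    def test_widening_a_wildcard_never_removes_matches(self, seq, extra):
        narrow = compile_pattern("[DE]-x(0,1)-[DE]")
        wide = compile_pattern(f"[DE]-x(0,{1 + extra})-[DE]")
        narrow_hits = {(m.start, m.end) for m in scan(seq, narrow)}
        wide_hits = {(m.start, m.end) for m in scan(seq, wide)}
        assert narrow_hits <= wide_hits
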