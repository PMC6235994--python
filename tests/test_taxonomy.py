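"""Conversion-file parsing, letter-pair similarity, staged name matching."""

from collections import Counter

import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cavedata.taxonomy import (
    Checklist, ConversionEntry, DuplicateCodeError, MatchThresholds,
    ReferenceTaxon, bigram_similarity, export_review_list, load_overrides,
    parse_conversion_file, resolve_codes, resolve_name,
)


def conversion_frame(rows):
    return pd.DataFrame(rows, columns=["row_number", "flags", "alphacode",
                                       "published_name", "updated_name"])


class TestConversionFile:
    def test_packed_flags_unpack_positionally(self):
        df = conversion_frame([
            (2, "L G", "ABELMOSC", "Abelmoschus moschatus", ""),
            (20, "SZG", "ACACARMA", "Acacia armata", "Acacia paradoxa"),
            (21, "MLG", "ACACASHA", "Acacia ashanesii", "Acacia oshanesii"),
            (3019, "SIG", "RUMEACET", "Rumex acetosella", "Acetosella vulgaris"),
        ])
        entries = parse_conversion_file(df, formation="sclerophyll")
        by_code = {e.alphacode: e for e in entries}
        e = by_code["ABELMOSC"]
        assert (e.validity_flag, e.growth_habit_flag, e.stage_code) == ("L", "", "G")
        assert e.updated_name is None
        e = by_code["ACACARMA"]
        assert (e.validity_flag, e.growth_habit_flag) == ("S", "Z")
        assert e.updated_name == "Acacia paradoxa"
        assert by_code["ACACASHA"].validity_flag == "M"
        assert by_code["RUMEACET"].growth_habit_flag == "I"

    def test_row_numbers_preserved(self):
        df = conversion_frame([(466, "S G", "BORRCARP/", "Borreria carpentariae", "")])
        (entry,) = parse_conversion_file(df)
        assert entry.row_number == 466
        assert entry.alphacode == "BORRCARP/"

    def test_duplicate_code_in_formation_rejected(self):
        df = conversion_frame([
            (1, "L G", "ACACARMA", "Acacia armata", ""),
            (2, "L G", "ACACARMA", "Acacia armata", ""),
        ])
        with pytest.raises(DuplicateCodeError):
            parse_conversion_file(df, formation="sclerophyll")

    def test_unknown_flag_kept_with_warning(self):
        df = conversion_frame([(1, "XQG", "AAAA____", "Aus bus", "")])
        with pytest.warns(UserWarning, match="UNKNOWN_FLAG"):
            (entry,) = parse_conversion_file(df)
        assert entry.validity_flag == "X"
        assert entry.growth_habit_flag == "Q"

    def test_query_name_prefers_updated(self):
        e = ConversionEntry(1, "S", "Z", "G", "ACACARMA",
                            "Acacia armata", "Acacia paradoxa")
        assert e.query_name == "Acacia paradoxa"
        e2 = ConversionEntry(1, "L", "", "G", "ABELMOSC",
                             "Abelmoschus moschatus", None)
        assert e2.query_name == "Abelmoschus moschatus"


def oracle_pairs(s):
    """Independent brute-force letter-pair enumeration (list scan, not Counter)."""
    out = []
    for word in " ".join(s.split()).casefold().split():
        for i in range(len(word) - 1):
            out.append(word[i] + word[i + 1])
    return out


def oracle_similarity(a, b):
    pa, pb = oracle_pairs(a), oracle_pairs(b)
    if not pa and not pb:
        return 0.0
    hits = 0
    remaining = list(pb)
    for p in pa:
        if p in remaining:
            remaining.remove(p)
            hits += 1
    return 2.0 * hits / (len(pa) + len(pb))


class TestBigramSimilarity:
    def test_identity(self):
        assert bigram_similarity("ACACIA", "ACACIA") == 1.0

    def test_night_nacht(self):
        assert bigram_similarity("NIGHT", "NACHT") == pytest.approx(0.25)

    def test_single_letters_contribute_no_pairs(self):
        assert bigram_similarity("A", "B") == 0.0
        assert bigram_similarity("", "") == 0.0

    def test_case_and_whitespace_folding(self):
        assert bigram_similarity("Acacia  paradoxa", "ACACIA PARADOXA") == 1.0

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(st.text(alphabet="abcde ", max_size=20),
           st.text(alphabet="abcde ", max_size=20))
    def test_agrees_with_bruteforce_oracle(self, a, b):
        assert bigram_similarity(a, b) == pytest.approx(oracle_similarity(a, b))

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.text(alphabet="abcdefg ", max_size=25),
           st.text(alphabet="abcdefg ", max_size=25))
    def test_symmetric_and_bounded(self, a, b):
        s = bigram_similarity(a, b)
        assert s == bigram_similarity(b, a)
        assert 0.0 <= s <= 1.0

    def test_score_one_iff_identical_pair_multisets(self):
        # different words, identical pair multiset
        assert bigram_similarity("abab", "ab ab ab") < 1.0
        assert bigram_similarity("ab ba", "ba ab") == 1.0


class TestResolveName:
    def test_exact_accepted_name(self, small_checklist):
        r = resolve_name("Acacia paradoxa", small_checklist)
        assert (r.category, r.best_name, r.score) == ("MATCH", "Acacia paradoxa", 1.0)
        assert r.needs_review is False

    def test_synonym_chains_to_accepted(self, small_checklist):
        r = resolve_name("Acacia armata", small_checklist)
        assert r.category == "MATCH"
        assert r.best_name == "Acacia paradoxa"

    def test_orth_var_chains_to_accepted(self, small_checklist):
        r = resolve_name("Acacia oshanessii", small_checklist)
        assert r.category == "MATCH"
        assert r.best_name == "Acacia oshanesii"

    def test_case_insensitive_exact(self, small_checklist):
        r = resolve_name("ACACIA PARADOXA", small_checklist)
        assert r.category == "MATCH"

    def test_misapplied_exact_is_not_match(self, small_checklist):
        r = resolve_name("Carpobrotus aequilaterus", small_checklist)
        assert r.category != "MATCH"
        assert r.needs_review is True
        assert "misapplied" in r.evidence

    def test_single_substitution_lands_fuzzy(self, small_checklist):
        r = resolve_name("Acacia ashanesii", small_checklist)
        assert r.category == "FUZZY"
        assert r.best_name == "Acacia oshanesii"
        # frozen from the brute-force pair enumeration of the two names
        assert r.score == pytest.approx(oracle_similarity(
            "Acacia ashanesii", "Acacia oshanesii"))
        assert r.score == pytest.approx(12 / 13)

    def test_ambiguous_names_reported_for_review(self, small_checklist):
        r = resolve_name("Eragrostis ciliata", small_checklist)
        assert r.needs_review is True
        assert len(r.candidates) >= 2
        reported = {name for name, _ in r.candidates}
        assert "Eragrostis ciliolata" in reported
        assert "Eragrostis cilianensis" in reported

    def test_weak_retains_best_match(self):
        checklist = Checklist([
            ReferenceTaxon("Banksia serrata", "accepted", "Banksia serrata")])
        r = resolve_name("Banksia sp aff serr", checklist,
                         MatchThresholds(fuzzy_min=0.95, weak_min=0.10))
        assert r.category == "WEAK"
        assert r.best_name == "Banksia serrata"

    def test_taxm_has_no_best_name(self, small_checklist):
        r = resolve_name("Xyz qqq", small_checklist)
        assert r.category == "TAXM"
        assert r.best_name is None

    def test_empty_checklist_is_taxm_with_evidence(self):
        r = resolve_name("Acacia paradoxa", Checklist([]))
        assert r.category == "TAXM"
        assert "EMPTY_CHECKLIST" in r.evidence

    def test_partial_left_anchored(self):
        checklist = Checklist([
            ReferenceTaxon("Melaleuca quinquenervia", "accepted",
                           "Melaleuca quinquenervia")])
        r = resolve_name("Melaleuca quinque", checklist)
        assert r.category == "PARTIAL_L"
        assert r.best_name == "Melaleuca quinquenervia"
        assert 0 < r.score < 1

    def test_partial_right_anchored(self):
        checklist = Checklist([
            ReferenceTaxon("Eucalyptus camaldulensis", "accepted",
                           "Eucalyptus camaldulensis")])
        r = resolve_name("tus camaldulensis", checklist)
        assert r.category == "PARTIAL_R"

    def test_genus_rank_restricts_pool(self, small_checklist):
        r = resolve_name("Gahnia", small_checklist, rank="genus")
        assert (r.category, r.best_name) == ("MATCH", "Gahnia")
        r2 = resolve_name("Banksia", small_checklist, rank="genus")
        assert r2.category != "MATCH"

    def test_override_wins(self, small_checklist):
        r = resolve_name("Mystery name", small_checklist,
                         overrides={"Mystery name": "Acacia paradoxa"})
        assert (r.category, r.best_name) == ("MATCH", "Acacia paradoxa")

    def test_needs_review_exactly_for_non_match(self, small_checklist):
        for query in ["Acacia paradoxa", "Acacia armata", "Acacia ashanesii",
                      "Eragrostis ciliata", "Xyz qqq"]:
            r = resolve_name(query, small_checklist)
            assert r.needs_review == (r.category != "MATCH")

    def test_threshold_monotonicity(self, small_checklist):
        """Raising fuzzy_min can only move FUZZY toward WEAK, never back."""
        query = "Acacia ashanesii"
        low = resolve_name(query, small_checklist, MatchThresholds(fuzzy_min=0.60))
        high = resolve_name(query, small_checklist, MatchThresholds(fuzzy_min=0.95))
        assert low.category == "FUZZY"
        assert high.category == "WEAK"
        assert low.score == high.score

    def test_deterministic_under_checklist_order(self, small_checklist):
        shuffled = Checklist(list(reversed(small_checklist.taxa)))
        for query in ["Acacia ashanesii", "Eragrostis ciliata", "Xyz qqq"]:
            a = resolve_name(query, small_checklist)
            b = resolve_name(query, shuffled)
            assert (a.category, a.best_name, a.score, a.candidates) == \
                   (b.category, b.best_name, b.score, b.candidates)


class TestResolveCodes:
    def test_updated_name_used_and_both_recorded(self, small_checklist):
        entries = [ConversionEntry(20, "S", "Z", "G", "ACACARMA",
                                   "Acacia armata", "Acacia paradoxa")]
        results = resolve_codes(entries, small_checklist)
        r = results["ACACARMA"]
        assert (r.category, r.best_name) == ("MATCH", "Acacia paradoxa")
        assert "Acacia armata" in r.evidence
        assert "Acacia paradoxa" in r.evidence

    def test_genus_level_code_resolved_at_genus_rank(self, small_checklist):
        entries = [ConversionEntry(1, "L", "", "G", "GAHNIA__", "Gahnia", None)]
        results = resolve_codes(entries, small_checklist)
        assert results["GAHNIA__"].category == "MATCH"

    def test_empty_entries_empty_mapping(self, small_checklist):
        assert resolve_codes([], small_checklist) == {}


class TestReviewList:
    def test_all_match_gives_empty_list(self, small_checklist):
        entries = [ConversionEntry(1, "L", "", "G", "ACACPARA",
                                   "Acacia paradoxa", None)]
        review = export_review_list(resolve_codes(entries, small_checklist))
        assert review.empty

    def test_taxm_sorted_before_fuzzy(self, small_checklist):
        entries = [
            ConversionEntry(1, "L", "", "G", "ACACASHA", "Acacia ashanesii", None),
            ConversionEntry(2, "L", "", "G", "XYZQQQ__", "Xyz qqq", None),
        ]
        review = export_review_list(resolve_codes(entries, small_checklist))
        assert list(review["category"]) == ["TAXM", "FUZZY"]

    def test_override_reimport_yields_match(self, small_checklist, tmp_path):
        entries = [ConversionEntry(1, "L", "", "G", "XYZQQQ__", "Xyz qqq", None)]
        review = export_review_list(resolve_codes(entries, small_checklist))
        review.loc[0, "accepted_name"] = "Acacia paradoxa"
        path = tmp_path / "overrides.csv"
        review.to_csv(path, index=False)
        overrides = load_overrides(path)
        rerun = resolve_codes(entries, small_checklist, overrides=overrides)
        assert rerun["XYZQQQ__"].category == "MATCH"
        assert rerun["XYZQQQ__"].best_name == "Acacia paradoxa"
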