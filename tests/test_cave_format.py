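"""Line classification, species tokenization, block assembly, round-trip."""

import pytest
from hypothesis import given, settings, strategies as st

import cavedata as cd
from cavedata.cave_format import (
    CommunityRecord, EmptySpeciesLineError, LineKind, LocationBlock,
    NonNumericIdError, SpeciesCode, UnknownLineIdError, blocks_from_jsonl,
    blocks_to_jsonl, classify_line, parse_cave_stream, tokenize_species_line,
    write_canonical,
)


@pytest.mark.parametrize("line, kind, payload_start", [
    ("800000 N", LineKind.STATE, "N"),
    ("503200 LOCATION N032 = CENTRAL COAST: SYDNEY (PIDGEON 1940)",
     LineKind.LOCATION, "LOCATION N032"),
    ("903200 33 51 151 13", LineKind.LATLON, "33 51"),
    ("503201 COMMUNITY 01 = FRESHWATER RIVER (COMBINED LIST)",
     LineKind.COMMUNITY, "COMMUNITY 01"),
    ("303701 EUCAPAPU ACACVICT #", LineKind.COMMENT, "EUCAPAPU"),
    ("003201 UTRIAUST UTRIEXOL #", LineKind.SPECIES, "UTRIAUST"),
    ("500000 ----", LineKind.END, "----"),
    # three-digit location numbers shift the two leading digits
    ("512300 LOCATION N123 = SOMEWHERE", LineKind.LOCATION, "LOCATION"),
    ("912300 20 0 140 0", LineKind.LATLON, "20"),
    ("012301 AAAA____ #", LineKind.SPECIES, "AAAA"),
])
def test_classify_line_kinds(line, kind, payload_start):
    raw = classify_line(line, 1)
    assert raw.kind is kind
    assert raw.payload.startswith(payload_start)
    assert raw.line_id == line[:6]


def test_classify_line_community_digits():
    raw = classify_line("503201 COMMUNITY 01 = FRESHWATER RIVER", 4)
    assert raw.kind is LineKind.COMMUNITY
    assert raw.line_id[4:6] == "01"


@pytest.mark.parametrize("line, exc", [
    ("ABC123 junk", NonNumericIdError),
    ("12345", NonNumericIdError),  # too short to carry a 6-digit ID
    ("123456 unknown control digit", UnknownLineIdError),
    ("700001 unknown control digit", UnknownLineIdError),
])
def test_classify_line_rejects(line, exc):
    with pytest.raises(exc):
        classify_line(line, 1)


class TestTokenizer:
    def test_plain_codes_with_terminator(self):
        toks = tokenize_species_line("UTRIAUST UTRIEXOL UTRIBILO #")
        assert [t.code for t in toks] == ["UTRIAUST", "UTRIEXOL", "UTRIBILO"]
        assert not any(t.genus_level for t in toks)

    def test_trailing_asterisk_marks_genus(self):
        toks = tokenize_species_line("NAJAMARI MYRIPROP PHRAAUST ELEOCHAR* #")
        assert toks[3].code == "ELEOCHAR"
        assert toks[3].genus_level is True

    def test_padded_genus_codes(self):
        toks = tokenize_species_line("GAHNIA__* CAREX___* #")
        assert [(t.code, t.genus_level) for t in toks] == [
            ("GAHNIA__", True), ("CAREX___", True)]

    def test_fused_chunk_splits_in_two(self):
        toks = tokenize_species_line("GOODENIA*GOMPCONI")
        assert [(t.code, t.genus_level) for t in toks] == [
            ("GOODENIA", True), ("GOMPCONI", False)]

    def test_displaced_leading_asterisk(self):
        toks = tokenize_species_line("POLYGALA *PORTFILI #")
        assert [(t.code, t.genus_level) for t in toks] == [
            ("POLYGALA", True), ("PORTFILI", False)]

    def test_nine_character_codes_kept_whole(self):
        toks = tokenize_species_line("PLUCTETRT HIBISTURC BORRCARP/ #")
        assert [t.code for t in toks] == ["PLUCTETRT", "HIBISTURC", "BORRCARP/"]
        assert toks[0].ninth_char == "T"
        assert toks[2].ninth_char == "/"

    def test_digits_allowed_in_codes(self):
        toks = tokenize_species_line("BRUNAUS2 SWAIBUR3 #")
        assert [t.code for t in toks] == ["BRUNAUS2", "SWAIBUR3"]

    def test_long_fused_chunk_without_marker(self):
        toks = tokenize_species_line("ABUTOTOCACACADSU")
        assert [t.code for t in toks] == ["ABUTOTOC", "ACACADSU"]

    @pytest.mark.parametrize("payload", ["", "#", "  # "])
    def test_empty_payload_raises(self, payload):
        with pytest.raises(EmptySpeciesLineError):
            tokenize_species_line(payload)


class TestWorkedExample:
    def test_two_blocks_three_communities(self, example_blocks):
        assert len(example_blocks) == 2
        assert sum(len(b.communities) for b in example_blocks) == 3

    def test_block_headers(self, example_blocks):
        n032, p037 = example_blocks
        assert (n032.state_code, n032.location_code) == ("N", "N032")
        assert n032.location_name == "CENTRAL COAST: SYDNEY"
        assert n032.source_citation_text == "PIDGEON 1940"
        assert n032.verbatim_coords == (33, 51, 151, 13)
        assert p037.location_code == "P037"
        assert p037.verbatim_coords == (20, 15, 131, 45)

    def test_species_code_counts(self, example_blocks):
        n032, p037 = example_blocks
        assert [len(c.species_codes) for c in n032.communities] == [44, 25]
        assert len(p037.communities[0].species_codes) == 99

    def test_comment_line_tokenizes_to_dominants(self, example_blocks):
        comment = example_blocks[1].communities[0].comment_payload
        toks = tokenize_species_line(comment)
        assert [t.code for t in toks] == ["EUCAPAPU", "ACACVICT"]

    def test_nothing_quarantined(self, example_result):
        assert example_result.quarantined == []
        assert example_result.issues == []

    def test_line_conservation(self, example_result):
        assert (example_result.n_attached_lines
                + len(example_result.quarantined)
                == example_result.n_nonblank_lines)


class TestStreamRecovery:
    def test_orphan_species_line_quarantined(self):
        res = parse_cave_stream(["003201 UTRIAUST #", "800000 N"])
        assert res.blocks == []
        assert [q.reason for q in res.quarantined] == ["ORPHAN_LINE"]

    def test_non_numeric_line_quarantined(self):
        lines = ["800000 N",
                 "503200 LOCATION N032 = PLACE (SMITH 1950)",
                 "903200 33 51 151 13",
                 "503201 COMMUNITY 01 = RIVER",
                 "corrupted line from another file",
                 "003201 UTRIAUST #",
                 "500000 ----"]
        res = parse_cave_stream(lines)
        assert len(res.blocks) == 1
        assert [q.reason for q in res.quarantined] == ["NON_NUMERIC_ID"]
        assert res.n_attached_lines + 1 == res.n_nonblank_lines

    def test_non_ascii_line_quarantined(self):
        res = parse_cave_stream(["800000 N", "503200 LOCATION N032 = CAFÉ"])
        assert [q.reason for q in res.quarantined] == ["NON_ASCII"]

    def test_missing_latlon_block_kept_with_issue(self):
        lines = ["800000 N",
                 "503200 LOCATION N032 = PLACE (SMITH 1950)",
                 "503201 COMMUNITY 01 = RIVER",
                 "003201 UTRIAUST #",
                 "500000 ----"]
        res = parse_cave_stream(lines)
        assert len(res.blocks) == 1
        assert res.blocks[0].verbatim_coords is None
        assert "MISSING_LATLON" in [i.code for i in res.issues]
        assert res.quarantined == []

    def test_empty_species_line_quarantined_block_continues(self):
        lines = ["800000 N",
                 "503200 LOCATION N032 = PLACE (SMITH 1950)",
                 "903200 33 51 151 13",
                 "503201 COMMUNITY 01 = RIVER",
                 "003201 #",
                 "003201 UTRIAUST #",
                 "500000 ----"]
        res = parse_cave_stream(lines)
        assert [q.reason for q in res.quarantined] == ["EMPTY_SPECIES_LINE"]
        assert len(res.blocks[0].communities[0].species_codes) == 1

    def test_state_line_updates_subsequent_blocks(self, example_blocks):
        assert example_blocks[0].state_code == "N"
        assert example_blocks[1].state_code == "P"


class TestCanonicalWriter:
    def test_roundtrip_fixed_point_on_example(self, example_blocks):
        lines = write_canonical(example_blocks)
        reparsed = parse_cave_stream(lines).blocks
        assert [b.structure() for b in reparsed] == \
               [b.structure() for b in example_blocks]
        # second application is a fixed point
        again = parse_cave_stream(write_canonical(reparsed)).blocks
        assert [b.structure() for b in again] == \
               [b.structure() for b in reparsed]

    def test_empty_block_list(self):
        assert write_canonical([]) == []

    def test_nine_codes_split_over_two_lines(self):
        block = LocationBlock(
            state_code="N", location_code="N001", location_name="X",
            verbatim_coords=(20, 0, 140, 0),
            communities=[CommunityRecord(
                community_number=1, description="D",
                species_codes=[SpeciesCode(f"CODE{i:04d}") for i in range(9)])])
        lines = write_canonical([block])
        species_lines = [l for l in lines if l.startswith("000101")]
        assert len(species_lines) == 2
        assert len(species_lines[0].split()) == 10  # id + 8 codes + '#'
        assert len(species_lines[1].split()) == 3

    def test_jsonl_roundtrip(self, example_blocks, tmp_path):
        path = tmp_path / "blocks.jsonl"
        blocks_to_jsonl(example_blocks, path)
        loaded = blocks_from_jsonl(path)
        assert [b.structure() for b in loaded] == \
               [b.structure() for b in example_blocks]


_code_st = st.text(alphabet=st.sampled_from("ABCDEFGHIJKLMNOPQRSTUVWXYZ"),
                   min_size=8, max_size=8)


@settings(max_examples=50, deadline=None)
@given(st.lists(
    st.tuples(_code_st, st.booleans()), min_size=1, max_size=30, unique=True))
def test_writer_parser_roundtrip_property(codes):
    """Any block survives write -> parse structurally intact."""
    block = LocationBlock(
        state_code="N", location_code="N005", location_name="PROP SITE",
        source_citation_text="SMITH 1950", verbatim_coords=(25, 30, 140, 15),
        communities=[CommunityRecord(
            community_number=1, description="TEST COMMUNITY",
            species_codes=[SpeciesCode(c, genus_level=g) for c, g in codes])])
    reparsed = parse_cave_stream(write_canonical([block])).blocks
    assert len(reparsed) == 1
    assert reparsed[0].structure() == block.structure()


def test_token_conservation(example_result):
    """Sum of community code lists equals total tokens in species payloads."""
    text = cd.example_core_path().read_text()
    total = 0
    for line in text.splitlines():
        if line[:1] == "0" and line[:6].isdigit():
            total += len(tokenize_species_line(line[6:]))
    parsed = sum(len(c.species_codes)
                 for b in example_result.blocks for c in b.communities)
    assert parsed == total == 168
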