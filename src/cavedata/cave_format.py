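"""Reading and canonical re-writing of CAVE sequential core-data files.

The CAVE (Classification of Australian VEgetation) core files are plain-text
sequential records.  Every line opens with a six-digit line ID whose leading
control digit declares the role of the data that follows:

========  =====================================================
``800000``  state/territory identifier for subsequent locations
``5xxx00``  location header: code, name and source citation
``9xxxbb``  latitude and longitude (degrees and minutes, four integers)
``5xxxbb``  community number ``bb`` at location ``xxx``, with description
``3xxxbb``  additional comment (often dominant-species codes)
``0xxxbb``  species list: 8-9 character alphacodes, ``#``-terminated
``500000``  end of the location block
========  =====================================================

``xxx`` is the zero-padded location number and ``bb`` the community number.
Species alphacodes pad short genus names with ``_``; a trailing ``*`` marks a
genus-level record and the ninth character is reserved for infraspecific taxa.

This module classifies lines, tokenizes species lists (including the fused and
displaced ``*`` forms that occur in the legacy printouts), assembles
:class:`LocationBlock` structures, and re-writes them in a canonical form of
the same grammar.  No input line is silently dropped: every non-blank line is
either attached to a block or quarantined with a reason.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field, asdict
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

logger = logging.getLogger(__name__)

__all__ = [
    "LineKind",
    "RawLine",
    "SpeciesCode",
    "CommunityRecord",
    "LocationBlock",
    "QuarantinedLine",
    "ParseIssue",
    "ParseResult",
    "CaveFormatError",
    "NonNumericIdError",
    "UnknownLineIdError",
    "EmptySpeciesLineError",
    "classify_line",
    "tokenize_species_line",
    "parse_cave_stream",
    "read_cave_file",
    "write_canonical",
    "blocks_to_jsonl",
    "blocks_from_jsonl",
]


class CaveFormatError(ValueError):
    """Base class for recoverable CAVE-format errors."""

    code = "CAVE_FORMAT_ERROR"


class NonNumericIdError(CaveFormatError):
    """First six characters of a line are not all digits."""

    code = "NON_NUMERIC_ID"


class UnknownLineIdError(CaveFormatError):
    """Six-digit ID whose control digit matches no known record class."""

    code = "UNKNOWN_LINE_ID"


class EmptySpeciesLineError(CaveFormatError):
    """A species/comment payload with no tokens (e.g. a stray ``#``)."""

    code = "EMPTY_SPECIES_LINE"


class LineKind(Enum):
    STATE = "STATE"
    LOCATION = "LOCATION"
    LATLON = "LATLON"
    COMMUNITY = "COMMUNITY"
    COMMENT = "COMMENT"
    SPECIES = "SPECIES"
    END = "END"


@dataclass(frozen=True)
class RawLine:
    """One classified input line (1-based ``line_number``)."""

    line_number: int
    line_id: str
    payload: str
    kind: LineKind


@dataclass
class SpeciesCode:
    """One species alphacode token.

    ``code`` is the bare 8-9 character code with ``*``/``#`` markers stripped
    but ``_`` padding and any ninth character (``/``, digits, letters)
    retained.  ``genus_level`` is True when an asterisk was adjacent in the
    source, marking a genus-only record.
    """

    code: str
    genus_level: bool = False

    @property
    def ninth_char(self) -> Optional[str]:
        return self.code[8] if len(self.code) >= 9 else None

    def render(self) -> str:
        return self.code + ("*" if self.genus_level else "")


@dataclass
class CommunityRecord:
    community_number: int
    description: str = ""
    comment_payload: Optional[str] = None
    comment_line_number: Optional[int] = None
    species_codes: list[SpeciesCode] = field(default_factory=list)
    line_span: tuple[int, int] = (0, 0)
    line_id: str = ""

    def structure(self):
        """Provenance-free structural key used for round-trip comparison."""
        return (
            self.community_number,
            self.description,
            self.comment_payload,
            tuple((c.code, c.genus_level) for c in self.species_codes),
        )


@dataclass
class LocationBlock:
    state_code: str
    location_code: str
    location_name: str = ""
    source_citation_text: str = ""
    verbatim_coords: Optional[tuple[int, int, int, int]] = None
    communities: list[CommunityRecord] = field(default_factory=list)
    formation: str = ""
    source_file: str = ""
    line_span: tuple[int, int] = (0, 0)

    def structure(self):
        return (
            self.state_code,
            self.location_code,
            self.location_name,
            self.source_citation_text,
            self.verbatim_coords,
            tuple(c.structure() for c in self.communities),
        )

    @property
    def location_number(self) -> int:
        digits = re.sub(r"\D", "", self.location_code)
        return int(digits) if digits else 0


@dataclass(frozen=True)
class QuarantinedLine:
    line_number: int
    text: str
    reason: str


@dataclass(frozen=True)
class ParseIssue:
    """A non-fatal anomaly attached to an otherwise-kept block or line."""

    line_number: int
    code: str
    message: str


@dataclass
class ParseResult:
    blocks: list[LocationBlock]
    quarantined: list[QuarantinedLine]
    issues: list[ParseIssue] = field(default_factory=list)
    n_nonblank_lines: int = 0
    n_attached_lines: int = 0

    def __iter__(self):  # allows ``blocks, quarantined = parse_cave_stream(...)``
        return iter((self.blocks, self.quarantined))


_ID_RE = re.compile(r"^\d{6}$")


def classify_line(line: str, line_number: int = 0) -> RawLine:
    """Classify one input line by its six-digit control ID.

    The control digit (first character) declares the record class; the two
    trailing digits ``bb`` distinguish a location header (``bb == 00``) from a
    community record.  ``800000`` and ``500000`` are the state and end-of-block
    sentinels.

    Raises
    ------
    NonNumericIdError
        when the first six characters are not all digits (corrupted or
        foreign line; the caller quarantines it).
    UnknownLineIdError
        when the ID is numeric but matches no record class.
    """
    text = line.rstrip()
    if not text:
        raise CaveFormatError("empty line")
    line_id = text[:6]
    if not _ID_RE.match(line_id):
        raise NonNumericIdError(f"line {line_number}: non-numeric line ID {line_id!r}")
    payload = text[6:].strip()
    control = line_id[0]
    if line_id == "800000" or (control == "8" and line_id.endswith("00000")):
        kind = LineKind.STATE
    elif line_id == "500000":
        kind = LineKind.END
    elif control == "5":
        kind = LineKind.LOCATION if line_id[4:6] == "00" else LineKind.COMMUNITY
    elif control == "9":
        kind = LineKind.LATLON
    elif control == "3":
        kind = LineKind.COMMENT
    elif control == "0":
        kind = LineKind.SPECIES
    else:
        raise UnknownLineIdError(
            f"line {line_number}: unrecognised control digit in ID {line_id!r}"
        )
    return RawLine(line_number=line_number, line_id=line_id, payload=payload, kind=kind)


def tokenize_species_line(payload: str) -> list[SpeciesCode]:
    """Tokenize the payload of a species (or code-bearing comment) line.

    Handles the wrinkles found in the legacy printouts:

    * trailing ``#`` terminator removed;
    * fused chunks (``GOODENIA*GOMPCONI``) split greedily: cut after an
      asterisk within the first nine characters, else after eight;
    * a lone leading-``*`` chunk (``POLYGALA *PORTFILI``) is a displaced
      genus marker of the *preceding* token;
    * ``_`` padding and ninth characters are preserved verbatim.

    Raises :class:`EmptySpeciesLineError` when no tokens remain.
    """
    text = payload.strip()
    if text.endswith("#"):
        text = text[:-1].rstrip()
    tokens: list[SpeciesCode] = []
    for chunk in text.split():
        if chunk == "#":
            continue
        if chunk.startswith("*"):
            # displaced genus marker: belongs to the previous code
            if tokens:
                tokens[-1].genus_level = True
                logger.debug("re-attached displaced '*' to %s", tokens[-1].code)
            else:
                logger.warning("leading '*' with no preceding token in %r", payload)
            chunk = chunk[1:]
            if not chunk:
                continue
        rest = chunk
        while rest:
            if len(rest) <= 9 and "*" not in rest[:-1]:
                piece, rest = rest, ""
            else:
                star = rest.find("*")
                if 0 <= star <= 8:
                    piece, rest = rest[: star + 1], rest[star + 1 :]
                else:
                    piece, rest = rest[:8], rest[8:]
                logger.debug("split fused chunk %r -> %r + %r", chunk, piece, rest)
            genus = piece.endswith("*")
            code = piece.rstrip("*").rstrip("#")
            if code:
                tokens.append(SpeciesCode(code=code, genus_level=genus))
    if not tokens:
        raise EmptySpeciesLineError(f"no species tokens in payload {payload!r}")
    return tokens


_LOCATION_RE = re.compile(r"^LOCATION\s+(\S+)\s*=\s*(.*)$", re.IGNORECASE)
_COMMUNITY_RE = re.compile(r"^COMMUNITY\s+(\d+)\s*=\s*(.*)$", re.IGNORECASE)
_CITATION_RE = re.compile(r"^(.*?)\s*\(([^()]*\d{4}[^()]*)\)\s*$")


def _parse_location_payload(payload: str, line_id: str, state: Optional[str]):
    m = _LOCATION_RE.match(payload)
    if m:
        code, rest = m.group(1), m.group(2).strip()
    else:
        code = (state or "?") + line_id[1:4]
        rest = payload
    cm = _CITATION_RE.match(rest)
    if cm:
        name, citation = cm.group(1).strip(), cm.group(2).strip()
    else:
        name, citation = rest, ""
    return code, name, citation


def parse_cave_stream(
    lines: Iterable[str],
    formation: str = "",
    source_file: str = "",
) -> ParseResult:
    """Assemble location blocks from a sequence of CAVE text lines.

    The expected order within one file is ``STATE -> (LOCATION -> LATLON ->
    {COMMUNITY -> [COMMENT] -> SPECIES+}+ -> END)*``; a STATE line updates the
    current state for all subsequent blocks.  Orphan lines (species,
    community, comment or coordinates outside any block) and undecodable
    lines are quarantined with their line number; blocks with anomalies
    (missing coordinates, unterminated blocks, mismatched IDs) are kept and
    the anomaly is recorded as a :class:`ParseIssue`.

    Conservation invariant: every non-blank input line is either attached to
    a block (or is a state/end sentinel) or quarantined -- never dropped.
    """
    blocks: list[LocationBlock] = []
    quarantined: list[QuarantinedLine] = []
    issues: list[ParseIssue] = []
    state: Optional[str] = None
    block: Optional[LocationBlock] = None
    community: Optional[CommunityRecord] = None
    n_nonblank = 0
    n_attached = 0

    def close_block(end_line: Optional[int], terminated: bool) -> None:
        nonlocal block, community
        if block is None:
            return
        if not terminated:
            issues.append(
                ParseIssue(block.line_span[0], "UNTERMINATED_BLOCK",
                           f"block {block.location_code} not closed by 500000"))
        if block.verbatim_coords is None:
            issues.append(
                ParseIssue(block.line_span[0], "MISSING_LATLON",
                           f"location {block.location_code} has no coordinate line"))
        if not block.communities:
            issues.append(
                ParseIssue(block.line_span[0], "EMPTY_BLOCK",
                           f"location {block.location_code} has no communities"))
        if end_line is not None:
            block.line_span = (block.line_span[0], end_line)
        blocks.append(block)
        block, community = None, None

    for line_number, raw in enumerate(lines, start=1):
        text = raw.rstrip("\r\n")
        if not text.strip():
            continue
        n_nonblank += 1
        if any(ord(ch) > 127 for ch in text):
            quarantined.append(QuarantinedLine(line_number, text, "NON_ASCII"))
            continue
        try:
            rl = classify_line(text, line_number)
        except CaveFormatError as exc:
            quarantined.append(QuarantinedLine(line_number, text, exc.code))
            continue

        if rl.kind is LineKind.STATE:
            close_block(None, terminated=False) if block is not None else None
            state = rl.payload.split()[0] if rl.payload.split() else ""
            n_attached += 1
        elif rl.kind is LineKind.LOCATION:
            if block is not None:
                close_block(None, terminated=False)
            code, name, citation = _parse_location_payload(rl.payload, rl.line_id, state)
            if state is None:
                state = code[0]
                issues.append(ParseIssue(line_number, "MISSING_STATE",
                                         f"no 800000 line before {code}; inferred {state}"))
            if code[0] != state:
                issues.append(ParseIssue(line_number, "STATE_MISMATCH",
                                         f"location {code} under state {state}"))
            block = LocationBlock(
                state_code=state, location_code=code, location_name=name,
                source_citation_text=citation, formation=formation,
                source_file=source_file, line_span=(line_number, line_number))
            community = None
            n_attached += 1
        elif rl.kind is LineKind.LATLON:
            if block is None:
                quarantined.append(QuarantinedLine(line_number, text, "ORPHAN_LINE"))
                continue
            parts = rl.payload.split()
            if len(parts) != 4 or not all(p.lstrip("-").isdigit() for p in parts):
                quarantined.append(QuarantinedLine(line_number, text, "MALFORMED_LATLON"))
                continue
            coords = tuple(int(p) for p in parts)
            if not (0 <= coords[1] < 60 and 0 <= coords[3] < 60):
                issues.append(ParseIssue(line_number, "MINUTES_OUT_OF_RANGE",
                                         f"minutes outside [0,60) in {rl.payload!r}"))
            block.verbatim_coords = coords  # type: ignore[assignment]
            n_attached += 1
        elif rl.kind is LineKind.COMMUNITY:
            if block is None:
                quarantined.append(QuarantinedLine(line_number, text, "ORPHAN_LINE"))
                continue
            number = int(rl.line_id[4:6])
            m = _COMMUNITY_RE.match(rl.payload)
            description = m.group(2).strip() if m else rl.payload
            if block.verbatim_coords is None and not block.communities:
                # anomaly recorded once, at first community, block is kept
                pass  # reported at close_block
            community = CommunityRecord(
                community_number=number, description=description,
                line_span=(line_number, line_number), line_id=rl.line_id)
            block.communities.append(community)
            n_attached += 1
        elif rl.kind is LineKind.COMMENT:
            if community is None:
                quarantined.append(QuarantinedLine(line_number, text, "ORPHAN_LINE"))
                continue
            if community.comment_payload is None:
                community.comment_payload = rl.payload
                community.comment_line_number = line_number
            else:
                community.comment_payload += "\n" + rl.payload
            community.line_span = (community.line_span[0], line_number)
            n_attached += 1
        elif rl.kind is LineKind.SPECIES:
            if community is None:
                quarantined.append(QuarantinedLine(line_number, text, "ORPHAN_LINE"))
                continue
            try:
                tokens = tokenize_species_line(rl.payload)
            except EmptySpeciesLineError:
                quarantined.append(QuarantinedLine(line_number, text, "EMPTY_SPECIES_LINE"))
                continue
            expected = community.line_id[1:6]
            if rl.line_id[1:6] != expected:
                issues.append(ParseIssue(line_number, "ID_MISMATCH",
                                         f"species line {rl.line_id} under community "
                                         f"{community.line_id}"))
            community.species_codes.extend(tokens)
            community.line_span = (community.line_span[0], line_number)
            n_attached += 1
        elif rl.kind is LineKind.END:
            if block is None:
                quarantined.append(QuarantinedLine(line_number, text, "STRAY_END"))
                continue
            n_attached += 1
            close_block(line_number, terminated=True)

    close_block(None, terminated=False)
    return ParseResult(blocks=blocks, quarantined=quarantined, issues=issues,
                       n_nonblank_lines=n_nonblank, n_attached_lines=n_attached)


def read_cave_file(path, formation: str = "") -> ParseResult:
    """Read one CAVE core file, normalizing encoding first.

    The legacy data is ASCII; bytes are decoded through latin-1 (lossless) and
    any line containing non-ASCII characters is quarantined rather than
    guessed at.
    """
    path = Path(path)
    data = path.read_bytes().decode("latin-1")
    return parse_cave_stream(data.splitlines(), formation=formation,
                             source_file=path.name)


_END_RULE = "-" * 31
_CODES_PER_LINE = 8


def write_canonical(blocks: Sequence[LocationBlock]) -> list[str]:
    """Re-emit blocks in the same line grammar, normalized.

    Species lines carry at most eight codes each, single-space separated and
    ``#``-terminated; genus markers are re-attached as trailing ``*``.
    ``parse(write(parse(x)))`` is structurally identical to ``parse(x)``.
    """
    out: list[str] = []
    current_state: Optional[str] = None
    for block in blocks:
        if block.state_code != current_state:
            out.append(f"800000 {block.state_code}")
            current_state = block.state_code
        loc = block.location_number
        tail = f" ({block.source_citation_text})" if block.source_citation_text else ""
        out.append(f"5{loc:03d}00 LOCATION {block.location_code} = "
                   f"{block.location_name}{tail}")
        if block.verbatim_coords is not None:
            a, b, c, d = block.verbatim_coords
            out.append(f"9{loc:03d}00 {a} {b} {c} {d}")
        for comm in block.communities:
            bb = comm.community_number
            out.append(f"5{loc:03d}{bb:02d} COMMUNITY {bb:02d} = {comm.description}")
            if comm.comment_payload is not None:
                for comment_line in comm.comment_payload.split("\n"):
                    out.append(f"3{loc:03d}{bb:02d} {comment_line}")
            codes = comm.species_codes
            for i in range(0, len(codes), _CODES_PER_LINE):
                chunk = " ".join(c.render() for c in codes[i : i + _CODES_PER_LINE])
                out.append(f"0{loc:03d}{bb:02d} {chunk} #")
        out.append(f"500000 {_END_RULE}")
    return out


# ---------------------------------------------------------------------------
# JSON-lines interchange

def _block_to_dict(block: LocationBlock) -> dict:
    d = asdict(block)
    d["verbatim_coords"] = list(block.verbatim_coords) if block.verbatim_coords else None
    return d


def _block_from_dict(d: dict) -> LocationBlock:
    communities = [
        CommunityRecord(
            community_number=c["community_number"],
            description=c.get("description", ""),
            comment_payload=c.get("comment_payload"),
            comment_line_number=c.get("comment_line_number"),
            species_codes=[SpeciesCode(code=s["code"], genus_level=s["genus_level"])
                           for s in c.get("species_codes", [])],
            line_span=tuple(c.get("line_span", (0, 0))),
            line_id=c.get("line_id", ""),
        )
        for c in d.get("communities", [])
    ]
    coords = d.get("verbatim_coords")
    return LocationBlock(
        state_code=d["state_code"], location_code=d["location_code"],
        location_name=d.get("location_name", ""),
        source_citation_text=d.get("source_citation_text", ""),
        verbatim_coords=tuple(coords) if coords else None,
        communities=communities, formation=d.get("formation", ""),
        source_file=d.get("source_file", ""),
        line_span=tuple(d.get("line_span", (0, 0))))


def blocks_to_jsonl(blocks: Sequence[LocationBlock], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for block in blocks:
            fh.write(json.dumps(_block_to_dict(block), sort_keys=True) + "\n")


def blocks_from_jsonl(path) -> list[LocationBlock]:
    blocks = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                blocks.append(_block_from_dict(json.loads(line)))
    return blocks
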