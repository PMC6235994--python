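"""Master site table assembly: blocks + publications + coordinates.

One master-site row is produced per location x community.  Citation text in
the location header (the parenthetical ``(SURNAME YEAR)`` tail) is matched to
the publications table by first-author surname and year; where the original
compilers stacked multiple citations, one primary reference is selected and
every non-selected citation is preserved in the retrieval comments -- nothing
is lost, only demoted.

Overlapping formation files duplicated some blocks.  Duplicates with
identical species lists are collapsed (keeping the first seen); where one
copy's list contains the others', the larger list is kept; genuinely
conflicting copies are all kept and flagged, since duplication is preferable
to gaps.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import pandas as pd

from .cave_format import CommunityRecord, LocationBlock
from .geospatial import GeoPoint, dms_to_decimal, CoordinateEnvelopeWarning

__all__ = [
    "Publication",
    "MasterSiteRow",
    "MASTER_SITE_COLUMNS",
    "RunLog",
    "DuplicateRefIdError",
    "parse_publications",
    "extract_citations",
    "select_primary_reference",
    "build_master_sites",
    "master_sites_to_frame",
]


class DuplicateRefIdError(ValueError):
    code = "DUPLICATE_REF_ID"


@dataclass(frozen=True)
class Publication:
    ref_id: int
    authors: str
    year: Optional[int]
    title: str = ""
    journal: str = ""
    volume: str = ""
    pages: str = ""

    @property
    def first_surname(self) -> str:
        head = re.split(r"[,&]", self.authors, maxsplit=1)[0]
        return head.strip()

    def citation(self) -> str:
        bits = [self.authors, str(self.year) if self.year else "", self.title,
                self.journal, self.volume, self.pages]
        return " ".join(b for b in bits if b).strip()


#: Exact column set of the master site file, in output order.
MASTER_SITE_COLUMNS = [
    "formation", "source_file", "line_id_number", "location_code",
    "community_number", "locality", "state", "ref_id", "ref_date",
    "verbatim_lat_lon", "vegetation_type_1", "vegetation_type_2",
    "comment_line_number", "collator_notes", "decimal_latitude",
    "decimal_longitude", "uncertainty_m", "retrieval_comments",
]


@dataclass
class MasterSiteRow:
    formation: str = ""
    source_file: str = ""
    line_id_number: Optional[int] = None
    location_code: str = ""
    community_number: int = 0
    locality: str = ""
    state: str = ""
    ref_id: Optional[int] = None
    ref_date: Optional[int] = None
    verbatim_lat_lon: str = ""
    vegetation_type_1: str = ""
    vegetation_type_2: str = ""
    comment_line_number: Optional[int] = None
    collator_notes: str = ""
    decimal_latitude: Optional[float] = None
    decimal_longitude: Optional[float] = None
    uncertainty_m: Optional[float] = None
    retrieval_comments: str = ""
    # not part of the emitted column set; carried for export provenance
    community: Optional[CommunityRecord] = None
    source_citation_text: str = ""
    line_span: tuple[int, int] = (0, 0)

    def key(self) -> tuple[str, int]:
        return (self.location_code, self.community_number)


@dataclass(frozen=True)
class LogEvent:
    kind: str
    message: str
    provenance: str = ""


class RunLog:
    """Structured record of every drop, flag and unresolved item in a run."""

    def __init__(self) -> None:
        self.events: list[LogEvent] = []

    def add(self, kind: str, message: str, provenance: str = "") -> None:
        self.events.append(LogEvent(kind, message, provenance))

    def of_kind(self, kind: str) -> list[LogEvent]:
        return [e for e in self.events if e.kind == kind]

    def to_text(self) -> str:
        lines = [f"[{e.kind}] {e.message}" + (f"  ({e.provenance})" if e.provenance else "")
                 for e in self.events]
        return "\n".join(lines) + ("\n" if lines else "")


_PUB_ALIASES = {
    "ref_id": {"ref_id", "id"},
    "authors": {"authors", "author(s)", "author"},
    "year": {"year", "date"},
    "title": {"title"},
    "journal": {"journal", "journal etc.", "journal etc"},
    "volume": {"volume", "volume no.", "volume no"},
    "pages": {"pages", "page numbers"},
}


def parse_publications(
    source: Union[str, Path, pd.DataFrame],
) -> dict[int, Publication]:
    """Read the master publications table into a ref_id -> Publication map.

    Duplicate reference IDs are an error; a missing or non-4-digit year is
    kept with a warning (some sources carry no date).
    """
    if isinstance(source, pd.DataFrame):
        df = source
    else:
        df = pd.read_csv(source, dtype=str, keep_default_na=False)
    lowered = {str(c).strip().casefold(): c for c in df.columns}
    cols = {}
    for canonical, names in _PUB_ALIASES.items():
        for alias in names:
            if alias in lowered:
                cols[canonical] = lowered[alias]
                break
    if "ref_id" not in cols or "authors" not in cols:
        raise ValueError("publications table must carry ID and author columns")

    out: dict[int, Publication] = {}
    for r in df.to_dict("records"):
        ref_id = int(str(r[cols["ref_id"]]).strip())
        if ref_id in out:
            raise DuplicateRefIdError(f"reference ID {ref_id} occurs twice")
        year_raw = str(r.get(cols.get("year", ""), "")).strip()
        year: Optional[int] = None
        if re.fullmatch(r"\d{4}", year_raw):
            year = int(year_raw)
        else:
            warnings.warn(f"MISSING_YEAR: reference {ref_id} has year "
                          f"{year_raw!r}", stacklevel=2)
        out[ref_id] = Publication(
            ref_id=ref_id,
            authors=str(r[cols["authors"]]).strip(),
            year=year,
            title=str(r.get(cols.get("title", ""), "")).strip(),
            journal=str(r.get(cols.get("journal", ""), "")).strip(),
            volume=str(r.get(cols.get("volume", ""), "")).strip(),
            pages=str(r.get(cols.get("pages", ""), "")).strip(),
        )
    return out


_CITE_RE = re.compile(r"([A-Za-z][A-Za-z'.\-]*)\s+(\d{4})")


def extract_citations(text: str) -> list[tuple[str, int]]:
    """Pull (surname, year) pairs out of a location header's citation text."""
    return [(m.group(1), int(m.group(2))) for m in _CITE_RE.finditer(text or "")]


def select_primary_reference(
    candidates: Sequence[tuple[int, Optional[int]]],
    strategy: str = "latest",
    overrides: Optional[Mapping[str, int]] = None,
    site_key: Optional[str] = None,
) -> int:
    """Pick the single primary reference from stacked citations.

    An override table (site key -> ref_id) wins when present; otherwise the
    latest (default) or earliest year.  The latest citation is usually the
    compilation whose list was actually digitized.  Ties break on ref_id for
    determinism.
    """
    if not candidates:
        raise ValueError("candidates must be non-empty")
    if overrides and site_key is not None and site_key in overrides:
        return overrides[site_key]
    if strategy not in ("latest", "earliest"):
        raise ValueError(f"unknown strategy {strategy!r}")
    keyed = [(year if year is not None else -1, ref_id) for ref_id, year in candidates]
    chosen = max(keyed) if strategy == "latest" else min(keyed)
    return chosen[1]


def _codes_multiset(comm: CommunityRecord) -> tuple:
    return tuple(sorted((c.code, c.genus_level) for c in comm.species_codes))


def build_master_sites(
    blocks: Sequence[LocationBlock],
    publications: Mapping[int, Publication],
    geopoints: Optional[Mapping[str, GeoPoint]] = None,
    overrides: Optional[Mapping[str, GeoPoint]] = None,
    config: Optional[dict] = None,
) -> tuple[list[MasterSiteRow], RunLog]:
    """Assemble the master site table: one row per (location, community).

    ``geopoints`` optionally pre-supplies converted coordinates per location
    code (otherwise they are converted here from each block's verbatim
    integers); ``overrides`` carries verified manual corrections which win
    outright and mark the row amended.
    """
    cfg = config or {}
    strategy = cfg.get("reference_strategy", "latest")
    ref_overrides = cfg.get("reference_overrides") or {}
    log = RunLog()

    # deduplicate (location, community) pairs across formation files
    groups: dict[tuple[str, int], list[tuple[LocationBlock, CommunityRecord]]] = {}
    order: list[tuple[str, int]] = []
    for block in blocks:
        for comm in block.communities:
            key = (block.location_code, comm.community_number)
            if key not in groups:
                groups[key] = []
                order.append(key)
            groups[key].append((block, comm))

    selected: list[tuple[LocationBlock, CommunityRecord, str]] = []
    for key in order:
        copies = groups[key]
        if len(copies) == 1:
            selected.append((*copies[0], ""))
            continue
        sets = [set(_codes_multiset(c)) for _, c in copies]
        largest = max(range(len(copies)), key=lambda i: (len(sets[i]), -i))
        if all(s <= sets[largest] for s in sets):
            # identical or nested lists: keep the largest copy, log the rest
            for i, (b, c) in enumerate(copies):
                if i == largest:
                    continue
                log.add("DUPLICATE_DROPPED",
                        f"{key[0]} community {key[1]:02d} duplicated in "
                        f"{b.formation or b.source_file}; kept copy with "
                        f"{len(sets[largest])} codes",
                        provenance=f"{b.source_file}:{c.line_span[0]}")
            selected.append((*copies[largest], ""))
        else:
            for b, c in copies:
                log.add("CONFLICTING_DUPLICATE",
                        f"{key[0]} community {key[1]:02d}: conflicting species "
                        f"lists across formation files; all copies kept",
                        provenance=f"{b.source_file}:{c.line_span[0]}")
                selected.append((b, c, "CONFLICTING_DUPLICATE"))

    # index publications by (surname, year) for citation matching
    by_cite: dict[tuple[str, int], list[int]] = {}
    for pub in publications.values():
        if pub.year is not None:
            by_cite.setdefault((pub.first_surname.casefold(), pub.year),
                               []).append(pub.ref_id)

    # resolve citations once per block (communities share the header)
    cite_cache: dict[int, tuple[list, list[str], list[tuple[int, Optional[int]]]]] = {}

    def _block_citations(block: LocationBlock):
        key = id(block)
        if key in cite_cache:
            return cite_cache[key]
        comments: list[str] = []
        cites = extract_citations(block.source_citation_text)
        resolved: list[tuple[int, Optional[int]]] = []
        for surname, year in cites:
            ids = sorted(by_cite.get((surname.casefold(), year), []))
            if len(ids) == 1:
                resolved.append((ids[0], year))
            elif len(ids) > 1:
                log.add("AMBIGUOUS_CITATION",
                        f"({surname} {year}) matches references {ids}",
                        provenance=f"{block.source_file}:{block.line_span[0]}")
                comments.append(f"ambiguous citation ({surname} {year}): {ids}")
            else:
                log.add("UNRESOLVED_CITATION",
                        f"({surname} {year}) not in publications table",
                        provenance=f"{block.source_file}:{block.line_span[0]}")
                comments.append(f"unresolved citation ({surname} {year})")
        if not cites and block.source_citation_text:
            log.add("UNRESOLVED_CITATION",
                    f"unparseable citation {block.source_citation_text!r}",
                    provenance=f"{block.source_file}:{block.line_span[0]}")
            comments.append(f"unparseable citation {block.source_citation_text!r}")
        cite_cache[key] = (cites, comments, resolved)
        return cite_cache[key]

    rows: list[MasterSiteRow] = []
    for block, comm, dup_flag in selected:
        comments = []
        if dup_flag:
            comments.append(dup_flag)

        ref_id: Optional[int] = None
        ref_date: Optional[int] = None
        cites, cite_comments, resolved = _block_citations(block)
        comments.extend(cite_comments)
        if resolved:
            site_key = f"{block.location_code}:{comm.community_number:02d}"
            ref_id = select_primary_reference(resolved, strategy=strategy,
                                              overrides=ref_overrides,
                                              site_key=site_key)
            if len(cites) > 1:
                # date disambiguates only when citations were stacked
                ref_date = dict(resolved).get(ref_id)
                others = [f"{rid} ({yr})" for rid, yr in resolved if rid != ref_id]
                if others:
                    comments.append("non-primary references: " + ", ".join(others))

        # coordinates
        point: Optional[GeoPoint] = None
        if overrides and block.location_code in overrides:
            point = overrides[block.location_code]
            comments.append("coordinates amended" +
                            (f": {point.note}" if point.note else ""))
        elif geopoints and block.location_code in geopoints:
            point = geopoints[block.location_code]
        elif block.verbatim_coords is not None:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", CoordinateEnvelopeWarning)
                try:
                    point = dms_to_decimal(*block.verbatim_coords)
                except ValueError as exc:
                    log.add("BAD_COORDINATES", str(exc),
                            provenance=f"{block.source_file}:{block.line_span[0]}")
                    comments.append("coordinates unusable")
        else:
            comments.append("no verbatim coordinates")

        n_comms = len(block.communities)
        line_id_number = (comm.community_number if n_comms == 1
                          else block.line_span[0])

        verbatim = (" ".join(str(v) for v in block.verbatim_coords)
                    if block.verbatim_coords else "")
        rows.append(MasterSiteRow(
            formation=block.formation,
            source_file=block.source_file,
            line_id_number=line_id_number,
            location_code=block.location_code,
            community_number=comm.community_number,
            locality=block.location_name,
            state=block.state_code,
            ref_id=ref_id,
            ref_date=ref_date,
            verbatim_lat_lon=verbatim,
            vegetation_type_1=comm.description,
            vegetation_type_2=comm.comment_payload or "",
            comment_line_number=comm.comment_line_number,
            collator_notes=cfg.get("collator_notes", {}).get(
                f"{block.location_code}:{comm.community_number:02d}", ""),
            decimal_latitude=round(point.decimal_latitude, 6) if point else None,
            decimal_longitude=round(point.decimal_longitude, 6) if point else None,
            uncertainty_m=round(point.uncertainty_m) if point else None,
            retrieval_comments="; ".join(comments),
            community=comm,
            source_citation_text=block.source_citation_text,
            line_span=comm.line_span,
        ))

    # referential integrity
    for row in rows:
        if row.ref_id is not None and row.ref_id not in publications:
            raise AssertionError(f"ref_id {row.ref_id} missing from publications")
    return rows, log


def master_sites_to_frame(rows: Sequence[MasterSiteRow]) -> pd.DataFrame:
    """Master site rows as a DataFrame with exactly the documented columns."""
    records = []
    for row in rows:
        d = {col: getattr(row, col) for col in MASTER_SITE_COLUMNS}
        records.append(d)
    return pd.DataFrame(records, columns=MASTER_SITE_COLUMNS)
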