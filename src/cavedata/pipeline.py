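"""End-to-end orchestration: core files -> Darwin Core archive directory.

Thin glue over the stage modules, used by the command-line interface and by
tests; each stage remains independently callable.  Output is deterministic:
formations are processed in sorted order and every table is written with a
fixed column order and line terminator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Union

import pandas as pd

from . import assembly, dwc_export, taxonomy
from .cave_format import LocationBlock, ParseResult, read_cave_file
from .dwc_export import DwcConfig
from .geospatial import GeoPoint
from .taxonomy import MatchThresholds

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    blocks: list
    parse_results: dict
    entries: dict
    matches: dict
    sites: list
    run_log: assembly.RunLog
    events: pd.DataFrame
    occurrences: pd.DataFrame
    review: pd.DataFrame
    completeness: dwc_export.CompletenessReport
    eml_xml: str
    written: dict = field(default_factory=dict)


def run_pipeline(
    core_files: Mapping[str, Union[str, Path]],
    conversion_files: Mapping[str, Union[str, Path]],
    publications_file: Union[str, Path],
    checklist_file: Union[str, Path],
    out_dir: Optional[Union[str, Path]] = None,
    thresholds: Optional[MatchThresholds] = None,
    dwc_config: Optional[DwcConfig] = None,
    coordinate_overrides: Optional[Mapping[str, GeoPoint]] = None,
    name_overrides: Optional[Mapping[str, str]] = None,
    assembly_config: Optional[dict] = None,
) -> PipelineResult:
    """Parse, resolve, assemble and export one run of the rescue pipeline."""
    blocks: list[LocationBlock] = []
    parse_results: dict[str, ParseResult] = {}
    for formation in sorted(core_files):
        result = read_cave_file(core_files[formation], formation=formation)
        parse_results[formation] = result
        blocks.extend(result.blocks)

    checklist = taxonomy.load_checklist(checklist_file)
    entries: dict[str, taxonomy.ConversionEntry] = {}
    matches: dict[str, taxonomy.MatchResult] = {}
    for formation in sorted(conversion_files):
        form_entries = taxonomy.parse_conversion_file(
            conversion_files[formation], formation=formation)
        form_matches = taxonomy.resolve_codes(
            form_entries, checklist, thresholds=thresholds,
            overrides=name_overrides)
        for entry in form_entries:
            entries.setdefault(entry.alphacode, entry)
        for code, match in form_matches.items():
            matches.setdefault(code, match)

    publications = assembly.parse_publications(publications_file)
    sites, run_log = assembly.build_master_sites(
        blocks, publications, overrides=coordinate_overrides,
        config=assembly_config)

    events, occurrences = dwc_export.emit_dwc(
        sites, matches=matches, publications=publications,
        config=dwc_config, entries=entries)
    review = taxonomy.export_review_list(matches)
    completeness = dwc_export.completeness_report(occurrences, config=dwc_config)
    eml_xml = ""
    if not occurrences.empty:
        eml = dwc_export.emit_eml(occurrences, config=dwc_config)
        dwc_export.validate_eml(eml)
        eml_xml = dwc_export.eml_to_string(eml)

    written: dict[str, Path] = {}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        sites_df = assembly.master_sites_to_frame(sites)
        targets = {
            "sites": (out / "sites.csv", sites_df),
            "event": (out / "event.csv", events),
            "occurrence": (out / "occurrence.csv", occurrences),
            "review": (out / "review.csv", review),
            "completeness": (out / "completeness.csv", completeness.field_fill),
        }
        for key, (path, df) in targets.items():
            df.to_csv(path, index=False, lineterminator="\n")
            written[key] = path
        if eml_xml:
            (out / "eml.xml").write_text(eml_xml, encoding="utf-8")
            written["eml"] = out / "eml.xml"
        (out / "run_log.txt").write_text(run_log.to_text(), encoding="utf-8")
        written["run_log"] = out / "run_log.txt"

    return PipelineResult(
        blocks=blocks, parse_results=parse_results, entries=entries,
        matches=matches, sites=sites, run_log=run_log, events=events,
        occurrences=occurrences, review=review, completeness=completeness,
        eml_xml=eml_xml, written=written)
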