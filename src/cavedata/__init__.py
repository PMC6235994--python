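"""cavedata: rescue toolkit for legacy CAVE sequential vegetation-survey data.

Parses the line-ID-prefixed sequential core files of the historic Australian
vegetation-survey compilation, resolves species alphacodes to current
scientific names through a staged, category-scored matching process, rebuilds
site metadata with decimal coordinates and explicit uncertainty, and emits
Darwin Core event/occurrence tables with EML collection metadata.
"""

from importlib import resources

__version__ = "0.1.0"

from .cave_format import (  # noqa: F401
    LocationBlock, CommunityRecord, SpeciesCode, RawLine, LineKind,
    classify_line, tokenize_species_line, parse_cave_stream, read_cave_file,
    write_canonical,
)
from .taxonomy import (  # noqa: F401
    ConversionEntry, ReferenceTaxon, Checklist, MatchResult, MatchThresholds,
    parse_conversion_file, load_checklist, bigram_similarity, resolve_name,
    resolve_codes, export_review_list,
)
from .geospatial import (  # noqa: F401
    GeoPoint, dms_to_decimal, estimate_uncertainty,
)
from .assembly import (  # noqa: F401
    Publication, MasterSiteRow, parse_publications, select_primary_reference,
    build_master_sites, master_sites_to_frame,
)
from .dwc_export import (  # noqa: F401
    DwcConfig, emit_dwc, emit_eml, completeness_report,
)
from .fixtures import FixtureSpec, generate  # noqa: F401
from .pipeline import run_pipeline  # noqa: F401


def example_core_path():
    """Path to the bundled worked-example core-data file."""
    return resources.files("cavedata") / "data" / "example_core.txt"
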