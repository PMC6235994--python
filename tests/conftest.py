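import pandas as pd
import pytest

import cavedata as cd
from cavedata.fixtures import FixtureSpec, generate
from cavedata.taxonomy import Checklist, ReferenceTaxon


@pytest.fixture(scope="session")
def example_result():
    """Parsed worked example bundled with the package."""
    return cd.read_cave_file(cd.example_core_path(), formation="wetlands")


@pytest.fixture(scope="session")
def example_blocks(example_result):
    return example_result.blocks


@pytest.fixture(scope="session")
def small_checklist():
    taxa = [
        ReferenceTaxon("Acacia paradoxa", "accepted", "Acacia paradoxa"),
        ReferenceTaxon("Acacia armata", "synonym", "Acacia paradoxa"),
        ReferenceTaxon("Acacia oshanesii", "accepted", "Acacia oshanesii"),
        ReferenceTaxon("Acacia oshanessii", "orth_var", "Acacia oshanesii"),
        ReferenceTaxon("Eragrostis cilianensis", "accepted", "Eragrostis cilianensis"),
        ReferenceTaxon("Eragrostis ciliolata", "accepted", "Eragrostis ciliolata"),
        ReferenceTaxon("Eriachne ciliata", "accepted", "Eriachne ciliata"),
        ReferenceTaxon("Carpobrotus modestus", "accepted", "Carpobrotus modestus"),
        ReferenceTaxon("Carpobrotus aequilaterus", "misapplied", "Carpobrotus modestus"),
        ReferenceTaxon("Gahnia", "accepted", "Gahnia", rank="genus"),
        ReferenceTaxon("Acacia", "accepted", "Acacia", rank="genus"),
        ReferenceTaxon("Zygophyllum aurantiacum", "accepted", "Zygophyllum aurantiacum"),
    ]
    return Checklist(taxa)


@pytest.fixture(scope="session")
def publications_frame():
    return pd.DataFrame([
        {"ID": "1", "Author(s)": "Abbott, J.", "Date": "1977",
         "Title": "Species richness on islands.", "Journal": "Aust. J. Bot.",
         "Volume": "25", "Pages": "193-208"},
        {"ID": "8", "Author(s)": "Adams, L. D. & Craven, L. A.", "Date": "1976",
         "Title": "Checklist of vascular plants.", "Journal": "Tech. Mem.",
         "Volume": "76/16", "Pages": ""},
        {"ID": "387", "Author(s)": "McMahon, A.R.G., Carr, G.W.", "Date": "1990",
         "Title": "Conservation status of plant communities.", "Journal": "",
         "Volume": "", "Pages": ""},
        {"ID": "560", "Author(s)": "Tate, R.", "Date": "1880",
         "Title": "Geological and botanical features.", "Journal": "Trans. R. Soc.",
         "Volume": "13", "Pages": "112-120"},
        {"ID": "600", "Author(s)": "Pidgeon, I.", "Date": "1940",
         "Title": "The ecology of the central coast.", "Journal": "Proc. Linn. Soc.",
         "Volume": "65", "Pages": "221-249"},
        {"ID": "601", "Author(s)": "Maconochie, J.", "Date": "1973",
         "Title": "Desert vegetation survey.", "Journal": "Tech. Bull.",
         "Volume": "3", "Pages": "1-20"},
    ])


@pytest.fixture(scope="session")
def clean_fixture_set(tmp_path_factory):
    """Corruption-free synthetic dataset (all rates zero)."""
    spec = FixtureSpec(seed=11, n_locations=6)
    return generate(spec, tmp_path_factory.mktemp("fx_clean"))


@pytest.fixture(scope="session")
def corrupted_fixture_set(tmp_path_factory):
    """Dataset with typos, registered variants and synonyms injected."""
    spec = FixtureSpec(seed=12, n_locations=6, typo_rate=0.15,
                       orthvar_rate=0.15, synonym_rate=0.15)
    return generate(spec, tmp_path_factory.mktemp("fx_corrupt"))
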