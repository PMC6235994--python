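# cavedata

A rescue toolkit for legacy **CAVE** (Classification of Australian
VEgetation) sequential survey files: it parses the historic line-ID-prefixed
plain-text format, resolves obsolete species alphacodes and names against a
reference checklist, rebuilds site metadata with decimal coordinates and an
explicit uncertainty, and emits standards-compliant **Darwin Core**
event/occurrence tables with **EML** collection metadata.

It is written for biodiversity-informatics practitioners digitising
decades-old vegetation surveys: data managers mobilising plot data to GBIF/ALA
style aggregators, and ecologists who need the species lists of historic
community surveys in a modern, analysable form.

## The data model and the matching statistic

A CAVE core file is a sequence of records, each opened by a six-digit line ID
whose leading control digit declares its role:

```
800000  state/territory code (N, P, Q, ...)
5xxx00  location header: code, name, source citation
9xxxbb  latitude/longitude as four integers (deg min deg min)
5xxxbb  community number bb at location xxx, with description
3xxxbb  additional comment (often dominant-species codes)
0xxxbb  species list: 8-9 character alphacodes, '#'-terminated
500000  end of the location block
```

Species are 8–9 character alphacodes (`EUCAROBU`, `GAHNIA__*`); `_` pads short
genus names, a trailing `*` marks a genus-level record, and the ninth character
is reserved for infraspecific taxa. Per-formation *conversion files* map each
alphacode to its name as published (plus, where known, an updated name) with
packed validity/growth-habit/stage flags.

Name reconciliation is staged and category-scored. An exact hit — including
registered orthographic variants and synonyms chained to their accepted
name — is a `MATCH`; anchored substring matches give `PARTIAL_L`/`PARTIAL_R`;
otherwise the best **letter-pair similarity** over the checklist decides
between `FUZZY`, `WEAK` and `TAXM` (refer to expert). The similarity is the
Dice coefficient on bigram multisets taken word-by-word,

    S(a, b) = 2 |pairs(a) ∩ pairs(b)| / (|pairs(a)| + |pairs(b)|),

so e.g. S(`NIGHT`, `NACHT`) = 2·1/(4+4) = 0.25. Every category except
`MATCH` is flagged for manual review and exported on a worst-first review
list that re-imports as an override table.

Coordinates convert with fixed southern/eastern signs, and each point carries
`coordinateUncertaintyInMeters` computed as the half-diagonal of the
one-arc-minute resolution cell on a sphere: `h·k·sqrt(1 + cos²(lat))` with
`h` the half-resolution in radians and `k` = 6 371 000 m (≈1205 m at 33.85° S).

## Worked example

The package ships a small core-data sample (`cavedata.example_core_path()`),
and the `fixtures` command fabricates complete synthetic datasets (core files,
conversion files, publications, checklist) with a ground-truth table:

```console
$ cave fixtures --seed 1 --out fx
6 blocks, 17 communities, 180 codes -> fx

$ cave parse fx/core_sclerophyll_shrublands.txt \
      --formation sclerophyll_shrublands --out blocks.jsonl
3 blocks, 9 communities, 97 species codes -> blocks.jsonl

$ cave resolve --conversion fx/conversion_sclerophyll_shrublands.csv \
      --checklist fx/checklist.csv --review review.csv
73 codes resolved (MATCH=73); 0 need review -> review.csv

$ cave export \
      --core sclerophyll_shrublands=fx/core_sclerophyll_shrublands.txt \
      --core arid_woodlands=fx/core_arid_woodlands.txt \
      --conversion sclerophyll_shrublands=fx/conversion_sclerophyll_shrublands.csv \
      --conversion arid_woodlands=fx/conversion_arid_woodlands.csv \
      --pubs fx/publications.csv --checklist fx/checklist.csv --out dwc
17 events, 180 occurrences, 0 names for review -> dwc
```

The numbers mean: the two synthetic formation files hold 6 location blocks
with 17 plot communities and 180 species-code records in total; on this
corruption-free dataset every alphacode resolves `MATCH`, so the review list
is empty; the export writes one Darwin Core event per community (17) and one
occurrence per species record (180), e.g.

```
occurrenceID,eventID,basisOfRecord,scientificName,taxonRank,...
arid_woodlands:P002:01:0001,arid_woodlands:P002:01,HumanObservation,Westzieella saula,species,...
```

plus `sites.csv` (the master site table), `eml.xml` (collection metadata with
a computed bounding box), `completeness.csv` and `run_log.txt` (every
duplicate, unresolved citation and quarantined line, with provenance).

The same stages are available as a library — `read_cave_file`,
`resolve_codes`, `build_master_sites`, `emit_dwc`, `emit_eml`, or the
one-call `run_pipeline`.

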