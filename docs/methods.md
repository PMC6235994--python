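# Methods

This note documents the models, heuristics and numeric choices behind the
toolkit, module by module, in the order data flows through the pipeline.

## The sequential core format and its parser

The legacy format is positional, not field-based: the first character of each
six-digit line ID is a control digit declaring the record class, the next
three digits are the zero-padded location number, and the last two the
community number (`503201` = class 5, location 032, community 01; `800000`
and `500000` are the state and end-of-block sentinels). The parser classifies
by control digit rather than by two-character prefix so that location numbers
of 100–999 classify identically to the two-digit ones that dominate the
surviving material.

**Error policy.** The parser never silently drops input. Every non-blank line
is either attached to a block or *quarantined* with its line number and a
reason (`NON_NUMERIC_ID`, `UNKNOWN_LINE_ID`, `NON_ASCII`, `ORPHAN_LINE`,
`MALFORMED_LATLON`, `EMPTY_SPECIES_LINE`, `STRAY_END`), so that
`attached + quarantined = total` holds exactly — this conservation identity
is asserted in the tests on adversarially corrupted inputs. Anomalies of
otherwise-keepable blocks (missing coordinate line, unterminated block,
mismatched community IDs, out-of-range minutes) are recorded as *issues* on
the parse result instead of quarantining, because discarding a recoverable
block would trade a flag for a gap.

**Encoding.** The legacy data is ASCII. Files are decoded through latin-1
(lossless byte-to-char) and any line containing a non-ASCII character is
quarantined rather than guessed at; no charset detection is attempted.

**Tokenizer heuristics.** Species payloads are whitespace-split after
removing the trailing `#`. Two printed pathologies require heuristics, both
logged when applied:

* *Fused chunks* (`GOODENIA*GOMPCONI`): a chunk longer than nine characters
  is split greedily — cut after an asterisk within the first nine characters,
  else after eight, repeating. The asterisk-trails-its-code convention makes
  this unambiguous for every observed form.
* *Displaced genus markers* (`POLYGALA *PORTFILI`): a chunk with a lone
  leading asterisk transfers the genus marker to the *preceding* token;
  everywhere else the marker trails a (possibly `_`-padded) genus code.

Digits inside codes (`BRUNAUS2`) and a `/` ninth character (`BORRCARP/`) are
preserved verbatim; the ninth character, where present, is carried as the
infraspecific marker. Comment (`3xxxbb`) lines are stored verbatim and
additionally tokenized when they parse cleanly as codes, since they usually
carry dominant species.

**Canonical writer.** `write_canonical` re-emits the same grammar normalized:
at most eight codes per species line, single-space separated, `#`-terminated,
genus markers re-attached as trailing asterisks. One application of
parse-write-parse is a fixed point on block *structure* (provenance line
numbers necessarily change); this is property-tested with random blocks.

Duplicate blocks across formation files are retained at parse time by design;
deduplication is an assembly-stage decision (below).

## Name resolution

The conversion file's packed 1–3 character flag field is read positionally:
validity (L legal / S synonym / M misspelling), growth habit (a 19-letter
eco-morphological vocabulary), stage code (historically `G`). Unknown flag
characters are kept verbatim with a warning; stage codes other than `G` are
stored uninterpreted. Alphacodes must be unique within a formation (the
historical guarantee), and only there.

The resolution query is the updated name when the original compiler recorded
one, else the name as published; both are kept in the evidence trail.
Genus-level codes are resolved against the genus-rank slice of the checklist.
Stages:

1. **Override** — a reviewer-supplied `query → accepted name` table wins
   outright (this is how the review loop closes).
2. **Exact** — case-insensitive hit; synonyms and registered orthographic
   variants chain to their accepted name. Category `MATCH`, score 1. A hit
   on a *misapplied* name never auto-accepts (misapplication is precisely
   the case where the letters are right and the taxon is wrong); it is
   recorded in evidence and resolution falls through.
3. **Anchored substring** — the query is a leading (or trailing) substring
   of exactly one candidate, or vice versa, with length ratio ≥
   `partial_min`. Category `PARTIAL_L`/`PARTIAL_R`, scored by the length
   ratio (no other score is defined for a substring match; the ratio is 1
   only for equality, which stage 2 already consumed). Ambiguous anchored
   matches defer to stage 4.
4. **Letter-pair similarity** — Dice coefficient on the multisets of
   adjacent letter pairs taken within words (pairs never span a word
   boundary; single-letter words contribute none), after case-folding and
   whitespace collapsing. Best score `s` ≥ `fuzzy_min` → `FUZZY`;
   `weak_min` ≤ `s` < `fuzzy_min` → `WEAK` with the best match retained;
   below `weak_min` → `TAXM` with no best name. A score of exactly 1
   (identical pair multisets) upgrades to `MATCH` unless it ties across
   distinct accepted names or lands only on a misapplied name, in which
   case the result is forced to review with the score capped just below 1 —
   the invariant *score = 1 ⇒ MATCH* is preserved.

Ties break deterministically: higher score, then membership in an optional
user-supplied regional name list (the desk-study stand-in for restricting
candidates to a park or reserve species list), then accepted status over
synonym, then lexicographic order. A tie between distinct accepted names —
the signature of an unresolvable taxonomic split — is never auto-accepted.
Results are independent of checklist iteration order (tested against a
reversed checklist).

**Thresholds.** The historical workflow left its numeric thresholds
unstated, so the defaults here are the package's own: `fuzzy_min = 0.75`,
`weak_min = 0.50`, `partial_min = 0.60`, candidate-reporting window
`epsilon = 0.02`, top-5 candidates always reported. They are deliberately
conservative — a borderline case should cost a reviewer a glance rather
than silently enter the record — and all are configurable. Raising
`fuzzy_min` can only demote FUZZY toward WEAK, never the reverse
(monotonicity is tested). `needs_review` is true for exactly the non-MATCH
categories.

The review list is sorted TAXM-first then ascending score, and re-imports as
the stage-1 override table once an accepted name is filled in.

## Coordinates and uncertainty

Verbatim positions are four non-negative integers (degrees/minutes, printed
to the whole minute). All sites are Australian, so hemisphere signs are fixed
(latitude negative, longitude positive) rather than inferred; a coordinate
outside the envelope lat ∈ [−45, −9], lon ∈ [110, 155] warns but does not
fail, matching the manual verification posture of the original compilation.
Verified corrections enter through an override CSV and mark the row amended.

The uncertainty attached to each point is the half-diagonal of the
one-resolution-cell rectangle on a sphere of radius 6 371 000 m:
`u = h·k·sqrt(1 + cos²(lat))`, `h` = half the resolution in radians. At 1′
this gives ≈1310 m at the equator and ≈1205 m at 33.85° S; a configurable
floor (default 100 m) bounds it below. The rule is monotone increasing in
resolution and non-increasing in |latitude|. No datum is recorded in the
sources; coordinates are emitted as WGS84 on the grounds that the ≥1 km
uncertainty absorbs any datum shift. The cell-diagonal rule itself is a
documented choice of this package; nothing in the sources prescribes a
formula.

## Assembly

One master-site row per location × community, with exactly the documented
18-column set. Citations are matched on the parenthetical
`(SURNAME YEAR)` tail of the location header against first-author surname +
year in the publications table; ambiguous matches (two references, same
surname and year) flag rather than guess, unresolved ones keep the row with
an empty reference and a flag. Where several citations were stacked, one
primary reference is selected — override table first, then latest year by
default (the compilation credited the authority whose list was digitized;
`earliest` is available) — the reference date column is populated only in
this multi-citation case, and every non-selected citation is demoted to the
retrieval comments, not dropped.

Duplicates (same location and community from overlapping formation files):
identical species lists collapse to the first copy; nested lists keep the
largest; genuinely conflicting lists are all kept and flagged
`CONFLICTING_DUPLICATE`. Every drop and flag lands in the run log with file
and line provenance.

The site numerical identifier ("line ID number") is the community number
when the site has exactly one community, else the block's first line number —
the historical definition is circular for multi-community sites, and this
implementation choice is flagged here rather than hidden.

## Darwin Core and EML export

Event core: one event per master-site row, `eventID =
formation:location:community`; one occurrence per species code,
`occurrenceID = eventID:NNNN` in source order — IDs are deterministic and
re-running on identical input is byte-identical (fixed column order, sorted
emission, fixed float formatting, JSON `dynamicProperties` with sorted
keys). Constants: `basisOfRecord = HumanObservation`, `country = Australia`,
`kingdom = Plantae`. Only the source-publication year is reliably known, so
temporal information is emitted as `year` with the full citation in
`associatedReferences`.

`scientificName` is the resolved accepted name for every category except
`TAXM`, which keeps the verbatim published name with an
`identificationQualifier` — defective records are flagged, never dropped, so
the occurrence count equals the parsed token count minus explicitly logged
duplicates. Everything without a Darwin Core corollary (formation,
alphacode, flags, match category and score, verbatim and updated names,
source file and lines) travels in `dynamicProperties`. About 30 Darwin Core
terms are emitted; the term set is versioned in `DwcConfig`. Coordinate
redaction to 0.1° is available behind a config flag but off by default —
these data are published literature records.

The EML document computes its coverages from the records (bounding box,
source-year range, distinct-name count) and is checked structurally
(required elements, box ordering, serializability). Validation against the
full external XML schema is not performed. The completeness report follows
the required-field model: per-field fill rates worst-first plus a per-record
score = fraction of required fields present (default 10 fields).

## The synthetic-data generator

The generator emulates the *structure* of the legacy data, not its ecology:
no species-abundance realism is attempted, and the Latin binomials are
synthetic (syllable-built, globally unique), so tests touch no real
taxonomy. Defaults: 6 locations across two formation files, 1–4 communities
each (historical range 1–28 allowed), 6–16 codes per community from a
150-name pool, all corruption rates zero. Corruptions are applied per
conversion entry at configurable rates: unregistered single-character typos
(substitution or adjacent transposition in the epithet, guaranteed distinct
from every registered name), misspellings registered as orthographic
variants, synonym swaps registered in the checklist, plus a 20 % chance that
an uncorrupted entry carries an already-updated name (exercising the
both-names-recorded path). The truth table records every code occurrence
with its intended accepted name, corruption type and expected category —
`MATCH` for none/orth-var/synonym/updated, `NOT_MATCH` for typos (a typo's
exact landing category depends on distance, so only the MATCH boundary is
asserted).

Every dataset contains at least one of each grammar wrinkle (genus `*`
codes, a nine-character code placed clear of the fused positions, a fused
chunk, a displaced leading-`*` chunk, comment lines), so the tokenizer's
heuristics are always exercised. Duplicated blocks are copied verbatim into
the other formation's file with mirrored conversion entries, so they
deduplicate as identical copies. Generation is a pure function of the spec;
the same seed yields byte-identical files.

What passing these tests does *not* show about real data: OCR noise,
non-ASCII contamination beyond single quarantined lines, genuinely ambiguous
taxonomic splits, misapplied-name webs, and hand-edited structural damage
are richer in the wild than any generator; the corrupted-input tests cover
the failure *mechanisms* (quarantine, flags, conservation), not the full
failure distribution.

## Problem sizes

The default test and acceptance runs use 50 two-location datasets for the
round-trip/conservation properties, 10 000 random string pairs for the
similarity oracle, and six-location datasets (~100–180 occurrences) for the
category and end-to-end checks — sizes chosen so the full suite documents
the invariants while remaining quick enough to run on every change.

## Known limitations

* The original letter-pair score was built on top of a web service's own
  match score; the word-wise bigram Dice realization here is the published
  algorithm that name describes, but the historical arithmetic is not
  recoverable and the numeric thresholds are this package's defaults.
* PARTIAL-L/R are interpreted as left/right-*anchored* substring matches;
  the historical definition said only "significant substring match". The
  anchoring interpretation is recorded in each result's evidence.
* No live taxonomic web services are consulted; the checklist is a local
  table, and nomenclatural authority strings are not parsed.
* The master-site collator notes are carried as opaque keywords; the manual
  that defined them is unavailable.
* No Darwin Core Archive packaging (zip + meta.xml) beyond the two CSVs and
  the EML document.
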