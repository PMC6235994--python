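"""Alphacode-to-name conversion and taxonomic name reconciliation.

Two inputs drive this module: the per-formation *species conversion file*
(alphacode, validity/growth-habit/stage flags, name as published, and the
updated name where the original compiler recorded one) and a local *reference
checklist* (name, status, accepted name, rank) standing in for a national
species-list service.

Name reconciliation is staged.  An exact (case-insensitive) hit -- including
hits on registered orthographic variants and synonyms, which chain to their
accepted name -- is a ``MATCH`` and needs no review.  Failing that, a
significant left- or right-anchored substring match yields ``PARTIAL_L`` /
``PARTIAL_R``; otherwise the best letter-pair (bigram Dice) similarity over
the checklist decides between ``FUZZY``, ``WEAK`` (best match retained below
the fuzzy threshold) and ``TAXM`` (no acceptable match; refer to an expert).
Every category except ``MATCH`` is flagged for manual review.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "VALIDITY_FLAGS",
    "GROWTH_HABIT_FLAGS",
    "ConversionEntry",
    "ReferenceTaxon",
    "Checklist",
    "MatchThresholds",
    "MatchResult",
    "DuplicateCodeError",
    "parse_conversion_file",
    "load_checklist",
    "bigram_similarity",
    "resolve_name",
    "resolve_codes",
    "export_review_list",
    "load_overrides",
]

#: Validity flags: L = legal (valid) taxon, S = synonym, M = misspelling.
VALIDITY_FLAGS = frozenset("LSM")

#: Growth-habit flags (eco-morphological classes): A aquatic, B semi-aquatic,
#: C creeper, D dwarf sclerophyllous shrub, E epiphyte, F fern, G graminoid,
#: H hummock grass, I invasive, K non-sclerophyll shrub, L low tree,
#: M medium tree, P parasite, S shrub >2 m, U geophyte, V vine,
#: W dwarf non-sclerophyllous shrub, Y evergreen, Z sclerophyllous shrub.
GROWTH_HABIT_FLAGS = frozenset("ABCDEFGHIKLMPSUVWYZ")


class DuplicateCodeError(ValueError):
    """An alphacode occurs twice within one formation's conversion file."""

    code = "DUPLICATE_CODE_IN_FORMATION"


@dataclass
class ConversionEntry:
    row_number: int
    validity_flag: str  # "L", "S", "M" or ""
    growth_habit_flag: str
    stage_code: str  # the general-purpose stage-of-analysis code, usually "G"
    alphacode: str
    published_name: str
    updated_name: Optional[str] = None
    formation: str = ""

    @property
    def query_name(self) -> str:
        """Name used for resolution: updated when present, else published."""
        return self.updated_name or self.published_name

    @property
    def genus_level(self) -> bool:
        return self.alphacode.endswith("*") or len(self.query_name.split()) == 1


@dataclass(frozen=True)
class ReferenceTaxon:
    name: str
    status: str  # accepted | synonym | orth_var | misapplied
    accepted_name: str
    rank: str = "species"  # species | genus | infraspecific
    taxon_id: str = ""


class Checklist:
    """A reference checklist with a case-folded exact-lookup index."""

    def __init__(self, taxa: Iterable[ReferenceTaxon]):
        self.taxa: list[ReferenceTaxon] = sorted(
            taxa, key=lambda t: (t.name.casefold(), t.status))
        self._index: dict[str, list[ReferenceTaxon]] = {}
        accepted = {t.name for t in self.taxa if t.status == "accepted"}
        for t in self.taxa:
            self._index.setdefault(_fold(t.name), []).append(t)
            if t.status == "accepted" and t.accepted_name != t.name:
                warnings.warn(f"accepted taxon {t.name!r} with accepted_name "
                              f"{t.accepted_name!r}", stacklevel=2)
            if t.status in ("synonym", "orth_var") and t.accepted_name not in accepted:
                warnings.warn(f"{t.status} {t.name!r} points to {t.accepted_name!r} "
                              "which is not an accepted entry", stacklevel=2)

    def __len__(self) -> int:
        return len(self.taxa)

    def lookup(self, name: str) -> list[ReferenceTaxon]:
        return self._index.get(_fold(name), [])

    def at_rank(self, rank: Optional[str]) -> list[ReferenceTaxon]:
        if rank is None:
            return self.taxa
        return [t for t in self.taxa if t.rank == rank]


@dataclass(frozen=True)
class MatchThresholds:
    """Decision thresholds for the staged matcher.

    The legacy workflow left its numeric thresholds unstated; these defaults
    are deliberately conservative so that borderline cases are routed to
    manual review rather than silently accepted.
    """

    fuzzy_min: float = 0.75
    weak_min: float = 0.50
    partial_min: float = 0.60
    epsilon: float = 0.02  # candidates within epsilon of the best are reported
    max_candidates: int = 5


CATEGORIES = ("MATCH", "PARTIAL_L", "PARTIAL_R", "FUZZY", "WEAK", "TAXM")


@dataclass
class MatchResult:
    query: str
    best_name: Optional[str]
    category: str
    score: float
    candidates: list[tuple[str, float]] = field(default_factory=list)
    evidence: str = ""

    @property
    def needs_review(self) -> bool:
        return self.category != "MATCH"


def _fold(s: str) -> str:
    return " ".join(s.split()).casefold()


# ---------------------------------------------------------------------------
# Conversion files

_CONVERSION_ALIASES = {
    "row_number": {"row_number", "row", "id", "sequential row number"},
    "flags": {"flags", "flag", "validity and growth habit flag"},
    "alphacode": {"alphacode", "species code", "code"},
    "published_name": {"published_name", "scientific name (in publication)",
                       "scientific name", "published name"},
    "updated_name": {"updated_name", "updated name", "new scientific name",
                     "new scientific name (at time of original entry)"},
}


def _resolve_columns(df: pd.DataFrame, aliases: Mapping[str, set]) -> dict[str, str]:
    mapping = {}
    lowered = {str(c).strip().casefold(): c for c in df.columns}
    for canonical, names in aliases.items():
        for alias in names:
            if alias in lowered:
                mapping[canonical] = lowered[alias]
                break
    return mapping


def parse_conversion_file(
    source: Union[str, Path, pd.DataFrame],
    formation: str = "",
) -> list[ConversionEntry]:
    """Read one formation's species conversion file.

    The flag column is a packed 1-3 character field read positionally:
    validity, growth habit, stage -- so ``"L G"`` unpacks to validity ``L``,
    habit blank, stage ``G`` and ``"SZG"`` to ``S``, ``Z``, ``G``.  Alphacodes
    must be unique within a formation (they are guaranteed unique only there);
    a repeat raises :class:`DuplicateCodeError`.  Characters outside the flag
    vocabularies are kept verbatim with a warning.
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = pd.read_csv(source, dtype=str, keep_default_na=False,
                         skipinitialspace=False)
    cols = _resolve_columns(df, _CONVERSION_ALIASES)
    missing = {"flags", "alphacode", "published_name"} - set(cols)
    if missing:
        raise ValueError(f"conversion file missing columns: {sorted(missing)}")

    entries: list[ConversionEntry] = []
    seen: dict[str, int] = {}
    for i, row in enumerate(df.itertuples(index=False), start=1):
        rec = dict(zip(df.columns, row))
        packed = str(rec[cols["flags"]] or "")
        padded = packed.ljust(3)
        validity, habit, stage = padded[0], padded[1], padded[2]
        validity = "" if validity == " " else validity
        habit = "" if habit == " " else habit
        stage = "" if stage == " " else stage
        if validity and validity not in VALIDITY_FLAGS:
            warnings.warn(f"UNKNOWN_FLAG: validity {validity!r} in row {i}",
                          stacklevel=2)
        if habit and habit not in GROWTH_HABIT_FLAGS:
            warnings.warn(f"UNKNOWN_FLAG: growth habit {habit!r} in row {i}",
                          stacklevel=2)
        code = str(rec[cols["alphacode"]]).strip()
        if code in seen:
            raise DuplicateCodeError(
                f"alphacode {code!r} repeated in formation {formation!r} "
                f"(rows {seen[code]} and {i})")
        seen[code] = i
        updated = str(rec.get(cols.get("updated_name", ""), "") or "").strip()
        row_number = i
        if "row_number" in cols:
            raw = str(rec[cols["row_number"]]).strip()
            if raw.isdigit():
                row_number = int(raw)
        entries.append(ConversionEntry(
            row_number=row_number, validity_flag=validity,
            growth_habit_flag=habit, stage_code=stage, alphacode=code,
            published_name=str(rec[cols["published_name"]]).strip(),
            updated_name=updated or None, formation=formation))
    return entries


def load_checklist(source: Union[str, Path, pd.DataFrame]) -> Checklist:
    """Load a reference checklist CSV (name, status, accepted_name, rank, taxon_id)."""
    if isinstance(source, pd.DataFrame):
        df = source
    else:
        df = pd.read_csv(source, dtype=str, keep_default_na=False)
    taxa = [
        ReferenceTaxon(
            name=str(r["name"]).strip(),
            status=str(r.get("status", "accepted")).strip() or "accepted",
            accepted_name=str(r.get("accepted_name", "") or r["name"]).strip()
            or str(r["name"]).strip(),
            rank=str(r.get("rank", "species")).strip() or "species",
            taxon_id=str(r.get("taxon_id", "")).strip(),
        )
        for r in df.to_dict("records")
    ]
    return Checklist(taxa)


# ---------------------------------------------------------------------------
# Letter-pair (bigram Dice) similarity

def _letter_pairs(s: str) -> Counter:
    """Multiset of adjacent letter pairs, gathered word by word.

    Pairs never span a word boundary; single-letter words contribute none.
    """
    pairs: Counter = Counter()
    for word in s.split():
        for i in range(len(word) - 1):
            pairs[word[i : i + 2]] += 1
    return pairs


def bigram_similarity(a: str, b: str) -> float:
    """Letter-pair similarity: Dice coefficient on bigram multisets.

    ``2 * |pairs(a) & pairs(b)| / (|pairs(a)| + |pairs(b)|)`` with pairs taken
    within words after case-folding and whitespace collapsing.  Symmetric,
    bounded in [0, 1]; 1 exactly when the two names have identical pair
    multisets.  Defined as 0 when neither string contributes any pair.
    """
    pa = _letter_pairs(_fold(a))
    pb = _letter_pairs(_fold(b))
    total = sum(pa.values()) + sum(pb.values())
    if total == 0:
        return 0.0
    shared = sum((pa & pb).values())
    return 2.0 * shared / total


# ---------------------------------------------------------------------------
# Staged resolution

_STATUS_RANK = {"accepted": 0, "synonym": 1, "orth_var": 2, "misapplied": 3}


def _accepted_of(taxon: ReferenceTaxon) -> str:
    return taxon.accepted_name or taxon.name


def resolve_name(
    query: str,
    checklist: Checklist,
    thresholds: Optional[MatchThresholds] = None,
    rank: Optional[str] = None,
    overrides: Optional[Mapping[str, str]] = None,
    region_names: Optional[set] = None,
) -> MatchResult:
    """Resolve one scientific name against the checklist.

    Stages: (0) expert override table; (1) exact case-insensitive hit,
    chaining synonyms and orthographic variants to their accepted name;
    (2) anchored substring match (``PARTIAL_L`` leading / ``PARTIAL_R``
    trailing, scored by length ratio); (3) best letter-pair similarity
    (``FUZZY`` / ``WEAK`` / ``TAXM`` by threshold).  Ties are broken by
    higher score, presence in the optional regional name list, accepted
    status over synonym, then lexicographically; a tie between distinct
    accepted names is never auto-accepted.

    Genus-level queries pass ``rank="genus"`` to restrict the candidate pool.
    """
    th = thresholds or MatchThresholds()
    evidence: list[str] = []
    q = " ".join(query.split())

    if overrides:
        folded = {_fold(k): v for k, v in overrides.items()}
        if _fold(q) in folded:
            name = folded[_fold(q)]
            return MatchResult(query=q, best_name=name, category="MATCH", score=1.0,
                               candidates=[(name, 1.0)],
                               evidence="expert override applied")

    pool = checklist.at_rank(rank)
    if not pool:
        note = "EMPTY_CHECKLIST: no reference taxa" + (f" at rank {rank}" if rank else "")
        return MatchResult(query=q, best_name=None, category="TAXM", score=0.0,
                           candidates=[], evidence=note)

    # Stage 1: exact hit (accepted / synonym / orth_var chain to accepted)
    rank_names = None if rank is None else {t.name for t in pool}
    hits = [t for t in checklist.lookup(q)
            if rank_names is None or t.name in rank_names]
    resolvable = [t for t in hits if t.status in ("accepted", "synonym", "orth_var")]
    if resolvable:
        accepted = sorted({_accepted_of(t) for t in resolvable})
        if len(accepted) == 1:
            via = sorted({t.status for t in resolvable})
            evidence.append(f"exact hit via {'/'.join(via)}")
            return MatchResult(query=q, best_name=accepted[0], category="MATCH",
                               score=1.0, candidates=[(accepted[0], 1.0)],
                               evidence="; ".join(evidence))
        evidence.append(f"ambiguous exact hit: {len(accepted)} accepted names "
                        f"{accepted}; forced review, score capped")
        cands = [(a, 1.0) for a in accepted]
        return MatchResult(query=q, best_name=accepted[0], category="FUZZY",
                           score=0.999, candidates=cands,
                           evidence="; ".join(evidence))
    misapplied = [t for t in hits if t.status == "misapplied"]
    if misapplied:
        evidence.append("exact hit on misapplied name "
                        f"(-> {sorted({_accepted_of(t) for t in misapplied})}); "
                        "needs review, falling through to similarity stages")

    # Stage 2: anchored substring match (left / right), length ratio scored
    names = sorted({t.name for t in pool})
    qf = _fold(q)

    def _ratio(n: str) -> float:
        nf = _fold(n)
        return min(len(qf), len(nf)) / max(len(qf), len(nf))

    for anchor, category in (("left", "PARTIAL_L"), ("right", "PARTIAL_R")):
        if anchor == "left":
            cands = [n for n in names
                     if (n.casefold().startswith(qf) or qf.startswith(_fold(n)))
                     and _fold(n) != qf and _ratio(n) >= th.partial_min]
        else:
            cands = [n for n in names
                     if (n.casefold().endswith(qf) or qf.endswith(_fold(n)))
                     and _fold(n) != qf and _ratio(n) >= th.partial_min]
        if len(cands) == 1:
            name = cands[0]
            best = _chain(name, checklist)
            score = _ratio(name)
            evidence.append(f"{anchor}-anchored substring match on {name!r} "
                            f"(length ratio {score:.3f})")
            return MatchResult(query=q, best_name=best, category=category,
                               score=round(score, 6), candidates=[(name, round(score, 6))],
                               evidence="; ".join(evidence))
        if len(cands) > 1:
            evidence.append(f"{anchor}-anchored substring ambiguous over "
                            f"{len(cands)} names; deferred to similarity")

    # Stage 3: letter-pair similarity over the pool
    by_name: dict[str, ReferenceTaxon] = {}
    for t in sorted(pool, key=lambda t: (_STATUS_RANK.get(t.status, 9),
                                         t.name.casefold())):
        by_name.setdefault(t.name, t)
    scored = []
    for name, taxon in by_name.items():
        s = bigram_similarity(q, name)
        in_region = bool(region_names) and name in region_names
        scored.append((-s, not in_region, _STATUS_RANK.get(taxon.status, 9),
                       name.casefold(), name, s, taxon))
    scored.sort()
    best_s = scored[0][5]
    top = [row for row in scored if row[5] >= best_s - 1e-12]

    ranked = [(row[4], round(row[5], 6)) for row in scored]
    keep = max(th.max_candidates,
               sum(1 for row in scored if row[5] >= best_s - th.epsilon))
    candidates = ranked[:keep]

    best_accepted = sorted({_accepted_of(row[6]) for row in top})
    if best_s >= 1.0 - 1e-12:
        # a misapplied name never auto-accepts, even at score 1
        clean = sorted({_accepted_of(row[6]) for row in top
                        if row[6].status != "misapplied"})
        if len(clean) == 0:
            evidence.append("score-1 hit only on misapplied name; forced "
                            "review, score capped")
            return MatchResult(query=q, best_name=best_accepted[0],
                               category="FUZZY", score=0.999,
                               candidates=candidates,
                               evidence="; ".join(evidence))
        best_accepted = clean
        if len(best_accepted) == 1:
            evidence.append("identical letter-pair multiset (score 1)")
            return MatchResult(query=q, best_name=best_accepted[0], category="MATCH",
                               score=1.0, candidates=candidates,
                               evidence="; ".join(evidence))
        evidence.append(f"score-1 tie across accepted names {best_accepted}; "
                        "forced review, score capped")
        return MatchResult(query=q, best_name=best_accepted[0], category="FUZZY",
                           score=0.999, candidates=candidates,
                           evidence="; ".join(evidence))

    best_name = _accepted_of(scored[0][6])
    if len(best_accepted) > 1:
        evidence.append(f"tie at score {best_s:.3f} across accepted names "
                        f"{best_accepted}; forced review")
    if best_s >= th.fuzzy_min:
        category = "FUZZY"
        evidence.append(f"letter-pair similarity {best_s:.3f} >= fuzzy_min "
                        f"{th.fuzzy_min}")
    elif best_s >= th.weak_min:
        category = "WEAK"
        evidence.append(f"letter-pair similarity {best_s:.3f} in "
                        f"[{th.weak_min}, {th.fuzzy_min}); best match retained")
    else:
        evidence.append(f"letter-pair similarity {best_s:.3f} < weak_min "
                        f"{th.weak_min}; no acceptable match")
        return MatchResult(query=q, best_name=None, category="TAXM",
                           score=round(best_s, 6), candidates=candidates,
                           evidence="; ".join(evidence))
    return MatchResult(query=q, best_name=best_name, category=category,
                       score=round(best_s, 6), candidates=candidates,
                       evidence="; ".join(evidence))


def _chain(name: str, checklist: Checklist) -> str:
    for t in checklist.lookup(name):
        if t.status in ("accepted", "synonym", "orth_var"):
            return _accepted_of(t)
    return name


def resolve_codes(
    entries: Sequence[ConversionEntry],
    checklist: Checklist,
    thresholds: Optional[MatchThresholds] = None,
    overrides: Optional[Mapping[str, str]] = None,
    region_names: Optional[set] = None,
) -> dict[str, MatchResult]:
    """Resolve every conversion entry's name; returns alphacode -> result.

    The query is the updated name when the original compiler recorded one,
    else the name as published; both are kept in the evidence trail so no
    fidelity to the original record is lost.  Genus-level codes are resolved
    at genus rank.  Results are cached per distinct (query, rank).
    """
    cache: dict[tuple[str, Optional[str]], MatchResult] = {}
    results: dict[str, MatchResult] = {}
    for entry in entries:
        query = entry.query_name
        rank = "genus" if entry.genus_level else None
        key = (_fold(query), rank)
        if key not in cache:
            cache[key] = resolve_name(query, checklist, thresholds=thresholds,
                                      rank=rank, overrides=overrides,
                                      region_names=region_names)
        base = cache[key]
        trail = (f"alphacode={entry.alphacode}; published={entry.published_name!r}; "
                 f"updated={entry.updated_name!r}")
        results[entry.alphacode] = replace(
            base, evidence=(base.evidence + "; " if base.evidence else "") + trail)
    return results


def export_review_list(results: Mapping[str, MatchResult]) -> pd.DataFrame:
    """Tabulate every result that needs manual review, worst first.

    ``TAXM`` rows come first, then ascending score, so the expert sees the
    hardest cases at the top.  The table re-imports as an override file once
    an ``accepted_name`` column is filled in.
    """
    rows = []
    for code in sorted(results):
        r = results[code]
        if not r.needs_review:
            continue
        rows.append({
            "alphacode": code,
            "query": r.query,
            "category": r.category,
            "score": r.score,
            "best_name": r.best_name or "",
            "candidates": " | ".join(f"{n} ({s:.3f})" for n, s in r.candidates),
            "evidence": r.evidence,
            "accepted_name": "",  # to be filled by the reviewer
        })
    df = pd.DataFrame(rows, columns=["alphacode", "query", "category", "score",
                                     "best_name", "candidates", "evidence",
                                     "accepted_name"])
    if df.empty:
        return df
    df["_taxm"] = (df["category"] != "TAXM").astype(int)
    df = df.sort_values(["_taxm", "score", "alphacode"]).drop(columns="_taxm")
    return df.reset_index(drop=True)


def load_overrides(source: Union[str, Path, pd.DataFrame]) -> dict[str, str]:
    """Read reviewer overrides: columns ``query`` and ``accepted_name``."""
    if isinstance(source, pd.DataFrame):
        df = source
    else:
        df = pd.read_csv(source, dtype=str, keep_default_na=False)
    out = {}
    for r in df.to_dict("records"):
        query = str(r.get("query", "")).strip()
        accepted = str(r.get("accepted_name", "")).strip()
        if query and accepted:
            out[query] = accepted
    return out
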