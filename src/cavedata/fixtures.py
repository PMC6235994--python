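"""Synthetic CAVE datasets with ground truth, for end-to-end testing.

Every pipeline stage needs realistic inputs without any download: this
module fabricates a coherent set of core files (one per formation),
per-formation species conversion files, a publications table and a reference
checklist, together with a *truth table* recording every emitted code, its
intended accepted name, any injected corruption and the match category it
should receive under default thresholds.

The species names are synthetic Latin binomials built from syllables -- no
real taxa are used, so no external checklist is ever required.  Generation
is a pure function of the :class:`FixtureSpec`: the same seed yields
byte-identical files.  Each generated dataset always exercises every parsing
wrinkle of the legacy grammar at least once: genus-level ``*`` codes, a
nine-character code, ``#`` terminators, a fused chunk (``CODEA*CODEB``), a
displaced leading-``*`` chunk, comment lines, and (when requested)
duplicated blocks and missing coordinate lines.

Structure, not ecology, is simulated: community composition carries no
species-abundance realism.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import pandas as pd

__all__ = [
    "FixtureSpec",
    "FixtureSet",
    "InvalidSpecError",
    "generate",
    "corrupt_name",
]


class InvalidSpecError(ValueError):
    code = "INVALID_SPEC"


@dataclass(frozen=True)
class FixtureSpec:
    seed: int = 0
    n_locations: int = 6
    communities_per_location: tuple = (1, 4)  # inclusive range, within 1-28
    species_pool_size: int = 150
    codes_per_community: tuple = (6, 16)  # inclusive range
    typo_rate: float = 0.0  # unregistered single-character corruption
    synonym_rate: float = 0.0  # published name replaced by a registered synonym
    orthvar_rate: float = 0.0  # misspelling registered as an orth. var.
    duplicate_block_rate: float = 0.0  # block copied into a second formation file
    missing_latlon_rate: float = 0.0  # coordinate line omitted

    def validate(self) -> None:
        rates = {"typo_rate": self.typo_rate, "synonym_rate": self.synonym_rate,
                 "orthvar_rate": self.orthvar_rate,
                 "duplicate_block_rate": self.duplicate_block_rate,
                 "missing_latlon_rate": self.missing_latlon_rate}
        for name, value in rates.items():
            if not (0.0 <= value <= 1.0):
                raise InvalidSpecError(f"{name}={value} outside [0, 1]")
        if self.typo_rate + self.synonym_rate + self.orthvar_rate > 1.0:
            raise InvalidSpecError("name-corruption rates sum above 1")
        if not (1 <= self.n_locations <= 999):
            raise InvalidSpecError("n_locations must be in [1, 999]")
        lo, hi = self.communities_per_location
        if not (1 <= lo <= hi <= 28):
            raise InvalidSpecError("communities_per_location must sit within [1, 28]")
        lo, hi = self.codes_per_community
        if not (1 <= lo <= hi):
            raise InvalidSpecError("codes_per_community range invalid")
        if self.species_pool_size < 20:
            raise InvalidSpecError("species_pool_size must be at least 20")


@dataclass
class FixtureSet:
    spec: FixtureSpec
    core_files: dict
    conversion_files: dict
    publications_file: Path
    checklist_file: Path
    truth_file: Path
    truth: pd.DataFrame
    counts: dict


_GENUS_SYL = ["al", "ban", "cal", "dry", "eu", "gre", "hak", "lep", "mel",
              "oro", "pul", "ric", "syn", "tel", "ver", "west", "xan", "zie"]
_GENUS_END = ["ia", "ella", "opsis", "anthus", "ium", "ina", "aria"]
_EPI_SYL = ["ba", "ca", "da", "fo", "gu", "la", "me", "ni", "pa", "ra",
            "sa", "ta", "ve", "lu", "mi", "no", "pe", "ri", "to", "vi"]
_EPI_END = ["ensis", "oides", "atum", "iana", "ifolia", "escens", "ula",
            "osa", "ata", "ella", "ianum", "icola"]

_SURNAMES = ["ARCHER", "BARTON", "COLE", "DUNNE", "EVANS", "FINCH", "GRAY",
             "HOLT", "IRWIN", "KEANE", "LOGAN", "MERCER", "NASH", "OAKES",
             "PRICE", "QUINN", "ROSS", "STONE", "TATE", "VANCE", "WHITE",
             "YOUNG"]
_JOURNALS = ["Aust. J. Bot.", "Proc. R. Soc.", "Trans. Nat. Hist. Soc.",
             "Veg. Surv. Bull.", "Flora Rec."]
_LOCALITY_A = ["NORTHERN", "EASTERN", "UPPER", "LOWER", "WESTERN", "COASTAL",
               "INLAND", "CENTRAL", "SOUTHERN"]
_LOCALITY_B = ["RIDGE", "CREEK", "PLAIN", "RANGE", "SWAMP", "DUNE", "GORGE",
               "FLAT", "BASIN", "LAGOON", "SCARP", "TABLELAND"]
_VEGTYPES = ["OPEN SHRUBLAND", "LOW WOODLAND", "TUSSOCK GRASSLAND",
             "CLOSED HEATH", "SEDGELAND", "TALL OPEN FOREST",
             "CHENOPOD SHRUBLAND", "SWAMP COMPLEX"]
_STATES = "NPQSVWT"
_FORMATIONS = ["sclerophyll_shrublands", "arid_woodlands"]


class _Names:
    """Deterministic synthetic Latin-binomial factory with global uniqueness."""

    def __init__(self, rng: random.Random):
        self.rng = rng
        self.used: set[str] = set()

    def _fresh(self, maker) -> str:
        for _ in range(1000):
            name = maker()
            if name.casefold() not in self.used:
                self.used.add(name.casefold())
                return name
        raise RuntimeError("name space exhausted")

    def genus(self) -> str:
        def make():
            n = self.rng.choice((1, 2))
            stem = "".join(self.rng.choice(_GENUS_SYL) for _ in range(n))
            return (stem + self.rng.choice(_GENUS_END)).capitalize()
        return self._fresh(make)

    def epithet(self) -> str:
        def make():
            n = self.rng.choice((1, 2))
            stem = "".join(self.rng.choice(_EPI_SYL) for _ in range(n))
            return stem + self.rng.choice(_EPI_END)
        # uniqueness is enforced on the full binomial by the caller
        return make()

    def binomial(self, genus: str) -> str:
        def make():
            return f"{genus} {self.epithet()}"
        return self._fresh(make)

    def reserve(self, name: str) -> bool:
        """Claim a name if free; False when it collides with a known name."""
        key = name.casefold()
        if key in self.used:
            return False
        self.used.add(key)
        return True


def _mutate_word(word: str, rng: random.Random) -> str:
    """One substitution or adjacent transposition, never a no-op."""
    letters = "abcdefghijklmnopqrstuvwxyz"
    for _ in range(50):
        chars = list(word)
        if rng.random() < 0.5 and len(chars) >= 2:
            i = rng.randrange(len(chars) - 1)
            chars[i], chars[i + 1] = chars[i + 1], chars[i]
        else:
            i = rng.randrange(len(chars))
            chars[i] = rng.choice(letters)
        out = "".join(chars)
        if out != word:
            return out
    return word + "x"


def corrupt_name(
    name: str,
    kind: str,
    rng: random.Random,
    names: Optional[_Names] = None,
    checklist_rows: Optional[list] = None,
) -> str:
    """Corrupt a binomial the way the legacy data was corrupted.

    ``typo``: one substitution/transposition in the epithet, left
    *unregistered* (must not collide with any known name).
    ``registered_orthvar``: same mutation, but additionally registered in the
    checklist as an orthographic variant of ``name``.
    ``synonym_swap``: replaced by a freshly coined binomial registered as a
    synonym of ``name``.
    """
    if not name:
        raise ValueError("name must be non-empty")
    parts = name.split()
    if kind in ("typo", "registered_orthvar"):
        target = parts[-1]
        for _ in range(100):
            variant = " ".join(parts[:-1] + [_mutate_word(target, rng)])
            if names is None or names.reserve(variant):
                break
        if kind == "registered_orthvar":
            if checklist_rows is None:
                raise ValueError("registered_orthvar needs checklist_rows")
            checklist_rows.append({"name": variant, "status": "orth_var",
                                   "accepted_name": name, "rank": "species",
                                   "taxon_id": ""})
        return variant
    if kind == "synonym_swap":
        if checklist_rows is None or names is None:
            raise ValueError("synonym_swap needs names and checklist_rows")
        genus = parts[0]
        synonym = names.binomial(genus)
        checklist_rows.append({"name": synonym, "status": "synonym",
                               "accepted_name": name, "rank": "species",
                               "taxon_id": ""})
        return synonym
    raise ValueError(f"unknown corruption kind {kind!r}")


def _make_code(name: str, used: set[str], ninth: Optional[str] = None) -> str:
    parts = name.upper().split()
    if len(parts) == 1:  # genus-level code: padded genus name
        base = parts[0][:8].ljust(8, "_")
    else:
        base = (parts[0][:4] + parts[-1][:4]).ljust(8, "_")
    base = "".join(ch if ch.isalnum() or ch == "_" else "X" for ch in base)[:8]
    code = base + (ninth or "")
    if code not in used:
        used.add(code)
        return code
    for digit in "23456789":
        cand = base[:7] + digit + (ninth or "")
        if cand not in used:
            used.add(cand)
            return cand
    for i in range(10, 1000):
        cand = base[: 8 - len(str(i))] + str(i) + (ninth or "")
        if cand not in used:
            used.add(cand)
            return cand
    raise RuntimeError("alphacode space exhausted")


def generate(spec: FixtureSpec, out_dir) -> FixtureSet:
    """Write a complete synthetic dataset and its truth table to ``out_dir``."""
    spec.validate()
    rng = random.Random(spec.seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    names = _Names(rng)
    checklist_rows: list[dict] = []

    n_genera = max(10, spec.species_pool_size // 5)
    genera = [names.genus() for _ in range(n_genera)]
    for g in genera:
        checklist_rows.append({"name": g, "status": "accepted",
                               "accepted_name": g, "rank": "genus",
                               "taxon_id": ""})
    species = []
    for i in range(spec.species_pool_size):
        g = genera[i % n_genera]
        sp = names.binomial(g)
        species.append(sp)
        checklist_rows.append({"name": sp, "status": "accepted",
                               "accepted_name": sp, "rank": "species",
                               "taxon_id": ""})

    # publications: one per location, unique (surname, year)
    pubs = []
    used_cites: set[tuple[str, int]] = set()
    for i in range(spec.n_locations):
        for _ in range(1000):
            surname = rng.choice(_SURNAMES)
            year = rng.randint(1880, 1995)
            if (surname, year) not in used_cites:
                used_cites.add((surname, year))
                break
        pubs.append({"ID": i + 1,
                     "Author(s)": f"{surname.capitalize()}, "
                                  f"{chr(ord('A') + i % 26)}.",
                     "Date": year,
                     "Title": f"Vegetation survey no. {i + 1}.",
                     "Journal": rng.choice(_JOURNALS),
                     "Volume": str(rng.randint(1, 99)),
                     "Pages": f"{rng.randint(1, 200)}-{rng.randint(201, 400)}",
                     "_surname": surname})

    used_codes: set[str] = set()
    # per formation: species/genus name -> (code, conversion row)
    registry: dict[str, dict[str, dict]] = {f: {} for f in _FORMATIONS}
    conv_rows: dict[str, list[dict]] = {f: [] for f in _FORMATIONS}
    habit_choices = ["", "Z", "S", "G", "M", "L", "K", "F", "H", "A"]

    def register(formation: str, name: str, genus_level: bool,
                 ninth: Optional[str] = None) -> dict:
        reg = registry[formation]
        if name in reg:
            return reg[name]
        code = _make_code(name, used_codes, ninth=ninth)
        if genus_level:
            corruption, published, updated, validity = "none", name, "", "L"
        else:
            r = rng.random()
            if r < spec.typo_rate:
                corruption = "typo"
                published = corrupt_name(name, "typo", rng, names=names)
                updated, validity = "", "M"
            elif r < spec.typo_rate + spec.orthvar_rate:
                corruption = "registered_orthvar"
                published = corrupt_name(name, "registered_orthvar", rng,
                                         names=names,
                                         checklist_rows=checklist_rows)
                updated, validity = "", "M"
            elif r < spec.typo_rate + spec.orthvar_rate + spec.synonym_rate:
                corruption = "synonym_swap"
                published = corrupt_name(name, "synonym_swap", rng,
                                         names=names,
                                         checklist_rows=checklist_rows)
                updated, validity = "", "S"
            elif rng.random() < 0.2:
                # the original compiler already updated the name: both recorded
                corruption = "updated_name"
                published = corrupt_name(name, "synonym_swap", rng,
                                         names=names,
                                         checklist_rows=checklist_rows)
                updated, validity = name, "S"
            else:
                corruption, published, updated, validity = "none", name, "", "L"
        habit = "" if genus_level else rng.choice(habit_choices)
        flags = (validity or " ") + (habit or " ") + "G"
        row = {"row_number": len(conv_rows[formation]) + 1, "flags": flags,
               "alphacode": code, "published_name": published,
               "updated_name": updated}
        conv_rows[formation].append(row)
        expected = "NOT_MATCH" if corruption == "typo" else "MATCH"
        meta = {"code": code, "corruption": corruption, "expected": expected,
                "accepted": name, "published": published,
                "genus_level": genus_level}
        reg[name] = meta
        return meta

    truth_rows: list[dict] = []
    file_lines: dict[str, list[str]] = {f: [] for f in _FORMATIONS}
    file_state: dict[str, Optional[str]] = {f: None for f in _FORMATIONS}
    n_communities = 0
    n_codes = 0
    n_missing_latlon = 0
    duplicates: list[tuple[str, list[str], str]] = []  # (formation, lines, state)

    for i in range(1, spec.n_locations + 1):
        formation = _FORMATIONS[(i - 1) % len(_FORMATIONS)]
        state = _STATES[(i - 1) % len(_STATES)]
        loc_code = f"{state}{i:03d}"
        pub = pubs[i - 1]
        locality = (f"{rng.choice(_LOCALITY_A)} {rng.choice(_LOCALITY_B)}: "
                    f"AREA {i}")
        missing_latlon = rng.random() < spec.missing_latlon_rate
        coords = (rng.randint(10, 43), rng.randint(0, 59),
                  rng.randint(113, 152), rng.randint(0, 59))
        n_comms = rng.randint(*spec.communities_per_location)
        wrinkle_site = i == 1

        block_lines: list[str] = []
        block_lines.append(f"5{i:03d}00 LOCATION {loc_code} = {locality} "
                           f"({pub['_surname']} {pub['Date']})")
        if missing_latlon:
            n_missing_latlon += 1
        else:
            block_lines.append(f"9{i:03d}00 {coords[0]} {coords[1]} "
                               f"{coords[2]} {coords[3]}")
        for bb in range(1, n_comms + 1):
            n_communities += 1
            desc = f"{rng.choice(_VEGTYPES)} ({rng.choice(_LOCALITY_B)})"
            block_lines.append(f"5{i:03d}{bb:02d} COMMUNITY {bb:02d} = {desc}")

            m = rng.randint(*spec.codes_per_community)
            wrinkles_here = wrinkle_site and bb == 1
            if wrinkles_here:
                m = max(m, 6)
            chosen = rng.sample(species, m)
            tokens: list[tuple[dict, bool]] = []  # (meta, genus_level)
            if wrinkles_here:
                g1, g2 = rng.sample(genera, 2)
                tokens.append((register(formation, g1, genus_level=True), True))
            elif rng.random() < 0.15:
                g = rng.choice(genera)
                tokens.append((register(formation, g, genus_level=True), True))
            for j, sp in enumerate(chosen):
                # the nine-character code sits clear of the fused/displaced
                # positions so it appears as a standalone chunk
                ninth = "/" if wrinkles_here and j == 5 else None
                tokens.append((register(formation, sp, genus_level=False,
                                        ninth=ninth), False))
            if wrinkles_here:
                # second genus token, placed mid-list for the displaced form
                tokens.insert(3, (register(formation, g2, genus_level=True), True))

            # truth rows, in emission order
            for seq, (meta, genus_level) in enumerate(tokens, start=1):
                n_codes += 1
                truth_rows.append({
                    "formation": formation, "state": state,
                    "location_code": loc_code, "community_number": bb,
                    "seq": seq, "alphacode": meta["code"],
                    "genus_level": genus_level,
                    "accepted_name": meta["accepted"],
                    "published_name": meta["published"],
                    "corruption": meta["corruption"],
                    "expected_category": meta["expected"],
                })

            # comment line: dominant codes (first two non-genus tokens)
            dominants = [m_ for m_, gl in tokens if not gl][:2]
            if dominants and (wrinkles_here or rng.random() < 0.4):
                dom = " ".join(m_["code"] for m_ in dominants)
                block_lines.append(f"3{i:03d}{bb:02d} {dom} #")

            # emission units: rendered tokens, with fused / displaced wrinkles
            units: list[str] = []
            skip_next = False
            for j, (meta, genus_level) in enumerate(tokens):
                if skip_next:
                    skip_next = False
                    continue
                rendered = meta["code"] + ("*" if genus_level else "")
                if wrinkles_here and j == 0 and genus_level and j + 1 < len(tokens):
                    # fused chunk: genus marker directly abuts the next code
                    nxt = tokens[j + 1]
                    units.append(rendered + nxt[0]["code"]
                                 + ("*" if nxt[1] else ""))
                    skip_next = True
                elif (wrinkles_here and j == 3 and genus_level
                      and j + 1 < len(tokens)):
                    # displaced marker: asterisk leads the following chunk
                    nxt = tokens[j + 1]
                    units.append(meta["code"])
                    units.append("*" + nxt[0]["code"] + ("*" if nxt[1] else ""))
                    skip_next = True
                else:
                    units.append(rendered)
            for k in range(0, len(units), 8):
                chunk = " ".join(units[k : k + 8])
                block_lines.append(f"0{i:03d}{bb:02d} {chunk} #")
        block_lines.append("500000 " + "-" * 31)

        def emit(formation_: str, lines_: list[str], state_: str) -> None:
            if file_state[formation_] != state_:
                file_lines[formation_].append(f"800000 {state_}")
                file_state[formation_] = state_
            file_lines[formation_].extend(lines_)

        emit(formation, block_lines, state)
        if rng.random() < spec.duplicate_block_rate:
            other = _FORMATIONS[(_FORMATIONS.index(formation) + 1)
                                % len(_FORMATIONS)]
            duplicates.append((other, block_lines, state))
            # the duplicate file needs the same conversion entries
            for meta in list(registry[formation].values()):
                name = meta["accepted"]
                if name not in registry[other]:
                    row = {"row_number": len(conv_rows[other]) + 1,
                           "flags": "L G" if meta["genus_level"] else "LZG",
                           "alphacode": meta["code"],
                           "published_name": meta["published"],
                           "updated_name": ""}
                    # mirror the original entry verbatim so both formations
                    # resolve identically
                    src = next(r for r in conv_rows[formation]
                               if r["alphacode"] == meta["code"])
                    row["flags"] = src["flags"]
                    row["updated_name"] = src["updated_name"]
                    conv_rows[other].append(row)
                    registry[other][name] = meta

    for other, lines, state in duplicates:
        if file_state[other] != state:
            file_lines[other].append(f"800000 {state}")
            file_state[other] = state
        file_lines[other].extend(lines)

    # ---- write files -----------------------------------------------------
    core_files: dict[str, Path] = {}
    conversion_files: dict[str, Path] = {}
    active = [f for f in _FORMATIONS if file_lines[f]]
    for formation in active:
        core = out / f"core_{formation}.txt"
        core.write_text("\n".join(file_lines[formation]) + "\n",
                        encoding="ascii")
        core_files[formation] = core
        conv = out / f"conversion_{formation}.csv"
        pd.DataFrame(conv_rows[formation],
                     columns=["row_number", "flags", "alphacode",
                              "published_name", "updated_name"]
                     ).to_csv(conv, index=False, lineterminator="\n")
        conversion_files[formation] = conv

    pubs_df = pd.DataFrame([{k: v for k, v in p.items() if k != "_surname"}
                            for p in pubs])
    publications_file = out / "publications.csv"
    pubs_df.to_csv(publications_file, index=False, lineterminator="\n")

    check_df = pd.DataFrame(checklist_rows,
                            columns=["name", "status", "accepted_name",
                                     "rank", "taxon_id"])
    check_df = check_df.sort_values(["name", "status"]).reset_index(drop=True)
    check_df["taxon_id"] = [f"T{i:05d}" for i in range(1, len(check_df) + 1)]
    checklist_file = out / "checklist.csv"
    check_df.to_csv(checklist_file, index=False, lineterminator="\n")

    truth = pd.DataFrame(truth_rows)
    truth_file = out / "truth.csv"
    truth.to_csv(truth_file, index=False, lineterminator="\n")

    counts = {
        "n_blocks": spec.n_locations,
        "n_communities": n_communities,
        "n_codes": n_codes,
        "n_duplicate_blocks": len(duplicates),
        "n_missing_latlon": n_missing_latlon,
    }
    return FixtureSet(spec=spec, core_files=core_files,
                      conversion_files=conversion_files,
                      publications_file=publications_file,
                      checklist_file=checklist_file, truth_file=truth_file,
                      truth=truth, counts=counts)
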