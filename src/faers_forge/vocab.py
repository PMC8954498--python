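"""Pluggable drug vocabulary: RxNorm-style atoms, names and relationships.

The standardization cascade only needs three things from a vocabulary:

* atoms — string-level entries carrying an RXAUI (atom id), an RXCUI
  (concept id), a name, a term type and a source vocabulary code;
* a name index for exact lookups;
* a relationship graph that can be walked from any matched atom down to
  ingredient-level atoms (``has_ingredient``, ``consists_of``,
  ``tradename_of`` and friends).

Two interchangeable loaders implement this interface: :func:`Vocabulary.from_rrf`
for RRF pipe-delimited concept/relationship files (the RxNorm release
layout), and the bundled mini-vocabulary built programmatically in
:mod:`faers_forge.synthetic`.  Real RxNorm content is never required.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

#: term types considered "single active ingredient level"
INGREDIENT_TERM_TYPES = frozenset({"IN", "PIN"})

#: the primary source vocabulary code (preferred on ambiguous names)
PRIMARY_SOURCE = "RXNORM"

#: relationship kinds followed when normalizing an atom toward ingredients.
#: A relation row (x, rela, y) is read as "x RELA y", i.e. walking x -> y
#: moves toward the ingredient level.
WALK_RELATIONS = frozenset({
    "has_ingredient",
    "consists_of",
    "tradename_of",
    "form_of",
    "has_precise_ingredient",
})


@dataclass(frozen=True)
class VocabularyEntry:
    """One atom: a (name, source, term-type) string with stable identifiers."""

    rxaui: str
    rxcui: str
    name: str
    term_type: str
    source: str
    #: None, or one of {"vaccine", "granularity", "non_rxnorm_ingredient"} —
    #: the normalization exceptions (vaccines kept whole; atoms whose other-
    #: vocabulary form is more granular; ingredients maintained only outside
    #: the primary source vocabulary).
    exception: str | None = None

    @property
    def is_ingredient(self) -> bool:
        return self.term_type in INGREDIENT_TERM_TYPES


def normalize_lookup_name(name: str) -> str:
    """Case-fold and whitespace-collapse a name for index lookups."""
    return " ".join(str(name).split()).upper()


class Vocabulary:
    """In-memory vocabulary: atoms + name index + ingredient-walk graph."""

    def __init__(
        self,
        entries: Iterable[VocabularyEntry],
        relations: Iterable[tuple[str, str, str]] = (),
    ) -> None:
        self.entries: dict[str, VocabularyEntry] = {}
        for e in entries:
            if e.rxaui in self.entries:
                raise ValueError(f"duplicate RXAUI {e.rxaui!r}")
            self.entries[e.rxaui] = e
        self._name_index: dict[str, list[str]] = defaultdict(list)
        for e in self.entries.values():
            self._name_index[normalize_lookup_name(e.name)].append(e.rxaui)
        self._edges: dict[str, list[str]] = defaultdict(list)
        self.relations: list[tuple[str, str, str]] = []
        for frm, rela, to in relations:
            self.relations.append((frm, rela, to))
            if rela in WALK_RELATIONS:
                self._edges[frm].append(to)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, rxaui: str) -> bool:
        return rxaui in self.entries

    def get(self, rxaui: str) -> VocabularyEntry | None:
        return self.entries.get(rxaui)

    def lookup(self, name: str) -> list[str]:
        """All atoms whose normalized name equals ``name``, best first.

        Preference: primary-source ingredient-level atoms, then any
        ingredient-level atom, then primary-source atoms, then lowest RXAUI.
        """
        cands = self._name_index.get(normalize_lookup_name(name), [])

        def rank(rxaui: str) -> tuple:
            e = self.entries[rxaui]
            primary = e.source == PRIMARY_SOURCE
            return (
                not (primary and e.is_ingredient),
                not e.is_ingredient,
                not primary,
                int(rxaui) if rxaui.isdigit() else rxaui,
            )

        return sorted(cands, key=rank)

    def walk_targets(self, rxaui: str) -> list[str]:
        """Direct walk successors of an atom (toward ingredient level)."""
        return self._edges.get(rxaui, [])

    # ------------------------------------------------------------------ RRF IO

    @classmethod
    def from_rrf(
        cls,
        directory: str | Path,
        concepts_file: str = "RXNCONSO.RRF",
        relations_file: str = "RXNREL.RRF",
        exceptions: Mapping[str, str] | None = None,
    ) -> "Vocabulary":
        """Load a vocabulary from RRF pipe-delimited release files.

        Only the columns the cascade needs are read (RXCUI, RXAUI, SAB, TTY,
        STR from the concept file; RXAUI1, RELA, RXAUI2 from the relationship
        file).  ``exceptions`` optionally maps RXAUI -> exception flag, since
        the RRF layout has no column for the normalization exceptions.
        """
        directory = Path(directory)
        exceptions = dict(exceptions or {})
        entries = []
        with open(directory / concepts_file, encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                f = line.split("|")
                rxcui, rxaui, sab, tty, name = f[0], f[7], f[11], f[12], f[14]
                entries.append(VocabularyEntry(
                    rxaui=rxaui, rxcui=rxcui, name=name, term_type=tty,
                    source=sab, exception=exceptions.get(rxaui),
                ))
        relations = []
        rel_path = directory / relations_file
        if rel_path.exists():
            with open(rel_path, encoding="utf-8") as fh:
                for line in fh:
                    line = line.rstrip("\n")
                    if not line:
                        continue
                    f = line.split("|")
                    rxaui1, rela, rxaui2 = f[1], f[7], f[5]
                    if rela:
                        relations.append((rxaui1, rela, rxaui2))
        return cls(entries, relations)

    def to_rrf(self, directory: str | Path) -> None:
        """Write the vocabulary back out in the RRF column layout."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        with open(directory / "RXNCONSO.RRF", "w", encoding="utf-8") as fh:
            for e in sorted(self.entries.values(), key=lambda e: e.rxaui):
                f = [""] * 18
                f[0], f[1], f[6] = e.rxcui, "ENG", "Y"
                f[7], f[11], f[12] = e.rxaui, e.source, e.term_type
                f[13], f[14], f[16] = e.rxcui, e.name, "N"
                fh.write("|".join(f) + "|\n")
        with open(directory / "RXNREL.RRF", "w", encoding="utf-8") as fh:
            for frm, rela, to in self.relations:
                f = [""] * 16
                e1 = self.entries.get(frm)
                e2 = self.entries.get(to)
                f[0] = e1.rxcui if e1 else ""
                f[1], f[2] = frm, "AUI"
                f[4] = e2.rxcui if e2 else ""
                f[5], f[6], f[7] = to, "AUI", rela
                fh.write("|".join(f) + "|\n")

    def exception_map(self) -> dict[str, str]:
        """RXAUI -> exception flag, for re-loading RRF round trips."""
        return {e.rxaui: e.exception for e in self.entries.values() if e.exception}
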