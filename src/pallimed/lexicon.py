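"""Drug-name lexicon: the dictionary that defines the "words of interest".

A lexicon maps every *surface form* a drug may take in clinical notes
(brand names, abbreviations, spelling variants) onto one *canonical*
generic name, e.g. ``diflucan -> fluconazole``. Matching downstream is
exact and case-insensitive; the lexicon is therefore validated hard at
load time: a surface form mapping to two different canonicals is an
error, never a silent overwrite, because a mis-canonicalized synonym
corrupts every downstream frequency.

The on-disk format is 2-3 column delimited text (TSV or CSV)::

    surface_form<TAB>canonical[<TAB>source_tag]

``#`` lines are comments; a header row is auto-detected. A small
fixture lexicon of common ICU agents ships with the package
(:func:`default_lexicon_path`).
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Optional, Union

from .text import tokenize

__all__ = [
    "LexiconEntry",
    "DrugLexicon",
    "LexiconError",
    "load_lexicon",
    "write_lexicon",
    "default_lexicon_path",
    "load_default_lexicon",
]

#: column names that mark an optional header row
_RESERVED_HEADERS = {"surface_form", "surface", "canonical", "source_tag", "source", "tag"}


class LexiconError(ValueError):
    """Raised when a lexicon file is empty, malformed or ambiguous."""


@dataclass(frozen=True)
class LexiconEntry:
    """One surface-form -> canonical mapping.

    ``surface_form`` is how the name may appear in notes; ``canonical``
    is the generic-name identifier it normalizes to; ``source_tag``
    records provenance (``generic``, ``brand``, ``abbreviation`` ...).
    """

    surface_form: str
    canonical: str
    source_tag: str = "generic"


def _normalize(text: str) -> str:
    """Case-fold and whitespace-normalize a name."""
    return " ".join(text.casefold().split())


def _surface_variants(tokens: tuple[str, ...]) -> set[tuple[str, ...]]:
    """Token-tuple variants treating hyphen and space as equivalent.

    ``("piperacillin-tazobactam",)`` and ``("piperacillin",
    "tazobactam")`` both match either written form.
    """
    variants = {tokens}
    # split every hyphenated token
    split: list[str] = []
    for tok in tokens:
        split.extend(tok.split("-"))
    variants.add(tuple(split))
    # join everything into one hyphenated token
    if len(tokens) > 1 or len(split) > 1:
        variants.add(("-".join(split),))
    return {v for v in variants if v and all(v)}


class DrugLexicon:
    """Validated synonym -> canonical map over drug names.

    Parameters
    ----------
    entries : iterable of LexiconEntry
        Raw entries; surface forms are case-folded and
        whitespace-normalized, hyphen/space variants of multi-word
        forms are registered, and a self-entry is auto-added for every
        canonical that lacks one.

    Raises
    ------
    LexiconError
        If any surface form maps to more than one canonical, or no
        entries are given.
    """

    def __init__(self, entries: Iterable[LexiconEntry]):
        raw = list(entries)
        if not raw:
            raise LexiconError("lexicon has no entries")

        self._entries: list[LexiconEntry] = []
        self._map: dict[tuple[str, ...], str] = {}
        conflicts: list[str] = []
        seen_canonicals: set[str] = set()

        def register(tokens: tuple[str, ...], canonical: str) -> None:
            prior = self._map.get(tokens)
            if prior is not None and prior != canonical:
                conflicts.append(
                    f"surface {' '.join(tokens)!r} maps to both "
                    f"{prior!r} and {canonical!r}"
                )
            else:
                self._map[tokens] = canonical

        for entry in raw:
            surface = _normalize(entry.surface_form)
            canonical = _normalize(entry.canonical)
            if not surface:
                raise LexiconError("empty surface form in lexicon entry")
            if not canonical:
                raise LexiconError(f"empty canonical for surface {surface!r}")
            norm = LexiconEntry(surface, canonical, entry.source_tag)
            self._entries.append(norm)
            seen_canonicals.add(canonical)
            tokens = tuple(tokenize(surface))
            if not tokens:
                raise LexiconError(f"surface form {surface!r} has no tokens")
            for variant in _surface_variants(tokens):
                register(variant, canonical)

        # every canonical maps to itself (auto-added when absent)
        for canonical in sorted(seen_canonicals):
            tokens = tuple(tokenize(canonical))
            for variant in _surface_variants(tokens):
                if variant not in self._map:
                    register(variant, canonical)
            if not any(e.surface_form == canonical for e in self._entries):
                self._entries.append(LexiconEntry(canonical, canonical, "generic"))

        if conflicts:
            raise LexiconError(
                "ambiguous synonym mapping:\n  " + "\n  ".join(sorted(set(conflicts)))
            )

        self._canonical_terms = frozenset(self._map.values())
        self._max_ngram = max(len(k) for k in self._map)

    # -- queries -----------------------------------------------------

    def lookup(self, surface: str) -> Optional[str]:
        """Case-insensitive exact lookup; ``None`` when absent."""
        tokens = tuple(tokenize(surface))
        return self._map.get(tokens)

    def lookup_tokens(self, tokens: tuple[str, ...]) -> Optional[str]:
        """Lookup of an already-tokenized surface form."""
        return self._map.get(tokens)

    @property
    def canonical_terms(self) -> frozenset[str]:
        """The image of the surface -> canonical map."""
        return self._canonical_terms

    @property
    def max_ngram(self) -> int:
        """Longest surface form in tokens (scan window for matching)."""
        return self._max_ngram

    def entries(self) -> list[LexiconEntry]:
        """Normalized entries, sorted for deterministic output."""
        return sorted(self._entries, key=lambda e: (e.canonical, e.surface_form))

    def surface_map(self) -> dict[str, str]:
        """Full surface -> canonical map (surface keys space-joined)."""
        return {" ".join(k): v for k, v in sorted(self._map.items())}

    def __contains__(self, surface: str) -> bool:
        return self.lookup(surface) is not None

    def __len__(self) -> int:
        return len(self._canonical_terms)

    def __iter__(self) -> Iterator[str]:
        return iter(sorted(self._canonical_terms))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DrugLexicon):
            return NotImplemented
        return self._map == other._map

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"DrugLexicon({len(self._canonical_terms)} canonical terms, "
            f"{len(self._map)} surface forms)"
        )

    def synonyms(self, canonical: str) -> list[str]:
        """All surface forms of a canonical term other than itself."""
        canonical = _normalize(canonical)
        return sorted(
            {
                e.surface_form
                for e in self._entries
                if e.canonical == canonical and e.surface_form != canonical
            }
        )


def _sniff_delimiter(sample_lines: list[str]) -> str:
    for line in sample_lines:
        if "\t" in line:
            return "\t"
    return ","


def load_lexicon(
    path: Union[str, Path], delimiter: Optional[str] = None
) -> DrugLexicon:
    """Load and validate a lexicon from delimited text.

    Parameters
    ----------
    path : path-like
        2-3 column TSV/CSV: surface_form, canonical[, source_tag].
        ``#`` comment lines are ignored; a header row is auto-detected
        by reserved column names.
    delimiter : str, optional
        Explicit delimiter; sniffed (tab, then comma) when omitted.

    Raises
    ------
    LexiconError
        Empty file, malformed rows, or conflicting canonical mappings.
    """
    path = Path(path)
    lines = [
        ln
        for ln in path.read_text(encoding="utf-8").splitlines()
        if ln.strip() and not ln.lstrip().startswith("#")
    ]
    if not lines:
        raise LexiconError(f"lexicon file {path} is empty")
    if delimiter is None:
        delimiter = _sniff_delimiter(lines)

    rows = list(csv.reader(io.StringIO("\n".join(lines)), delimiter=delimiter))
    first = [c.strip().casefold() for c in rows[0]]
    if first and first[0] in _RESERVED_HEADERS:
        rows = rows[1:]
    if not rows:
        raise LexiconError(f"lexicon file {path} has a header but no data rows")

    entries = []
    for i, row in enumerate(rows, start=1):
        cells = [c.strip() for c in row if c.strip()]
        if len(cells) < 2:
            raise LexiconError(
                f"{path}, row {i}: expected 2-3 columns, got {row!r}"
            )
        surface, canonical = cells[0], cells[1]
        tag = cells[2] if len(cells) > 2 else "generic"
        entries.append(LexiconEntry(surface, canonical, tag))
    return DrugLexicon(entries)


def write_lexicon(lexicon: DrugLexicon, path: Union[str, Path]) -> None:
    """Write a lexicon back to TSV (round-trips through load_lexicon)."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["surface_form", "canonical", "source_tag"])
        for entry in lexicon.entries():
            writer.writerow([entry.surface_form, entry.canonical, entry.source_tag])


def default_lexicon_path() -> Path:
    """Path of the bundled fixture lexicon (common ICU agents)."""
    return Path(str(resources.files("pallimed").joinpath("data/drug_lexicon.tsv")))


def load_default_lexicon() -> DrugLexicon:
    """Load the bundled fixture lexicon."""
    return load_lexicon(default_lexicon_path())
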