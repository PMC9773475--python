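"""Drug-term extraction and the patient x term document-term matrix.

The extraction stage scans tokenized note text against a validated
:class:`~pallimed.lexicon.DrugLexicon` using longest-match-first,
non-overlapping matching (so "piperacillin-tazobactam" never also
counts as "piperacillin"), and pools all of a patient's notes into one
row of a document-term matrix A. Two modes exist:

``binary`` (default)
    entry = 1 if the patient's notes mention the term at all. One
    patient contributes at most 1 per term, so a term's column sum is
    its patient-level document frequency.
``count``
    entry = total number of mentions across the patient's notes.

Terms never observed in the corpus are dropped, and columns are
ordered lexicographically, so the matrix layout is deterministic.
"""

from __future__ import annotations

import csv
import json
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .lexicon import DrugLexicon
from .text import tokenize

__all__ = [
    "NoteDocument",
    "DocumentTermMatrix",
    "tokenize",
    "extract_terms",
    "build_dtm",
    "DrugTermVectorizer",
    "read_notes",
    "write_notes",
    "write_dtm",
    "read_dtm",
]

NOTE_TYPES = ("admission", "weekly", "free", "hospice", "other")


@dataclass(frozen=True)
class NoteDocument:
    """One free-text clinical note.

    ``note_type`` is one of admission | weekly | free | hospice |
    other; ``text`` may be empty (records are messy)."""

    patient_id: str
    text: str = ""
    note_type: str = "other"
    date: Optional[str] = None  # ISO-8601 or None


@dataclass
class DocumentTermMatrix:
    """Patients x canonical drug terms occurrence matrix (the matrix A).

    Attributes
    ----------
    row_ids : list of str
        Patient identifiers, one per row, in corpus order.
    terms : list of str
        Canonical terms, lexicographically ordered; all-zero columns
        are never present.
    values : ndarray of int, shape (n_patients, n_terms)
    mode : {"binary", "count"}
    """

    row_ids: list[str]
    terms: list[str]
    values: np.ndarray
    mode: str = "binary"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int64)
        if self.values.shape != (len(self.row_ids), len(self.terms)):
            raise ValueError(
                f"shape {self.values.shape} inconsistent with "
                f"{len(self.row_ids)} patients x {len(self.terms)} terms"
            )
        if self.mode not in ("binary", "count"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if (self.values < 0).any():
            raise ValueError("negative entries in document-term matrix")
        if self.mode == "binary" and self.values.size and self.values.max() > 1:
            raise ValueError("binary-mode matrix has entries > 1")
        if list(self.terms) != sorted(self.terms):
            raise ValueError("term columns must be lexicographically sorted")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def binarize(self) -> "DocumentTermMatrix":
        """Presence/absence view of the matrix."""
        return DocumentTermMatrix(
            list(self.row_ids), list(self.terms), (self.values > 0).astype(np.int64),
            mode="binary",
        )

    def column(self, term: str) -> np.ndarray:
        return self.values[:, self.terms.index(term)]

    def term_frequencies(self) -> pd.Series:
        """Per-term column sums (document frequency in binary mode)."""
        return pd.Series(
            self.values.sum(axis=0), index=pd.Index(self.terms, name="term"),
            name="frequency",
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.row_ids, name="patient_id"),
            columns=self.terms,
        )

    def subset_rows(self, patient_ids: Sequence[str]) -> "DocumentTermMatrix":
        """Row subset (e.g. one cohort group), dropping zero columns."""
        idx = [self.row_ids.index(p) for p in patient_ids]
        values = self.values[idx]
        keep = values.sum(axis=0) > 0
        return DocumentTermMatrix(
            [self.row_ids[i] for i in idx],
            [t for t, k in zip(self.terms, keep) if k],
            values[:, keep],
            mode=self.mode,
        )


def extract_terms(
    doc: Union[NoteDocument, str], lexicon: DrugLexicon
) -> Counter:
    """Extract canonical drug-term mentions from one note.

    Longest-match-first, non-overlapping scan over the token stream:
    multi-word surface forms are tried before their prefixes, and a
    matched span is consumed. Every match contributes its canonical
    term once per occurrence.

    Returns
    -------
    collections.Counter
        canonical term -> number of mentions.
    """
    text = doc.text if isinstance(doc, NoteDocument) else doc
    tokens = tokenize(text)
    counts: Counter = Counter()
    i, n = 0, len(tokens)
    window = lexicon.max_ngram
    while i < n:
        for length in range(min(window, n - i), 0, -1):
            canonical = lexicon.lookup_tokens(tuple(tokens[i : i + length]))
            if canonical is not None:
                counts[canonical] += 1
                i += length
                break
        else:
            i += 1
    return counts


def build_dtm(
    docs: Iterable[NoteDocument],
    lexicon: DrugLexicon,
    mode: str = "binary",
) -> DocumentTermMatrix:
    """Assemble the patient-level document-term matrix.

    All notes of one patient are pooled into a single row (the
    document unit is the patient). Terms never observed are dropped;
    columns are sorted lexicographically; rows follow the order in
    which patients first appear in ``docs``.

    Raises
    ------
    ValueError
        On an empty document collection or unknown mode.
    """
    if mode not in ("binary", "count"):
        raise ValueError(f"unknown mode {mode!r}")
    docs = list(docs)
    if not docs:
        raise ValueError("empty document collection")

    per_patient: dict[str, Counter] = {}
    for doc in docs:
        if not doc.patient_id:
            raise ValueError("note without a patient_id")
        per_patient.setdefault(doc.patient_id, Counter()).update(
            extract_terms(doc, lexicon)
        )

    row_ids = list(per_patient)
    terms = sorted({t for c in per_patient.values() for t in c})
    values = np.zeros((len(row_ids), len(terms)), dtype=np.int64)
    col = {t: j for j, t in enumerate(terms)}
    for i, pid in enumerate(row_ids):
        for term, k in per_patient[pid].items():
            values[i, col[term]] = k
    if mode == "binary":
        values = (values > 0).astype(np.int64)
    return DocumentTermMatrix(row_ids, terms, values, mode=mode)


class DrugTermVectorizer(TransformerMixin, BaseEstimator):
    """Vectorize clinical notes into drug-term occurrence rows.

    A scikit-learn transformer over collections of
    :class:`NoteDocument`. ``fit`` learns the vocabulary (canonical
    terms observed in the corpus, sorted); ``transform`` pools each
    patient's notes into one row over that vocabulary.

    Parameters
    ----------
    lexicon : DrugLexicon
        Validated synonym -> canonical map.
    mode : {"binary", "count"}, default "binary"
        Presence/absence versus total mention counts.

    Attributes
    ----------
    vocabulary_ : list of str
        Canonical terms observed during fit, lexicographic order.
    """

    def __init__(self, lexicon: Optional[DrugLexicon] = None, mode: str = "binary"):
        self.lexicon = lexicon
        self.mode = mode

    def _check(self) -> DrugLexicon:
        if self.lexicon is None:
            raise ValueError("DrugTermVectorizer requires a lexicon")
        if self.mode not in ("binary", "count"):
            raise ValueError(f"unknown mode {self.mode!r}")
        return self.lexicon

    def fit(self, X: Iterable[NoteDocument], y=None) -> "DrugTermVectorizer":
        lexicon = self._check()
        dtm = build_dtm(X, lexicon, mode=self.mode)
        self.vocabulary_ = list(dtm.terms)
        return self

    def transform(self, X: Iterable[NoteDocument]) -> np.ndarray:
        lexicon = self._check()
        if not hasattr(self, "vocabulary_"):
            raise ValueError("DrugTermVectorizer is not fitted")
        X = list(X)
        if not X:
            raise ValueError("empty document collection")
        per_patient: dict[str, Counter] = {}
        for doc in X:
            per_patient.setdefault(doc.patient_id, Counter()).update(
                extract_terms(doc, lexicon)
            )
        col = {t: j for j, t in enumerate(self.vocabulary_)}
        values = np.zeros((len(per_patient), len(col)), dtype=np.int64)
        for i, (pid, counts) in enumerate(per_patient.items()):
            for term, k in counts.items():
                if term in col:
                    values[i, col[term]] = k
        if self.mode == "binary":
            values = (values > 0).astype(np.int64)
        return values

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        return np.asarray(self.vocabulary_, dtype=object)

    def to_dtm(self, X: Iterable[NoteDocument]) -> DocumentTermMatrix:
        """Full DocumentTermMatrix (with row ids) for a corpus."""
        return build_dtm(X, self._check(), mode=self.mode)


# -- note and matrix I/O -------------------------------------------------

_NOTE_FIELDS = ("patient_id", "note_type", "date", "text")


def read_notes(path: Union[str, Path]) -> list[NoteDocument]:
    """Read notes from JSON-lines or CSV (by file extension).

    Expected fields/columns: patient_id, note_type, date (ISO-8601),
    text. Missing note_type defaults to "other"; unknown note types
    are warned on, not rejected.
    """
    path = Path(path)
    rows: list[dict] = []
    if path.suffix.lower() in (".jsonl", ".ndjson", ".json"):
        with path.open(encoding="utf-8") as fh:
            for line in fh:
                if line.strip():
                    rows.append(json.loads(line))
    else:
        with path.open(encoding="utf-8", newline="") as fh:
            rows.extend(csv.DictReader(fh))
    docs = []
    for row in rows:
        note_type = row.get("note_type") or "other"
        if note_type not in NOTE_TYPES:
            warnings.warn(f"unknown note_type {note_type!r}", stacklevel=2)
        docs.append(
            NoteDocument(
                patient_id=str(row["patient_id"]),
                text=row.get("text") or "",
                note_type=note_type,
                date=row.get("date") or None,
            )
        )
    return docs


def write_notes(docs: Iterable[NoteDocument], path: Union[str, Path]) -> None:
    """Write notes as JSON-lines (UTF-8, key order fixed)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for doc in docs:
            fh.write(
                json.dumps(
                    {
                        "patient_id": doc.patient_id,
                        "note_type": doc.note_type,
                        "date": doc.date,
                        "text": doc.text,
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )


def write_dtm(
    dtm: DocumentTermMatrix, path: Union[str, Path], fmt: str = "tsv"
) -> None:
    """Export the matrix as wide TSV or sparse triplets.

    ``tsv``: patient rows x canonical-term columns. ``triplets``:
    three columns (patient_id, term, value), zero entries omitted.
    """
    path = Path(path)
    if fmt == "tsv":
        dtm.to_frame().to_csv(path, sep="\t")
    elif fmt == "triplets":
        with path.open("w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t")
            writer.writerow(["patient_id", "term", "value"])
            for i, pid in enumerate(dtm.row_ids):
                for j, term in enumerate(dtm.terms):
                    v = int(dtm.values[i, j])
                    if v:
                        writer.writerow([pid, term, v])
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_dtm(path: Union[str, Path], mode: Optional[str] = None) -> DocumentTermMatrix:
    """Read a wide-TSV matrix written by :func:`write_dtm`."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    values = frame.to_numpy(dtype=np.int64)
    if mode is None:
        mode = "binary" if (values.size == 0 or values.max() <= 1) else "count"
    order = np.argsort(frame.columns.to_numpy())
    return DocumentTermMatrix(
        [str(p) for p in frame.index],
        [str(c) for c in frame.columns[order]],
        values[:, order],
        mode=mode,
    )
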