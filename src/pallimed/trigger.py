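"""The Palliative trigger index (PTI): ranking referral-trigger drugs.

For each canonical drug term, let ``f_e`` be its word frequency in
the early-integration group and ``f_l`` in the late-referral group
(in binary mode these are patient-level document frequencies). The
index is

    difference = f_e - f_l
    PTI        = f_e * difference

A drug prescribed widely in the early group but rarely in the late
group scores high and is a candidate trigger for early palliative
consultation. When either factor is zero the index is zero (its
stated minimum for non-negative inputs). Negative differences
(late-enriched drugs) are retained with negative PTI rather than
clamped: they carry information, and the top-k report is unaffected.

Ranks use competition ("min") ranking so tied values share a rank;
frequencies are compared raw, not normalized by group size (a
per-capita variant exists behind ``normalize=True``, as an
extension).
"""

from __future__ import annotations

from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator

from .cohort import EARLY, LATE, GroupAssignment
from .extract import DocumentTermMatrix

__all__ = [
    "group_frequencies",
    "compute_pti",
    "TriggerIndexRanker",
    "write_trigger_table",
    "read_frequency_table",
]

#: Table export column order (freq_late appended for completeness)
TABLE_COLUMNS = [
    "term",
    "freq_early",
    "rank_early",
    "difference",
    "rank_difference",
    "pti",
    "rank_pti",
    "freq_late",
]


def group_frequencies(
    dtm: DocumentTermMatrix, groups: GroupAssignment
) -> pd.DataFrame:
    """Per-term word frequencies in the early and late groups.

    freq_g(term) = sum of the term's column over group-g rows; in
    binary mode, the number of group-g patients mentioning the term.

    Raises
    ------
    KeyError
        If a matrix row's patient is missing from the assignment.
    """
    missing = [p for p in dtm.row_ids if p not in groups.groups]
    if missing:
        raise KeyError(f"patients in matrix but not in group assignment: {missing}")
    labels = np.array([groups.group_of(p) for p in dtm.row_ids])
    freq_early = dtm.values[labels == EARLY].sum(axis=0)
    freq_late = dtm.values[labels == LATE].sum(axis=0)
    return pd.DataFrame(
        {
            "term": dtm.terms,
            "freq_early": freq_early.astype(np.int64),
            "freq_late": freq_late.astype(np.int64),
        }
    )


def _competition_rank_desc(values: np.ndarray) -> np.ndarray:
    """Competition ("min") ranks, largest value = rank 1."""
    return rankdata(-np.asarray(values, dtype=float), method="min").astype(np.int64)


def compute_pti(
    freqs: pd.DataFrame,
    normalize: bool = False,
    group_sizes: Optional[tuple[int, int]] = None,
) -> pd.DataFrame:
    """Compute the trigger table from per-term group frequencies.

    Parameters
    ----------
    freqs : DataFrame
        Columns ``term``, ``freq_early``, ``freq_late`` (or a term
        index with the two frequency columns).
    normalize : bool, default False
        Extension: divide each group frequency by its group size
        before the difference/product, yielding a per-capita index.
        Requires ``group_sizes``.
    group_sizes : (n_early, n_late), optional
        Needed only when ``normalize`` is requested.

    Returns
    -------
    DataFrame
        Columns term, freq_early, freq_late, difference, pti,
        rank_early, rank_difference, rank_pti; sorted by pti
        descending, ties broken alphabetically by term. Ranks are
        competition ("min") ranks, so equal values share a rank.
    """
    table = freqs.reset_index() if "term" not in freqs.columns else freqs.copy()
    if "term" not in table.columns or not {"freq_early", "freq_late"} <= set(table.columns):
        raise ValueError("need columns term, freq_early, freq_late")
    table = table[["term", "freq_early", "freq_late"]].copy()

    fe = table["freq_early"].to_numpy()
    fl = table["freq_late"].to_numpy()
    if normalize:
        if group_sizes is None:
            raise ValueError("normalize=True requires group_sizes")
        n_e, n_l = group_sizes
        fe = fe / n_e
        fl = fl / n_l
        table["difference"] = fe - fl
        table["pti"] = fe * (fe - fl)
    else:
        fe = fe.astype(np.int64)
        fl = fl.astype(np.int64)
        table["difference"] = fe - fl
        table["pti"] = fe * (fe - fl)

    table["rank_early"] = _competition_rank_desc(fe)
    table["rank_difference"] = _competition_rank_desc(table["difference"].to_numpy())
    table["rank_pti"] = _competition_rank_desc(table["pti"].to_numpy())
    table = table.sort_values(
        ["pti", "term"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return table[
        ["term", "freq_early", "freq_late", "difference", "pti",
         "rank_early", "rank_difference", "rank_pti"]
    ]


class TriggerIndexRanker(BaseEstimator):
    """Rank candidate trigger drugs by the Palliative trigger index.

    scikit-learn style estimator: ``fit`` takes an occurrence matrix
    and early/late group labels and computes the trigger table.

    Parameters
    ----------
    normalize : bool, default False
        Per-capita extension (see :func:`compute_pti`).

    Attributes
    ----------
    table_ : DataFrame
        The trigger table, sorted by PTI descending.
    group_sizes_ : (int, int)
        (n_early, n_late).
    terms_ : list of str
    """

    def __init__(self, normalize: bool = False):
        self.normalize = normalize

    def fit(
        self,
        X: Union[DocumentTermMatrix, np.ndarray],
        y: Union[GroupAssignment, Sequence[str], None] = None,
    ) -> "TriggerIndexRanker":
        if isinstance(X, DocumentTermMatrix):
            if not isinstance(y, GroupAssignment):
                y = GroupAssignment(
                    dict(zip(X.row_ids, [str(g) for g in y])), threshold_days=np.nan
                )
            freqs = group_frequencies(X, y)
            terms = list(X.terms)
        else:
            X = np.asarray(X)
            labels = np.asarray([str(g) for g in y])
            if labels.shape[0] != X.shape[0]:
                raise ValueError("X rows and y labels differ in length")
            terms = [f"term_{j}" for j in range(X.shape[1])]
            freqs = pd.DataFrame(
                {
                    "term": terms,
                    "freq_early": X[labels == EARLY].sum(axis=0).astype(np.int64),
                    "freq_late": X[labels == LATE].sum(axis=0).astype(np.int64),
                }
            )
        n_early = int(np.sum(
            [g == EARLY for g in (y.groups.values() if isinstance(y, GroupAssignment) else y)]
        ))
        n_total = len(y.groups) if isinstance(y, GroupAssignment) else len(list(y))
        self.group_sizes_ = (n_early, n_total - n_early)
        self.table_ = compute_pti(
            freqs, normalize=self.normalize, group_sizes=self.group_sizes_
        )
        self.terms_ = terms
        return self

    def top_terms(self, k: int = 10) -> pd.DataFrame:
        """The k highest-PTI rows (ties at the boundary included)."""
        if not hasattr(self, "table_"):
            raise ValueError("TriggerIndexRanker is not fitted")
        if k < 1:
            raise ValueError("k must be >= 1")
        if len(self.table_) <= k:
            return self.table_.copy()
        cut = self.table_["pti"].iloc[k - 1]
        return self.table_[self.table_["pti"] >= cut].reset_index(drop=True)


def write_trigger_table(table: pd.DataFrame, path) -> None:
    """Export the trigger table as TSV in report column order."""
    table[TABLE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_frequency_table(path) -> pd.DataFrame:
    """Read a hand-written term/freq_early/freq_late table (TSV/CSV)."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    table = pd.read_csv(path, sep=sep)
    required = {"term", "freq_early", "freq_late"}
    if not required <= set(table.columns):
        raise ValueError(f"frequency table needs columns {sorted(required)}")
    return table
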