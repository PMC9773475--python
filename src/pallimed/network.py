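"""Term co-occurrence matrices and thresholded drug networks.

From a binary patient x term matrix A, the co-occurrence matrix is
the exact integer product C = A'A: entry (i, j) counts patients whose
records mention both term i and term j (the diagonal is each term's
document frequency). Edge weights for the network — the
*co-correlation* between two terms' patient-indicator columns — can
be computed three ways:

``phi`` (default)
    Pearson correlation of the two binary columns, from the 2x2
    contingency table: (n11*n00 - n10*n01) / sqrt(r1*r0*c1*c0).
    Constant columns have no defined phi and contribute no edge.
``cosine``
    n11 / sqrt(f_i * f_j), in [0, 1].
``jaccard``
    n11 / (f_i + f_j - n11), in [0, 1].

Networks keep terms whose group frequency reaches ``min_frequency``
(3 for the early group, 2 for the late group by convention here) and
draw an undirected edge where the co-correlation is defined and at
least ``corr_threshold`` (0.5 = "moderate co-occurrence"). Isolated
nodes are retained; node size in plots reflects term frequency.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .extract import DocumentTermMatrix

__all__ = [
    "CooccurrenceMatrix",
    "CocorrelationMatrix",
    "TermNetwork",
    "cooccurrence",
    "cocorrelation",
    "build_network",
    "top_cooccurrences",
    "export_network",
    "load_network",
    "plot_network",
    "CooccurrenceNetworkBuilder",
    "METHODS",
]

METHODS = ("phi", "cosine", "jaccard")


@dataclass
class CooccurrenceMatrix:
    """Symmetric term x term joint-appearance counts (C = A'A)."""

    terms: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.terms), len(self.terms)):
            raise ValueError("counts shape inconsistent with terms")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.terms, columns=self.terms)

    def pair(self, a: str, b: str) -> int:
        return int(self.counts[self.terms.index(a), self.terms.index(b)])


@dataclass
class CocorrelationMatrix:
    """Symmetric pairwise co-correlations; NaN marks undefined entries."""

    terms: list[str]
    values: np.ndarray
    method: str = "phi"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.terms), len(self.terms)):
            raise ValueError("values shape inconsistent with terms")
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.terms, columns=self.terms)

    def pair(self, a: str, b: str) -> float:
        return float(self.values[self.terms.index(a), self.terms.index(b)])


@dataclass
class TermNetwork:
    """Thresholded undirected drug network.

    ``graph`` is a networkx Graph whose nodes carry a ``frequency``
    attribute and whose edges carry ``cocorrelation``; thresholds and
    the correlation method used are stored as graph attributes.
    """

    graph: nx.Graph
    min_frequency: int
    corr_threshold: float
    method: str = "phi"

    @property
    def nodes(self) -> list[tuple[str, int]]:
        return sorted(
            (t, int(d["frequency"])) for t, d in self.graph.nodes(data=True)
        )

    @property
    def edges(self) -> list[tuple[str, str, float]]:
        out = []
        for a, b, d in self.graph.edges(data=True):
            a, b = sorted((a, b))
            out.append((a, b, float(d["cocorrelation"])))
        return sorted(out)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TermNetwork):
            return NotImplemented
        return (
            self.nodes == other.nodes
            and len(self.edges) == len(other.edges)
            and all(
                a == a2 and b == b2 and abs(v - v2) < 1e-9
                for (a, b, v), (a2, b2, v2) in zip(self.edges, other.edges)
            )
            and self.min_frequency == other.min_frequency
            and abs(self.corr_threshold - other.corr_threshold) < 1e-9
            and self.method == other.method
        )


def cooccurrence(dtm: DocumentTermMatrix) -> CooccurrenceMatrix:
    """Exact integer co-occurrence matrix C = A'A.

    In binary mode entry (i, j) is the number of patients mentioning
    both terms, and the diagonal is each term's document frequency.
    """
    if dtm.values.size == 0 and len(dtm.terms) == 0:
        raise ValueError("empty document-term matrix")
    a = dtm.values
    return CooccurrenceMatrix(list(dtm.terms), a.T @ a)


def _phi_matrix(b: np.ndarray) -> np.ndarray:
    """Pairwise phi coefficients of binary columns via 2x2 counts."""
    n = b.shape[0]
    n11 = b.T @ b
    colsum = b.sum(axis=0)
    n10 = colsum[:, None] - n11
    n01 = colsum[None, :] - n11
    n00 = n - n11 - n10 - n01
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = np.sqrt(
            (n11 + n10) * (n01 + n00) * (n11 + n01) * (n10 + n00), dtype=float
        )
        phi = (n11 * n00 - n10 * n01) / denom
    phi[denom == 0] = np.nan
    return phi


def cocorrelation(
    dtm: DocumentTermMatrix, method: str = "phi"
) -> CocorrelationMatrix:
    """Pairwise co-correlation of the terms' patient-indicator columns.

    Count-mode matrices are binarized first (with a warning); the
    similarity is defined on presence/absence. Zero-variance columns
    yield NaN under ``phi`` and are excluded from network edges.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    if dtm.mode != "binary":
        warnings.warn(
            "co-correlation is defined on presence/absence; binarizing "
            "count-mode matrix", stacklevel=2,
        )
        dtm = dtm.binarize()
    b = dtm.values.astype(np.int64)
    if method == "phi":
        values = _phi_matrix(b)
    else:
        n11 = (b.T @ b).astype(float)
        freq = b.sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            if method == "cosine":
                values = n11 / np.sqrt(np.outer(freq, freq))
            else:  # jaccard
                union = freq[:, None] + freq[None, :] - n11
                values = n11 / union
        values[np.outer(freq, freq) == 0] = np.nan
    return CocorrelationMatrix(list(dtm.terms), values, method=method)


def build_network(
    dtm: DocumentTermMatrix,
    corr: Optional[CocorrelationMatrix] = None,
    min_frequency: int = 3,
    corr_threshold: float = 0.5,
    method: str = "phi",
) -> TermNetwork:
    """Build the thresholded term network for one group's matrix.

    Nodes: terms whose frequency (column sum of ``dtm``) is at least
    ``min_frequency``; isolated nodes are retained. Edges: pairs of
    retained terms with a *defined* co-correlation >= threshold;
    endpoints stored in lexicographic order.
    """
    if corr is None:
        corr = cocorrelation(dtm, method=method)
    if list(corr.terms) != list(dtm.terms):
        raise ValueError("correlation matrix terms do not match the DTM")
    freqs = dtm.term_frequencies()
    keep = [t for t in dtm.terms if freqs[t] >= min_frequency]

    graph = nx.Graph(
        min_frequency=int(min_frequency),
        corr_threshold=float(corr_threshold),
        method=corr.method,
    )
    for term in keep:
        graph.add_node(term, frequency=int(freqs[term]))
    index = {t: i for i, t in enumerate(corr.terms)}
    for i, a in enumerate(keep):
        for b in keep[i + 1 :]:
            v = corr.values[index[a], index[b]]
            if np.isfinite(v) and v >= corr_threshold:
                x, y = sorted((a, b))
                graph.add_edge(x, y, cocorrelation=float(v))
    return TermNetwork(graph, int(min_frequency), float(corr_threshold), corr.method)


def top_cooccurrences(corr: CocorrelationMatrix, k: int = 10) -> list[tuple[str, str, float]]:
    """The k term pairs with highest defined co-correlation.

    Descending by value; ties broken lexicographically by pair. If
    fewer than k pairs are defined, all are returned.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    pairs = []
    terms = corr.terms
    for i in range(len(terms)):
        for j in range(i + 1, len(terms)):
            v = corr.values[i, j]
            if np.isfinite(v):
                a, b = sorted((terms[i], terms[j]))
                pairs.append((a, b, float(v)))
    pairs.sort(key=lambda p: (-p[2], p[0], p[1]))
    return pairs[:k]


def export_network(
    net: TermNetwork, path: Union[str, Path], fmt: Optional[str] = None
) -> None:
    """Write a network as GraphML or a 3-column edge TSV.

    GraphML keeps node ``frequency``, edge ``cocorrelation`` and the
    thresholds as typed attributes and round-trips losslessly through
    :func:`load_network`. ``edge-tsv`` writes (term_a, term_b,
    cocorrelation) plus a sidecar ``<stem>.nodes.tsv`` node table
    with a commented metadata block.
    """
    path = Path(path)
    if fmt is None:
        fmt = "graphml" if path.suffix == ".graphml" else "edge-tsv"
    if fmt == "graphml":
        nx.write_graphml(net.graph, path)
    elif fmt == "edge-tsv":
        with path.open("w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t")
            writer.writerow(["term_a", "term_b", "cocorrelation"])
            for a, b, v in net.edges:
                writer.writerow([a, b, f"{v:.6g}"])
        nodes_path = path.with_suffix(".nodes.tsv")
        with nodes_path.open("w", encoding="utf-8", newline="") as fh:
            fh.write(
                f"# min_frequency={net.min_frequency}\t"
                f"corr_threshold={net.corr_threshold}\tmethod={net.method}\n"
            )
            writer = csv.writer(fh, delimiter="\t")
            writer.writerow(["term", "frequency"])
            for term, freq in net.nodes:
                writer.writerow([term, freq])
    else:
        raise ValueError(f"unknown format {fmt!r}")


def load_network(path: Union[str, Path]) -> TermNetwork:
    """Re-import a GraphML file written by :func:`export_network`."""
    graph = nx.read_graphml(Path(path))
    graph = nx.relabel_nodes(graph, str)
    meta = graph.graph
    return TermNetwork(
        graph,
        min_frequency=int(meta.get("min_frequency", 1)),
        corr_threshold=float(meta.get("corr_threshold", 0.5)),
        method=str(meta.get("method", "phi")),
    )


def plot_network(net: TermNetwork, path: Union[str, Path], seed: int = 0) -> None:
    """Basic matplotlib rendering: dot size ~ frequency, edge width ~
    co-correlation strength."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    graph = net.graph
    pos = nx.spring_layout(graph, seed=seed)
    freqs = np.array([graph.nodes[n].get("frequency", 1) for n in graph.nodes]) if graph.nodes else np.array([])
    widths = [2 * graph.edges[e]["cocorrelation"] for e in graph.edges]
    fig, ax = plt.subplots(figsize=(8, 8))
    nx.draw_networkx(
        graph, pos=pos, ax=ax, with_labels=True, font_size=8,
        node_size=50 * freqs if freqs.size else 50, width=widths,
        node_color="#7fb3d5", edge_color="#2e86c1",
    )
    ax.set_axis_off()
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


class CooccurrenceNetworkBuilder(BaseEstimator):
    """Fit-style wrapper producing co-occurrence structures from a DTM.

    Parameters
    ----------
    method : {"phi", "cosine", "jaccard"}, default "phi"
    min_frequency : int, default 3
    corr_threshold : float, default 0.5

    Attributes
    ----------
    cooccurrence_ : CooccurrenceMatrix
    cocorrelation_ : CocorrelationMatrix
    network_ : TermNetwork
    """

    def __init__(
        self,
        method: str = "phi",
        min_frequency: int = 3,
        corr_threshold: float = 0.5,
    ):
        self.method = method
        self.min_frequency = min_frequency
        self.corr_threshold = corr_threshold

    def fit(self, X: DocumentTermMatrix, y=None) -> "CooccurrenceNetworkBuilder":
        if not isinstance(X, DocumentTermMatrix):
            raise TypeError("CooccurrenceNetworkBuilder expects a DocumentTermMatrix")
        self.cooccurrence_ = cooccurrence(X)
        self.cocorrelation_ = cocorrelation(X, method=self.method)
        self.network_ = build_network(
            X,
            corr=self.cocorrelation_,
            min_frequency=self.min_frequency,
            corr_threshold=self.corr_threshold,
        )
        return self
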