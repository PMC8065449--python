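"""Jaccard co-occurrence networks: similarity, filtering, clustering, depletion.

For two terms with posting sets of sizes A and B sharing C documents, the
Jaccard (Tanimoto) similarity is

    K = C / (A + B - C),        0 <= K <= 1,

i.e. |intersection| / |union|. A semantic network keeps a node for every
term supported by at least ``min_docs`` documents and an edge for every
co-occurring pair whose K strictly exceeds ``k_threshold``. Clusters are
the connected components of the retained graph. "Information depletion"
iteratively removes the most frequent — hence least informative — terms so
rarer relationships become visible.

K is kept as an exact ratio of integers (``fractions.Fraction``) so that
threshold comparisons and closed-form checks are free of floating-point
artifacts; serialized output rounds to 6 decimal places. A float threshold
is interpreted by its decimal literal (0.2 means exactly 1/5).
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from fractions import Fraction
from itertools import combinations
from pathlib import Path
from typing import AbstractSet, Iterable

import networkx as nx
import pandas as pd

from .tagging import IncidenceIndex

__all__ = [
    "CooccurrenceEdge",
    "SemanticNetwork",
    "ClusterSet",
    "jaccard",
    "build_network",
    "extract_clusters",
    "deplete",
    "write_clusters_tsv",
]


def _as_fraction(threshold: float | int | str | Fraction) -> Fraction:
    if isinstance(threshold, Fraction):
        return threshold
    if isinstance(threshold, float):
        return Fraction(str(threshold))
    return Fraction(threshold)


def jaccard(set_a: AbstractSet, set_b: AbstractSet) -> float:
    """Jaccard similarity K = C/(A + B - C) of two PMID sets.

    Raises ``ZeroDivisionError`` if both sets are empty (K is 0/0).
    """
    if not set_a and not set_b:
        raise ZeroDivisionError("Jaccard undefined for two empty sets (0/0)")
    c = len(set_a & set_b)
    return c / (len(set_a) + len(set_b) - c)


@dataclass(frozen=True)
class CooccurrenceEdge:
    """One co-occurrence: term pair with their document counts A, B, C and K.

    ``term_u < term_v`` lexicographically; ``count_u``/``count_v`` are the
    posting sizes A and B, ``count_both`` the shared-document count C.
    """

    term_u: str
    term_v: str
    count_u: int
    count_v: int
    count_both: int

    def __post_init__(self):
        if not self.term_u < self.term_v:
            raise ValueError(f"edge endpoints must satisfy term_u < term_v: {self.term_u!r}, {self.term_v!r}")
        if not 0 <= self.count_both <= min(self.count_u, self.count_v):
            raise ValueError(f"invalid counts A={self.count_u} B={self.count_v} C={self.count_both}")
        if self.count_u + self.count_v - self.count_both <= 0:
            raise ValueError("edge with empty union")

    @property
    def jaccard_exact(self) -> Fraction:
        return Fraction(self.count_both, self.count_u + self.count_v - self.count_both)

    @property
    def jaccard(self) -> float:
        return float(self.jaccard_exact)


@dataclass
class SemanticNetwork:
    """Thresholded co-occurrence graph.

    ``nodes`` maps term ID -> (display label, document count); ``params``
    records the (min_docs, k_threshold) pair the network was built with.
    """

    nodes: dict[str, tuple[str, int]]
    edges: list[CooccurrenceEdge]
    params: tuple[int, float]

    def __post_init__(self):
        for e in self.edges:
            if e.term_u not in self.nodes or e.term_v not in self.nodes:
                raise ValueError(f"edge {e.term_u}-{e.term_v} references a missing node")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_networkx(self) -> nx.Graph:
        from .corpus_io import _to_nx

        return _to_nx(self)


@dataclass
class ClusterSet:
    """Connected-component clusters (>= 2 members each) plus isolated nodes."""

    clusters: list[list[str]]
    unclustered: list[str]

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def membership(self) -> dict[str, int]:
        """Term -> cluster index (isolated nodes get -1)."""
        out = {t: i for i, members in enumerate(self.clusters) for t in members}
        out.update({t: -1 for t in self.unclustered})
        return out


def build_network(
    index: IncidenceIndex,
    min_docs: int = 5,
    k_threshold: float = 0.2,
    labels: dict[str, str] | None = None,
) -> SemanticNetwork:
    """Build the thresholded co-occurrence network from an incidence index.

    Nodes: terms posted to at least ``min_docs`` documents (inclusive).
    Edges: unordered node pairs sharing at least one document whose Jaccard
    similarity strictly exceeds ``k_threshold``. Pairs are enumerated
    through the inverted document->terms map, so disjoint pairs are never
    visited — this is what keeps 100k-abstract corpora tractable.
    """
    if min_docs < 1:
        raise ValueError("min_docs must be >= 1")
    thr = _as_fraction(k_threshold)
    if not 0 <= thr < 1:
        raise ValueError("k_threshold must be in [0, 1)")

    sizes = {t: len(p) for t, p in index.postings.items()}
    node_terms = {t for t, n in sizes.items() if n >= min_docs}

    doc_terms: dict[str, list[str]] = {}
    for term in node_terms:
        for pmid in index.postings[term]:
            doc_terms.setdefault(pmid, []).append(term)

    pair_counts: Counter[tuple[str, str]] = Counter()
    for terms in doc_terms.values():
        if len(terms) > 1:
            pair_counts.update(combinations(sorted(terms), 2))

    edges = []
    for (u, v), c in sorted(pair_counts.items()):
        a, b = sizes[u], sizes[v]
        if Fraction(c, a + b - c) > thr:
            edges.append(CooccurrenceEdge(term_u=u, term_v=v, count_u=a, count_v=b, count_both=c))

    labels = labels or {}
    nodes = {t: (labels.get(t, t), sizes[t]) for t in sorted(node_terms)}
    return SemanticNetwork(nodes=nodes, edges=edges, params=(min_docs, float(thr)))


def extract_clusters(network: SemanticNetwork) -> ClusterSet:
    """Connected components with >= 2 nodes, largest first.

    Components are ordered by descending size, then lexicographically by
    their first member; members within a cluster are sorted. Isolated nodes
    are reported separately as unclustered.
    """
    g = nx.Graph()
    g.add_nodes_from(network.nodes)
    g.add_edges_from((e.term_u, e.term_v) for e in network.edges)
    comps = [sorted(c) for c in nx.connected_components(g)]
    clusters = sorted((c for c in comps if len(c) >= 2), key=lambda c: (-len(c), c[0]))
    unclustered = sorted(t for c in comps if len(c) == 1 for t in c)
    return ClusterSet(clusters=clusters, unclustered=unclustered)


def deplete(index: IncidenceIndex, k: int) -> IncidenceIndex:
    """Remove the k most frequent terms (ties broken lexicographically).

    All remaining postings are unchanged. ``k`` larger than the vocabulary
    removes everything, with a warning.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    if k > len(index.postings):
        warnings.warn(
            f"deplete(k={k}) exceeds the {len(index.postings)}-term vocabulary: removing all terms",
            stacklevel=2,
        )
    ranked = sorted(index.postings, key=lambda t: (-len(index.postings[t]), t))
    doomed = set(ranked[:k])
    return IncidenceIndex(
        namespace=index.namespace,
        postings={t: p for t, p in index.postings.items() if t not in doomed},
        scanned_pmids=index.scanned_pmids,
    )


def write_clusters_tsv(clusters: ClusterSet, path: str | Path) -> None:
    """Cluster report TSV: ``cluster_id  size  members`` (members comma-delimited)."""
    rows = [
        {"cluster_id": i + 1, "size": len(members), "members": ",".join(members)}
        for i, members in enumerate(clusters.clusters)
    ]
    if clusters.unclustered:
        rows.append({"cluster_id": 0, "size": len(clusters.unclustered),
                     "members": ",".join(clusters.unclustered)})
    pd.DataFrame(rows, columns=["cluster_id", "size", "members"]).to_csv(path, sep="\t", index=False)
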