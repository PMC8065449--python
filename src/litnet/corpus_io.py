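"""Readers and writers for corpora, vocabularies, association tables and networks.

The on-disk formats are deliberately plain: MEDLINE/PubMed XML for real
abstract dumps, a five-column TSV for desk-scale corpora, tab-separated
synonym lists for gene dictionaries, a delimited gene-disease association
(GDA) table, and GraphML / GML / edge-list TSV for the networks.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd
from lxml import etree

from .errors import CorpusError, SchemaError

logger = logging.getLogger(__name__)

__all__ = [
    "Document",
    "TermDictionary",
    "GeneDiseaseAssociations",
    "read_medline_xml",
    "read_corpus_tsv",
    "write_corpus_tsv",
    "load_gene_dictionary",
    "load_gda_table",
    "write_graphml",
    "read_graphml",
    "write_gml",
    "write_edgelist_tsv",
]


@dataclass(frozen=True)
class Document:
    """One abstract: PMID, title, abstract text and curator-assigned MeSH descriptors.

    ``mesh_terms`` holds descriptor names only (no qualifiers), deduplicated;
    order is not meaningful. ``abstract`` may be empty — records without an
    abstract still contribute their MeSH terms to descriptor networks.
    """

    pmid: str
    title: str = ""
    abstract: str = ""
    mesh_terms: tuple[str, ...] = ()
    year: int | None = None

    def __post_init__(self):
        if not self.pmid:
            raise CorpusError("Document requires a non-empty pmid")
        # dedupe while keeping first-seen order
        seen: dict[str, None] = dict.fromkeys(self.mesh_terms)
        object.__setattr__(self, "mesh_terms", tuple(seen))


@dataclass
class TermDictionary:
    """A controlled vocabulary: canonical ID -> (label, synonyms).

    After loading, no synonym within the namespace maps to two canonical IDs;
    ambiguous synonyms are removed from every claimant (and logged), since a
    string that cannot be attributed to a single term would corrupt the
    per-term document counts downstream.
    """

    namespace: str
    entries: dict[str, tuple[str, tuple[str, ...]]] = field(default_factory=dict)

    def __post_init__(self):
        if self.namespace not in {"gene", "mesh", "custom"}:
            raise ValueError(f"unknown namespace {self.namespace!r}")

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.entries

    def label(self, term_id: str) -> str:
        return self.entries[term_id][0]

    def synonyms(self, term_id: str) -> tuple[str, ...]:
        return self.entries[term_id][1]

    def strings(self, term_id: str) -> tuple[str, ...]:
        """Canonical label plus synonyms, the full match target list."""
        label, syns = self.entries[term_id]
        return (label, *syns)


@dataclass
class GeneDiseaseAssociations:
    """DisGeNET-style rows of (gene symbol, disease ID, disease name, PMID).

    Exact-duplicate rows are collapsed at load time; every row carries a
    non-empty PMID, because the PMID set per gene is what the co-occurrence
    networks are built from.
    """

    table: pd.DataFrame  # columns: gene, disease_id, disease_name, pmid

    COLUMNS = ("gene", "disease_id", "disease_name", "pmid")

    def __post_init__(self):
        missing = [c for c in self.COLUMNS if c not in self.table.columns]
        if missing:
            raise SchemaError(f"GDA table missing columns: {missing}")
        self.table = self.table.loc[:, list(self.COLUMNS)].drop_duplicates().reset_index(drop=True)
        if (self.table["pmid"].astype(str).str.len() == 0).any():
            raise SchemaError("GDA table contains rows with empty PMID")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self.table["gene"])

    def filter_disease(self, disease_id: str) -> "GeneDiseaseAssociations":
        return GeneDiseaseAssociations(self.table[self.table["disease_id"] == disease_id].copy())


# ---------------------------------------------------------------------------
# corpus readers


def _check_unique_pmids(docs: Sequence[Document]) -> None:
    dupes = [p for p, n in Counter(d.pmid for d in docs).items() if n > 1]
    if dupes:
        raise CorpusError(f"duplicate PMIDs in corpus: {sorted(dupes)}")


def read_medline_xml(path: str | Path) -> list[Document]:
    """Parse a MEDLINE/PubMed ``PubmedArticleSet`` file into Documents.

    MeSH ``DescriptorName`` values are captured; qualifiers (subheadings) are
    dropped. Records lacking an abstract yield a Document with an empty
    abstract. Malformed XML raises :class:`CorpusError` naming the position;
    duplicate PMIDs raise :class:`CorpusError` listing them.
    """
    path = Path(path)
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        line, col = exc.position
        try:
            offset = sum(len(l) + 1 for l in path.read_bytes().split(b"\n")[: line - 1]) + col
        except OSError:
            offset = col
        raise CorpusError(
            f"malformed XML in {path} at line {line}, column {col} (byte offset {offset}): {exc.msg}"
        ) from exc

    docs: list[Document] = []
    for article in tree.iter("PubmedArticle"):
        citation = article.find("MedlineCitation")
        if citation is None:
            continue
        pmid = citation.findtext("PMID", default="").strip()
        title = citation.findtext("Article/ArticleTitle", default="") or ""
        abstract_parts = [
            (node.text or "") + "".join(etree.tostring(c, method="text", encoding="unicode") for c in node)
            for node in citation.findall("Article/Abstract/AbstractText")
        ]
        abstract = " ".join(p.strip() for p in abstract_parts if p and p.strip())
        mesh = tuple(
            dn.text.strip()
            for dn in citation.findall("MeshHeadingList/MeshHeading/DescriptorName")
            if dn.text and dn.text.strip()
        )
        year_text = citation.findtext("Article/Journal/JournalIssue/PubDate/Year")
        year = int(year_text) if year_text and year_text.strip().isdigit() else None
        docs.append(Document(pmid=pmid, title=title.strip(), abstract=abstract, mesh_terms=mesh, year=year))

    _check_unique_pmids(docs)
    return docs


_CORPUS_COLUMNS = ["pmid", "title", "abstract", "mesh_terms", "year"]


def read_corpus_tsv(path: str | Path) -> list[Document]:
    """Read a tabular corpus: ``pmid  title  abstract  mesh_terms  year``.

    ``mesh_terms`` is pipe-delimited; an empty cell means no descriptors.
    Same contract as :func:`read_medline_xml`.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _CORPUS_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"corpus TSV {path} missing columns: {missing}")
    docs = []
    for row in df.itertuples(index=False):
        mesh = tuple(t for t in str(row.mesh_terms).split("|") if t)
        year = int(row.year) if str(row.year).strip().isdigit() else None
        docs.append(
            Document(pmid=str(row.pmid), title=str(row.title), abstract=str(row.abstract),
                     mesh_terms=mesh, year=year)
        )
    _check_unique_pmids(docs)
    return docs


def write_corpus_tsv(docs: Iterable[Document], path: str | Path) -> None:
    rows = [
        {
            "pmid": d.pmid,
            "title": d.title,
            "abstract": d.abstract,
            "mesh_terms": "|".join(d.mesh_terms),
            "year": "" if d.year is None else d.year,
        }
        for d in docs
    ]
    pd.DataFrame(rows, columns=_CORPUS_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# vocabularies and association tables


def load_gene_dictionary(path: str | Path) -> TermDictionary:
    """Load a gene dictionary from tab-separated lines: symbol, then synonyms.

    Synonyms claimed by two or more symbols are ambiguous and removed from
    all claimants (logged as warnings). A synonym that collides with another
    entry's canonical symbol is likewise dropped — the canonical wins.
    """
    path = Path(path)
    raw: dict[str, list[str]] = {}
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), start=1):
        if not line.strip():
            continue
        parts = [p.strip() for p in line.split("\t")]
        symbol = parts[0]
        if not symbol:
            raise CorpusError(f"{path}:{lineno}: blank canonical symbol")
        if symbol in raw:
            raise CorpusError(f"{path}:{lineno}: duplicate canonical symbol {symbol!r}")
        synonyms = [s for s in parts[1:] if s]
        if any(not s for s in parts[1:]):
            logger.warning("%s:%d: empty synonym field ignored for %s", path, lineno, symbol)
        raw[symbol] = synonyms
    if not raw:
        raise CorpusError(f"gene dictionary {path} is empty")

    claims: dict[str, set[str]] = {}
    for symbol, syns in raw.items():
        for s in syns:
            claims.setdefault(s, set()).add(symbol)
    ambiguous = {s for s, owners in claims.items() if len(owners) > 1}
    # a synonym equal to another entry's canonical symbol: the canonical wins
    shadowing = {s for s, owners in claims.items() if s in raw and owners != {s}}
    drop = ambiguous | shadowing
    for s in sorted(ambiguous):
        logger.warning("ambiguous synonym %r claimed by %s — dropped from all", s, sorted(claims[s]))
    for s in sorted(shadowing - ambiguous):
        logger.warning("synonym %r collides with canonical symbol %r — dropped", s, s)

    entries = {
        symbol: (symbol, tuple(s for s in syns if s not in drop and s != symbol))
        for symbol, syns in raw.items()
    }
    return TermDictionary(namespace="gene", entries=entries)


def load_gda_table(
    path: str | Path,
    *,
    sep: str = "\t",
    gene_col: str = "gene",
    disease_id_col: str = "disease_id",
    disease_name_col: str = "disease_name",
    pmid_col: str = "pmid",
) -> GeneDiseaseAssociations:
    """Load a gene-disease association table; column names are configurable.

    Exact duplicates are collapsed and the retained row count is logged.
    """
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    rename = {gene_col: "gene", disease_id_col: "disease_id",
              disease_name_col: "disease_name", pmid_col: "pmid"}
    missing = [c for c in rename if c not in df.columns]
    if missing:
        raise SchemaError(f"GDA table {path} missing columns: {missing}")
    gdas = GeneDiseaseAssociations(df.rename(columns=rename))
    if len(gdas) == 0:
        logger.warning("GDA table %s is empty", path)
    logger.info("loaded %d unique associations from %s", len(gdas), path)
    return gdas


# ---------------------------------------------------------------------------
# network serialization


def _to_nx(network) -> nx.Graph:
    g = nx.Graph()
    g.graph["min_docs"] = network.params[0]
    g.graph["k_threshold"] = float(network.params[1])
    for term, (label, count) in network.nodes.items():
        g.add_node(term, label=label, doc_count=int(count))
    for e in network.edges:
        g.add_edge(
            e.term_u, e.term_v,
            jaccard=round(float(e.jaccard), 6),
            count_both=int(e.count_both),
            count_u=int(e.count_u),
            count_v=int(e.count_v),
        )
    return g


def write_graphml(network, path: str | Path) -> None:
    """Write a semantic network as GraphML.

    Node attributes ``label`` and ``doc_count``; edge attributes ``jaccard``
    (6 decimal places), ``count_both``, ``count_u``, ``count_v``. The file
    round-trips losslessly through :func:`read_graphml`.
    """
    nx.write_graphml(_to_nx(network), str(path))


def read_graphml(path: str | Path):
    """Read a GraphML file written by :func:`write_graphml` back into a SemanticNetwork."""
    from .network import CooccurrenceEdge, SemanticNetwork

    g = nx.read_graphml(str(path))
    nodes = {n: (d.get("label", n), int(d["doc_count"])) for n, d in g.nodes(data=True)}
    edges = []
    for u, v, d in g.edges(data=True):
        u, v = sorted((u, v))
        edges.append(
            CooccurrenceEdge(term_u=u, term_v=v, count_u=int(d["count_u"]),
                             count_v=int(d["count_v"]), count_both=int(d["count_both"]))
        )
    edges.sort(key=lambda e: (e.term_u, e.term_v))
    return SemanticNetwork(
        nodes=nodes,
        edges=edges,
        params=(int(g.graph.get("min_docs", 1)), float(g.graph.get("k_threshold", 0.0))),
    )


def write_gml(network, path: str | Path) -> None:
    nx.write_gml(_to_nx(network), str(path))


def write_edgelist_tsv(network, path: str | Path) -> None:
    """Edge-list TSV: ``u  v  A  B  C  K`` with K to 6 decimal places."""
    rows = [
        {
            "u": e.term_u, "v": e.term_v,
            "A": e.count_u, "B": e.count_v, "C": e.count_both,
            "K": f"{float(e.jaccard):.6f}",
        }
        for e in network.edges
    ]
    pd.DataFrame(rows, columns=["u", "v", "A", "B", "C", "K"]).to_csv(path, sep="\t", index=False)
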