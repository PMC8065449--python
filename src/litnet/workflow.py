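"""The five-step set-intersection workflow and gene-list comparisons.

Notation (sets of identifiers):

* ``PM``  — PMIDs of the corpus; ``PP`` — an optional user-supplied PMID
  allow-list (e.g. a most-cited-author sample).
* ``UP``  — gene IDs of the dictionary; ``DGN`` — gene IDs of the
  gene-disease association table.
* A disease query (a MeSH descriptor match or a PMID-list file) restricts
  each to its query subset: ``PMOb``, ``PPOb``, ``UPOb``, ``DGNOb``.

``UPOb ∩ DGNOb`` is the automated-vs-expert gene intersection that feeds
the cluster analysis; :func:`compare_gene_lists` reports recall, Jaccard
similarity and both asymmetric differences so any convention for "percent
difference between the lists" can be read off.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

from .corpus_io import (
    Document,
    GeneDiseaseAssociations,
    TermDictionary,
    load_gda_table,
    load_gene_dictionary,
    read_corpus_tsv,
    read_medline_xml,
    write_edgelist_tsv,
    write_graphml,
)
from .errors import PipelineError, ValidationError
from .network import build_network, extract_clusters, jaccard, write_clusters_tsv
from .tagging import IncidenceIndex, mesh_index, restrict_index, tag_corpus, write_index_tsv

logger = logging.getLogger(__name__)

__all__ = [
    "WorkflowSets",
    "RunConfig",
    "derive_workflow_sets",
    "intersect_gene_sets",
    "gda_incidence",
    "gene_reference_counts",
    "compare_gene_lists",
    "run_pipeline",
]


@dataclass(frozen=True)
class WorkflowSets:
    """The base sets and their query-restricted counterparts.

    Invariants: PPOb ⊆ PP, PMOb ⊆ PM, UPOb ⊆ UP, DGNOb ⊆ DGN.
    """

    PM: frozenset[str]
    UP: frozenset[str]
    DGN: frozenset[str]
    PMOb: frozenset[str]
    UPOb: frozenset[str]
    DGNOb: frozenset[str]
    PP: frozenset[str] | None = None
    PPOb: frozenset[str] | None = None

    def __post_init__(self):
        if not (self.PMOb <= self.PM and self.UPOb <= self.UP and self.DGNOb <= self.DGN):
            raise ValidationError("restricted sets must be subsets of their base sets")
        if (self.PP is None) != (self.PPOb is None):
            raise ValidationError("PP and PPOb must both be present or both absent")
        if self.PP is not None and not self.PPOb <= self.PP:
            raise ValidationError("PPOb must be a subset of PP")


def derive_workflow_sets(
    corpus: Sequence[Document],
    dictionary: TermDictionary,
    gdas: GeneDiseaseAssociations,
    query_pmids: Iterable[str],
    pp_pmids: Iterable[str] | None = None,
    fields: Iterable[str] = ("title", "abstract"),
    disease_filter: str | None = None,
    gene_index: IncidenceIndex | None = None,
) -> WorkflowSets:
    """Run the consecutive set intersections over a corpus and its vocabularies.

    ``query_pmids`` identifies the disease-relevant documents (for example
    the PMIDs whose MeSH descriptors include "Obesity"). ``UPOb`` is the
    set of dictionary genes tagged in at least one query document. The GDA
    table is assumed pre-filtered to the disease unless ``disease_filter``
    names a disease ID. Pass a precomputed ``gene_index`` to skip re-tagging.
    """
    query = frozenset(query_pmids)
    if not query:
        raise ValidationError("empty query_pmids: the workflow is undefined without a query")

    pm = frozenset(d.pmid for d in corpus)
    up = frozenset(dictionary.entries)
    if gene_index is None:
        gene_index = tag_corpus(corpus, dictionary, fields=fields)
    restricted = restrict_index(gene_index, query)
    up_ob = frozenset(restricted.postings)

    dgn_table = gdas.filter_disease(disease_filter) if disease_filter else gdas
    dgn = frozenset(gdas.genes)
    dgn_ob = frozenset(dgn_table.genes)

    pp = frozenset(pp_pmids) if pp_pmids is not None else None
    return WorkflowSets(
        PM=pm,
        UP=up,
        DGN=dgn,
        PMOb=pm & query,
        UPOb=up_ob,
        DGNOb=dgn_ob,
        PP=pp,
        PPOb=(pp & query) if pp is not None else None,
    )


def intersect_gene_sets(up_ob: Iterable[str], dgn_ob: Iterable[str]) -> list[str]:
    """Plain set intersection, returned sorted for determinism."""
    return sorted(frozenset(up_ob) & frozenset(dgn_ob))


def gda_incidence(gdas: GeneDiseaseAssociations) -> IncidenceIndex:
    """Incidence index gene -> supporting PMIDs, straight from the GDA rows.

    Feeding this into :func:`litnet.network.build_network` reproduces the
    expert-side gene network construction.
    """
    postings: dict[str, set[str]] = {}
    for row in gdas.table.itertuples(index=False):
        postings.setdefault(row.gene, set()).add(row.pmid)
    all_pmids = frozenset(gdas.table["pmid"]) if len(gdas) else frozenset()
    return IncidenceIndex(
        namespace="gene",
        postings={g: frozenset(p) for g, p in postings.items()},
        scanned_pmids=all_pmids,
    )


def gene_reference_counts(
    gdas: GeneDiseaseAssociations, disease_filter: str | None = None
) -> pd.DataFrame:
    """Per-gene distinct PMID and disease counts, descending by PMID count.

    With ``disease_filter`` the PMID count is restricted to that disease's
    rows while the disease count still reflects the full table, mirroring
    how per-gene reference counts are reported against a disease-specific
    query.
    """
    t = gdas.table
    n_diseases = t.groupby("gene")["disease_id"].nunique()
    scoped = t[t["disease_id"] == disease_filter] if disease_filter else t
    n_pmids = scoped.groupby("gene")["pmid"].nunique()
    out = (
        pd.DataFrame({"gene": n_pmids.index, "n_pmids": n_pmids.values})
        .assign(n_diseases=lambda d: d["gene"].map(n_diseases).astype(int))
        .sort_values(["n_pmids", "gene"], ascending=[False, True], kind="mergesort")
        .reset_index(drop=True)
    )
    return out[["gene", "n_pmids", "n_diseases"]]


def compare_gene_lists(
    automated: Iterable[str], reference: Iterable[str]
) -> dict[str, object]:
    """Compare an automated gene list against an expert reference panel.

    Returns recall = |automated ∩ reference| / |reference|, the Jaccard
    similarity of the two sets, and the sorted asymmetric differences.
    """
    auto = frozenset(automated)
    ref = frozenset(reference)
    if not ref:
        raise ValidationError("reference gene list is empty")
    return {
        "recall": len(auto & ref) / len(ref),
        "jaccard": jaccard(auto, ref) if auto or ref else 0.0,
        "only_automated": sorted(auto - ref),
        "only_reference": sorted(ref - auto),
    }


# ---------------------------------------------------------------------------
# pipeline orchestration


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    ``query`` is either a MeSH descriptor name (documents carrying it form
    the query set) or the path of a PMID-list file (one PMID per line).
    """

    corpus: str
    dictionary: str
    output_dir: str
    gda: str | None = None
    query: str | None = None
    pp_pmids: str | None = None
    disease_filter: str | None = None
    min_docs: int = 5
    k_threshold: float = 0.2
    fields: tuple[str, ...] = ("title", "abstract")
    reference_genes: str | None = None

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        if "fields" in data:
            data["fields"] = tuple(data["fields"])
        return cls(**data)

    def validate(self) -> None:
        missing = [k for k in ("corpus", "dictionary", "output_dir") if not getattr(self, k)]
        if missing:
            raise ValidationError(f"config missing required keys: {missing}")
        if not Path(self.corpus).exists():
            raise ValidationError(f"corpus path does not exist: {self.corpus}")
        if not Path(self.dictionary).exists():
            raise ValidationError(f"dictionary path does not exist: {self.dictionary}")
        for attr in ("gda", "pp_pmids", "reference_genes"):
            p = getattr(self, attr)
            if p and not Path(p).exists():
                raise ValidationError(f"{attr} path does not exist: {p}")
        if self.min_docs < 1:
            raise ValidationError("min_docs must be >= 1")
        if not 0 <= self.k_threshold < 1:
            raise ValidationError("k_threshold must be in [0, 1)")


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _read_pmid_list(path: str | Path) -> frozenset[str]:
    return frozenset(
        line.strip() for line in Path(path).read_text(encoding="utf-8").splitlines() if line.strip()
    )


def run_pipeline(config: RunConfig) -> dict[str, object]:
    """Execute the staged pipeline: ingest, tag, network, clusters, compare.

    Every artifact is written under ``config.output_dir`` together with a
    ``manifest.json`` recording the parameters, input checksums and
    artifact list. Any stage failure aborts with the stage name and cause.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    result: dict[str, object] = {}

    def stage(name):
        def deco(fn):
            try:
                return fn()
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - report stage + cause
                raise PipelineError(name, str(exc)) from exc

        return deco

    @stage("ingest")
    def _ingest():
        corpus_path = Path(config.corpus)
        if corpus_path.suffix.lower() == ".xml":
            docs = read_medline_xml(corpus_path)
        else:
            docs = read_corpus_tsv(corpus_path)
        dictionary = load_gene_dictionary(config.dictionary)
        gdas = load_gda_table(config.gda) if config.gda else None
        return docs, dictionary, gdas

    docs, dictionary, gdas = _ingest
    result["n_documents"] = len(docs)

    @stage("tag")
    def _tag():
        gene_idx = tag_corpus(docs, dictionary, fields=config.fields)
        mesh_idx = mesh_index(docs)
        write_index_tsv(gene_idx, out / "gene_index.tsv")
        write_index_tsv(mesh_idx, out / "mesh_index.tsv")
        artifacts["gene_index"] = "gene_index.tsv"
        artifacts["mesh_index"] = "mesh_index.tsv"
        return gene_idx, mesh_idx

    gene_idx, mesh_idx = _tag
    result["n_tagged_genes"] = len(gene_idx)

    @stage("query")
    def _query():
        if config.query is None:
            return frozenset(d.pmid for d in docs)
        if Path(config.query).exists():
            return _read_pmid_list(config.query)
        return frozenset(mesh_idx.postings.get(config.query, frozenset()))

    query_pmids = _query

    @stage("network")
    def _network():
        idx = restrict_index(gene_idx, query_pmids) if config.query else gene_idx
        net = build_network(idx, min_docs=config.min_docs, k_threshold=config.k_threshold)
        write_edgelist_tsv(net, out / "gene_edges.tsv")
        write_graphml(net, out / "gene_network.graphml")
        artifacts["gene_edges"] = "gene_edges.tsv"
        artifacts["gene_network"] = "gene_network.graphml"
        return net

    net = _network
    result["n_nodes"] = net.n_nodes
    result["n_edges"] = net.n_edges

    @stage("clusters")
    def _clusters():
        cl = extract_clusters(net)
        write_clusters_tsv(cl, out / "gene_clusters.tsv")
        artifacts["gene_clusters"] = "gene_clusters.tsv"
        return cl

    clusters = _clusters
    result["n_clusters"] = clusters.n_clusters
    result["clusters"] = clusters.clusters

    if gdas is not None:
        @stage("intersect")
        def _intersect():
            if not query_pmids:
                raise ValidationError("query matched no documents")
            sets = derive_workflow_sets(
                docs, dictionary, gdas, query_pmids,
                pp_pmids=_read_pmid_list(config.pp_pmids) if config.pp_pmids else None,
                fields=config.fields, disease_filter=config.disease_filter,
                gene_index=gene_idx,
            )
            genes = intersect_gene_sets(sets.UPOb, sets.DGNOb)
            counts = gene_reference_counts(gdas, config.disease_filter)
            counts.to_csv(out / "gene_reference_counts.tsv", sep="\t", index=False)
            artifacts["gene_reference_counts"] = "gene_reference_counts.tsv"
            payload: dict[str, object] = {
                "UPOb_size": len(sets.UPOb),
                "DGNOb_size": len(sets.DGNOb),
                "intersection": genes,
            }
            if config.reference_genes:
                ref = _read_pmid_list(config.reference_genes)
                payload["comparison"] = compare_gene_lists(genes, ref)
            (out / "gene_intersection.json").write_text(json.dumps(payload, indent=2))
            artifacts["gene_intersection"] = "gene_intersection.json"
            return payload

        result["intersection"] = _intersect

    @stage("manifest")
    def _manifest():
        inputs = {"corpus": config.corpus, "dictionary": config.dictionary}
        if config.gda:
            inputs["gda"] = config.gda
        manifest = {
            "parameters": {
                "min_docs": config.min_docs,
                "k_threshold": config.k_threshold,
                "fields": list(config.fields),
                "query": config.query,
                "disease_filter": config.disease_filter,
            },
            "inputs": {k: {"path": v, "sha256": _sha256(v)} for k, v in inputs.items()},
            "artifacts": artifacts,
            "summary": {k: v for k, v in result.items() if isinstance(v, (int, str))},
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        return manifest

    result["manifest"] = _manifest
    logger.info("pipeline complete: %d artifacts in %s", len(artifacts), out)
    return result
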