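"""Synthetic corpora with planted co-occurrence communities.

The generator plants a known community structure in a document collection
so that every pipeline stage — tokenisation, dictionary tagging, network
construction, clustering — can be exercised and its recovery checked
against ground truth, without downloading anything.

Construction
------------
For each community of genes the generator emits ``d`` "clique" documents
whose abstracts mention every member of the community, and for each gene
``b`` background documents mentioning only that gene. Optionally,
``cross_noise_docs`` documents each mention one random gene from each of
two distinct communities. Under this construction every within-community
pair has posting sizes A = B = d + b and shared count C = d, hence

    K = d / (d + 2b)

exactly, while cross-community pairs share only the noise co-mentions.
Clique documents (rather than pairwise co-mention documents) are used
because pairwise generation over a community of size s yields
K = 1/(2s - 3), which for s >= 3 can never clear a 0.2 edge threshold:
the clique construction makes the planted signal directly controllable
via d and b.

Abstract text is synthesised as gene symbols interleaved with filler
words, so the real tokenizer and matcher are exercised rather than
bypassed.
"""

from __future__ import annotations

import random
import string
from dataclasses import dataclass, field

import pandas as pd

from .corpus_io import Document, GeneDiseaseAssociations, TermDictionary
from .errors import ValidationError

__all__ = ["SyntheticCorpusSpec", "GroundTruth", "generate_corpus", "generate_gda"]

_FILLER = (
    "expression of the in adipose tissue was associated with increased "
    "body mass index and insulin resistance among study participants"
).split()


@dataclass(frozen=True)
class SyntheticCorpusSpec:
    """Parameters of the planted-community corpus.

    cluster_sizes
        Genes per planted community (each >= 2).
    docs_per_cluster
        d — documents mentioning every member of a community.
    background_docs_per_gene
        b — documents mentioning exactly one gene.
    cross_noise_docs
        Documents mentioning one random gene from each of two distinct
        communities.
    mesh_pool
        (descriptor, probability) pairs sampled independently per document.
    """

    cluster_sizes: tuple[int, ...] = (8, 5, 3, 3)
    docs_per_cluster: int = 10
    background_docs_per_gene: int = 5
    cross_noise_docs: int = 0
    mesh_pool: tuple[tuple[str, float], ...] = (("Obesity", 0.8), ("Humans", 0.9), ("Adipose Tissue", 0.3))
    seed: int = 0

    def __post_init__(self):
        if not self.cluster_sizes or any(s < 2 for s in self.cluster_sizes):
            raise ValidationError("cluster_sizes must be non-empty with every size >= 2")
        if min(self.docs_per_cluster, self.background_docs_per_gene, self.cross_noise_docs) < 0:
            raise ValidationError("document counts must be >= 0")
        if self.cross_noise_docs > 0 and len(self.cluster_sizes) < 2:
            raise ValidationError("cross_noise_docs requires at least two communities")
        for name, p in self.mesh_pool:
            if not name or not 0 <= p <= 1:
                raise ValidationError(f"bad mesh_pool entry ({name!r}, {p})")


@dataclass
class GroundTruth:
    """Planted community membership: community index -> member gene symbols."""

    communities: list[list[str]]

    def membership(self) -> dict[str, int]:
        return {g: i for i, members in enumerate(self.communities) for g in members}

    @property
    def genes(self) -> list[str]:
        return [g for members in self.communities for g in members]


def _gene_symbol(community: int, member: int) -> str:
    # >3 chars so matching is case-insensitive, like most real HGNC symbols
    return f"GEN{community + 1}{string.ascii_uppercase[member]}"


def generate_corpus(spec: SyntheticCorpusSpec) -> tuple[list[Document], TermDictionary, GroundTruth]:
    """Generate (documents, gene dictionary, ground truth) from a spec.

    Deterministic for a fixed spec (the seed is part of the spec). PMIDs
    are sequential strings starting at 9000001.
    """
    rng = random.Random(spec.seed)
    communities = [
        [_gene_symbol(c, i) for i in range(size)] for c, size in enumerate(spec.cluster_sizes)
    ]
    truth = GroundTruth(communities=[list(m) for m in communities])

    def abstract_for(genes: list[str]) -> str:
        words = []
        for g in genes:
            words.extend(rng.sample(_FILLER, 3))
            words.append(g)
        words.extend(rng.sample(_FILLER, 3))
        return " ".join(words)

    def mesh_for() -> tuple[str, ...]:
        return tuple(name for name, p in spec.mesh_pool if rng.random() < p)

    docs: list[Document] = []
    next_pmid = 9000001

    def emit(genes: list[str], title: str) -> None:
        nonlocal next_pmid
        docs.append(
            Document(
                pmid=str(next_pmid),
                title=title,
                abstract=abstract_for(genes),
                mesh_terms=mesh_for(),
                year=2020,
            )
        )
        next_pmid += 1

    for c, members in enumerate(communities):
        for j in range(spec.docs_per_cluster):
            emit(list(members), f"Community {c + 1} study {j + 1}")
    for members in communities:
        for g in members:
            for j in range(spec.background_docs_per_gene):
                emit([g], f"Background report on {g} ({j + 1})")
    for j in range(spec.cross_noise_docs):
        c1, c2 = rng.sample(range(len(communities)), 2)
        emit(
            [rng.choice(communities[c1]), rng.choice(communities[c2])],
            f"Cross-community observation {j + 1}",
        )

    entries = {g: (g, (f"synthetic protein {g.lower()}",)) for members in communities for g in members}
    dictionary = TermDictionary(namespace="gene", entries=entries)
    return docs, dictionary, truth


def generate_gda(
    truth: GroundTruth,
    disease_id: str = "C0028754",
    seed: int = 0,
    docs: list[Document] | None = None,
    pmids_per_gene: int = 5,
) -> GeneDiseaseAssociations:
    """Synthetic gene-disease association table for the planted genes.

    Every planted gene receives at least five distinct supporting PMIDs
    drawn from documents that mention it (so each gene can clear an
    "at least five articles" node filter downstream). If ``docs`` is not
    given, synthetic sequential PMIDs are used.
    """
    if not truth.genes:
        raise ValidationError("empty ground-truth membership")
    pmids_per_gene = max(5, pmids_per_gene)
    rng = random.Random(seed)

    gene_docs: dict[str, list[str]] = {g: [] for g in truth.genes}
    if docs is not None:
        for d in docs:
            tokens = set(d.abstract.split()) | set(d.title.split())
            for g in gene_docs:
                if g in tokens:
                    gene_docs[g].append(d.pmid)

    rows = []
    fallback = 8000001
    for g in truth.genes:
        pool = gene_docs[g]
        if len(pool) >= pmids_per_gene:
            chosen = rng.sample(pool, pmids_per_gene)
        else:
            extra = [str(fallback + i) for i in range(pmids_per_gene - len(pool))]
            fallback += len(extra)
            chosen = list(pool) + extra
        for p in sorted(chosen):
            rows.append({"gene": g, "disease_id": disease_id, "disease_name": "Obesity", "pmid": p})
    return GeneDiseaseAssociations(pd.DataFrame(rows))
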