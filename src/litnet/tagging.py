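"""Turn a corpus plus a vocabulary into a term -> PMID-set incidence index.

The incidence index is the substrate of every co-occurrence network here:
for each vocabulary term it records the set of documents mentioning it, so
the Jaccard similarity of two terms is just the Jaccard similarity of their
posting sets.

Matching rules (free-text tagging)
----------------------------------
* Text is split into whole tokens on non-alphanumeric characters, except
  that internal hyphens are kept ("TNF-alpha" is one token).
* Greek letters are normalised to their spelled-out names before
  tokenisation, so "TNF-α" matches a "TNF-alpha" synonym.
* Multi-word synonyms match as contiguous token sequences; the longest
  match wins and matches are taken non-overlapping left to right.
* Short gene symbols (single token, length <= 3) match case-sensitively —
  a precision guard against English words like "FAT" or "CAT" — while
  longer symbols and all multi-word synonyms match case-insensitively.

MeSH indexing uses the curator-assigned descriptors exactly; no free-text
matching is involved.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .corpus_io import Document, TermDictionary
from .errors import SchemaError

logger = logging.getLogger(__name__)

__all__ = [
    "IncidenceIndex",
    "tokenize",
    "tag_corpus",
    "mesh_index",
    "term_frequency_table",
    "restrict_index",
    "write_index_tsv",
    "read_index_tsv",
]

_GREEK = {
    "α": "alpha", "β": "beta", "γ": "gamma", "δ": "delta", "ε": "epsilon",
    "ζ": "zeta", "η": "eta", "θ": "theta", "ι": "iota", "κ": "kappa",
    "λ": "lambda", "μ": "mu", "ν": "nu", "ξ": "xi", "π": "pi", "ρ": "rho",
    "σ": "sigma", "τ": "tau", "υ": "upsilon", "φ": "phi", "χ": "chi",
    "ψ": "psi", "ω": "omega",
}
_GREEK.update({k.upper(): v for k, v in _GREEK.items()})
_GREEK_TABLE = str.maketrans(_GREEK)

_TOKEN_RE = re.compile(r"[A-Za-z0-9]+(?:-[A-Za-z0-9]+)*")

# length bound under which a single-token symbol matches case-sensitively
SHORT_SYMBOL_LEN = 3


def tokenize(text: str) -> list[str]:
    """Whole-token split keeping internal hyphens; Greek letters spelled out."""
    return _TOKEN_RE.findall(text.translate(_GREEK_TABLE))


@dataclass
class IncidenceIndex:
    """Mapping term ID -> set of PMIDs of the documents mentioning it.

    Invariants: no empty posting sets; every posted PMID belongs to the
    scanned corpus; each document contributes at most once per term.
    ``scanned_pmids`` records the whole scanned corpus (documents matching
    no term included), which :func:`restrict_index` needs to keep
    ``corpus_size`` exact under restriction.
    """

    namespace: str
    postings: dict[str, frozenset[str]] = field(default_factory=dict)
    scanned_pmids: frozenset[str] = frozenset()

    def __post_init__(self):
        self.postings = {t: frozenset(p) for t, p in self.postings.items() if p}
        stray = set().union(*self.postings.values(), set()) - set(self.scanned_pmids)
        if stray:
            raise ValueError(f"postings reference PMIDs outside the scanned corpus: {sorted(stray)[:5]}")

    @property
    def corpus_size(self) -> int:
        return len(self.scanned_pmids)

    def __len__(self) -> int:
        return len(self.postings)

    def __contains__(self, term: str) -> bool:
        return term in self.postings

    def terms(self) -> list[str]:
        return sorted(self.postings)


class _PhraseMatcher:
    """Dictionary compiled to token tuples for the left-to-right longest-match scan."""

    def __init__(self, dictionary: TermDictionary):
        self.exact: dict[tuple[str, ...], set[str]] = {}
        self.folded: dict[tuple[str, ...], set[str]] = {}
        self.max_len = 1
        for term_id in dictionary.entries:
            for s in dictionary.strings(term_id):
                toks = tuple(tokenize(s))
                if not toks:
                    continue
                self.max_len = max(self.max_len, len(toks))
                if len(toks) == 1 and len(toks[0]) <= SHORT_SYMBOL_LEN:
                    self.exact.setdefault(toks, set()).add(term_id)
                else:
                    self.folded.setdefault(tuple(t.lower() for t in toks), set()).add(term_id)

    def scan(self, tokens: Sequence[str]) -> set[str]:
        hits: set[str] = set()
        n = len(tokens)
        i = 0
        while i < n:
            advanced = False
            for length in range(min(self.max_len, n - i), 0, -1):
                seg = tuple(tokens[i : i + length])
                ids = self.exact.get(seg, set()) | self.folded.get(tuple(t.lower() for t in seg), set())
                if ids:
                    hits |= ids
                    i += length
                    advanced = True
                    break
            if not advanced:
                i += 1
        return hits


def tag_corpus(
    docs: Sequence[Document],
    dictionary: TermDictionary,
    fields: Iterable[str] = ("title", "abstract"),
) -> IncidenceIndex:
    """Tag every document against the dictionary over the chosen text fields.

    A term is credited to a document iff its canonical symbol or one of its
    synonyms matches under the module's matching rules; postings are
    deduplicated per document.
    """
    fields = frozenset(fields)
    bad = fields - {"title", "abstract"}
    if bad:
        raise ValueError(f"unknown fields: {sorted(bad)}")
    if not dictionary.entries:
        raise ValueError("dictionary is empty")
    if not docs:
        warnings.warn("empty corpus: returning empty index", stacklevel=2)

    matcher = _PhraseMatcher(dictionary)
    postings: dict[str, set[str]] = {}
    for doc in docs:
        text_parts = [getattr(doc, f) for f in sorted(fields)]
        hits: set[str] = set()
        for part in text_parts:
            if part:
                hits |= matcher.scan(tokenize(part))
        for term in hits:
            postings.setdefault(term, set()).add(doc.pmid)
    return IncidenceIndex(
        namespace=dictionary.namespace,
        postings={t: frozenset(p) for t, p in postings.items()},
        scanned_pmids=frozenset(d.pmid for d in docs),
    )


def mesh_index(docs: Sequence[Document]) -> IncidenceIndex:
    """Index over curator-assigned MeSH descriptors exactly (no free text)."""
    postings: dict[str, set[str]] = {}
    for doc in docs:
        for term in set(doc.mesh_terms):
            postings.setdefault(term, set()).add(doc.pmid)
    return IncidenceIndex(
        namespace="mesh",
        postings={t: frozenset(p) for t, p in postings.items()},
        scanned_pmids=frozenset(d.pmid for d in docs),
    )


def term_frequency_table(index: IncidenceIndex) -> pd.DataFrame:
    """Ranked term frequencies: columns ``term``, ``doc_count``, ``rank``.

    Descending by document count, ties broken lexicographically by term ID,
    dense ranks 1..n. With literature vocabularies this table is the usual
    Zipf-ranked frequency list.
    """
    rows = sorted(((t, len(p)) for t, p in index.postings.items()), key=lambda x: (-x[1], x[0]))
    return pd.DataFrame(
        [(t, c, r) for r, (t, c) in enumerate(rows, start=1)],
        columns=["term", "doc_count", "rank"],
    )


def restrict_index(index: IncidenceIndex, allowed_pmids: Iterable[str]) -> IncidenceIndex:
    """Intersect every posting with ``allowed_pmids``; drop emptied terms."""
    allowed = frozenset(allowed_pmids)
    return IncidenceIndex(
        namespace=index.namespace,
        postings={t: p & allowed for t, p in index.postings.items() if p & allowed},
        scanned_pmids=index.scanned_pmids & allowed,
    )


def write_index_tsv(index: IncidenceIndex, path: str | Path) -> None:
    """Serialize as TSV: ``term  pmid_count  pmids`` (pmids comma-delimited, sorted)."""
    rows = [
        {"term": t, "pmid_count": len(p), "pmids": ",".join(sorted(p))}
        for t, p in sorted(index.postings.items())
    ]
    df = pd.DataFrame(rows, columns=["term", "pmid_count", "pmids"])
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# namespace={index.namespace}\tcorpus_size={index.corpus_size}\t"
                 f"scanned_pmids={','.join(sorted(index.scanned_pmids))}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_index_tsv(path: str | Path) -> IncidenceIndex:
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise SchemaError(f"{path}: missing index metadata header line")
        meta = dict(kv.split("=", 1) for kv in header.lstrip("#").strip().split("\t"))
        df = pd.read_csv(fh, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in ("term", "pmid_count", "pmids") if c not in df.columns]
    if missing:
        raise SchemaError(f"index TSV {path} missing columns: {missing}")
    postings = {
        row.term: frozenset(p for p in str(row.pmids).split(",") if p)
        for row in df.itertuples(index=False)
    }
    scanned = frozenset(p for p in meta.get("scanned_pmids", "").split(",") if p)
    scanned = scanned | set().union(*postings.values(), set())
    return IncidenceIndex(namespace=meta.get("namespace", "custom"), postings=postings,
                          scanned_pmids=scanned)
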