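# Methods

## Model

`litnet` treats a literature corpus as a binary document–term incidence
structure. For a vocabulary term *t*, its *posting* is the set of PMIDs
of the documents mentioning it; the `IncidenceIndex` maps every term to
its posting and is the single substrate all downstream statistics operate
on. Co-occurrence is strictly document-level: two terms co-occur when the
same abstract mentions both, with no sentence- or window-level scoping.

The association between two terms is the Jaccard (Tanimoto) index of
their postings, `K = C/(A + B − C)` with `A`, `B` the posting sizes and
`C` the shared-document count. `K` is undefined (0/0) when both postings
are empty; the implementation raises rather than returning a sentinel.
A semantic network retains terms with at least `min_docs` supporting
documents (inclusive bound) and edges with `K` strictly greater than
`k_threshold`; clusters are the connected components with ≥ 2 members of
the retained graph. Component clustering is deliberate: the filtered
graphs this method produces are sparse and fall apart into small,
readable subnetworks, so no modularity-style community detection is
applied. "Information depletion" removes the *k* most frequent terms
(frequency ties broken lexicographically) and leaves all other postings
untouched; because term frequencies in literature vocabularies are
Zipf-distributed, a small *k* removes a disproportionate share of the
uninformative mass.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `min_docs` | 5 | minimum articles supporting a network node (inclusive) |
| `k_threshold` | 0.2 | edges require K strictly above this |
| `fields` | title, abstract | text fields scanned by the dictionary tagger |

The defaults are the conventional filter settings for this kind of
gene–literature network: five supporting articles per node and a 0.2
Jaccard edge threshold. Both are exposed on every interface rather than
hard-coded, since different corpora justify different operating points.

## Matching rules (dictionary tagging)

Free-text tagging is intentionally rule-based and transparent:

* Text splits into whole tokens on non-alphanumeric characters; internal
  hyphens are preserved ("TNF-alpha" is one token). Matching substrings
  inside tokens is never allowed, so "LEPR" does not credit "LEP".
* Greek letters are normalised to spelled-out names before tokenisation
  ("TNF-α" matches a "TNF-alpha" synonym) — the literature mixes both.
* Multi-word synonyms match as contiguous token sequences. The scan is
  left-to-right, longest match wins, matches do not overlap: "leptin
  receptor" credits the receptor gene only, not the hormone inside it.
* Single-token symbols of length ≤ 3 match case-sensitively; longer
  symbols and all multi-word synonyms match case-insensitively. This is
  the standard precision heuristic guarding against English-word
  collisions ("FAT", "CAT") while tolerating case variation in longer
  symbols.
* Synonyms claimed by two or more dictionary entries are ambiguous and
  dropped from all claimants at load time (logged), since an ambiguous
  string would corrupt per-term document counts.

MeSH indexing uses the curator-assigned descriptors verbatim; qualifiers
(subheadings) are dropped because only the descriptor identifies the
concept. Records without abstracts are kept — their MeSH terms still
contribute to descriptor networks. Duplicate PMIDs in a corpus are a hard
error, not a silent merge: merging would silently distort A, B and C.

## Numerical choices

Edge similarities are stored as exact integer ratios
(`fractions.Fraction`), so the strict threshold comparison `K > 0.2` and
closed-form checks like `K = 1/2` carry no floating-point artifacts. A
float threshold is interpreted via its decimal literal (0.2 means exactly
1/5). Serialized output rounds K to six decimal places. Pair enumeration
goes through the inverted document→terms map, so only pairs with `C ≥ 1`
are ever visited; disjoint pairs cost nothing, which keeps 10⁵-abstract
corpora tractable. All orderings (frequency tables, cluster reports,
set outputs) use deterministic sort keys — descending count, then
lexicographic — so reruns are byte-identical.

## Workflow semantics

The set-intersection workflow names four base sets — corpus PMIDs (`PM`),
an optional most-cited-author PMID allow-list (`PP`), dictionary genes
(`UP`) and expert-table genes (`DGN`) — and restricts each by a disease
query to `PMOb`, `PPOb`, `UPOb`, `DGNOb`. The query is a PMID set
(typically the documents carrying a MeSH descriptor, or a user-supplied
PMID file), never a live search: this keeps runs offline and
deterministic. The GDA table is assumed pre-filtered to the disease of
interest, with an optional disease-ID filter for mixed exports. Because
no single convention defines "percent difference between two gene lists",
`compare_gene_lists` reports recall, Jaccard similarity and both
asymmetric differences so any convention can be read off.

## Synthetic corpus generator

The generator plants a known community structure: each community of genes
contributes `d` clique documents mentioning every member, each gene gets
`b` solo background documents, and optional cross-noise documents mention
one gene from each of two communities. Abstract text is synthesised as
gene tokens interleaved with filler words, so tests exercise the real
tokenizer and matcher. The construction gives closed forms: within a
community every pair has `A = B = d + b`, `C = d`, hence
`K = d/(d + 2b)` exactly, and cross-community `C` equals the planted
noise count. Clique documents are used instead of pairwise co-mention
documents because pairwise generation over a community of size `s` yields
`K = 1/(2s − 3)`, which for `s ≥ 3` can never clear a 0.2 threshold.

The default spec (communities of 8/5/3/3 genes, `d = 10`, `b = 5`, no
cross noise) puts every within-community pair at `K = 0.5` and every gene
at 15 supporting documents, comfortably above both default filters. What
the generator does **not** emulate: natural-language variation (synonym
usage, abbreviations, sentence structure), the MeSH hierarchy, unbalanced
gene frequencies, or genes outside the planted dictionary. Passing the
planted-recovery tests therefore demonstrates the correctness of the
indexing→similarity→threshold→component chain, not the recall of the
tagger on real prose.

## Problem sizes in the test suite

Unit and property tests run on corpora of ≤ 20 documents with brute-force
oracles; planted recovery uses the default 135-document spec across 20
seeds; the scaling test runs the full pipeline on 10,000 documents × 500
genes (100 planted communities, `d = 10`, `b = 18`, within-community
`K = 10/46 ≈ 0.217`). These sizes were chosen as the smallest that
exercise each property convincingly.

## Known limitations

* Dictionary tagging is exact-string (after normalisation): no
  abbreviation expansion, no species disambiguation, no statistical NER.
  Short ambiguous symbols that are also English words in their canonical
  case (e.g. a gene literally named "WAS") will still false-hit.
* Co-occurrence is symmetric evidence of shared context, not causal or
  even directional association; the Jaccard filter has no significance
  calibration (a hypergeometric test is out of scope by design).
* Connected components are fragile to single spurious edges between
  otherwise separate clusters; the depletion operator is the intended
  remedy, applied iteratively under user control.
* MEDLINE XML parsing covers the `PubmedArticleSet` layout (PMID, title,
  abstract, MeSH headings, year); less common record variants fall back
  to empty fields rather than failing.
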