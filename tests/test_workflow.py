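"""Set-intersection workflow, GDA-driven networks and gene-list comparison."""

import json
import random

import pandas as pd
import pytest

from litnet import (
    Document,
    GeneDiseaseAssociations,
    IncidenceIndex,
    RunConfig,
    SyntheticCorpusSpec,
    TermDictionary,
    ValidationError,
    build_network,
    compare_gene_lists,
    derive_workflow_sets,
    gda_incidence,
    gene_reference_counts,
    generate_corpus,
    generate_gda,
    intersect_gene_sets,
    run_pipeline,
    write_corpus_tsv,
)


@pytest.fixture
def four_doc_corpus():
    return [
        Document(pmid="1", abstract="GENX is discussed here", mesh_terms=("Obesity",)),
        Document(pmid="2", abstract="nothing relevant", mesh_terms=("Obesity",)),
        Document(pmid="3", abstract="GENY appears outside the query", mesh_terms=("Humans",)),
        Document(pmid="4", abstract="also nothing", mesh_terms=("Humans",)),
    ]


@pytest.fixture
def xy_dict():
    return TermDictionary(namespace="gene",
                          entries={"GENX": ("GENX", ()), "GENY": ("GENY", ())})


class TestDeriveWorkflowSets:
    def test_gene_tagged_only_in_query_doc_enters_upob(self, four_doc_corpus, xy_dict, gda_fixture):
        sets = derive_workflow_sets(four_doc_corpus, xy_dict, gda_fixture,
                                    query_pmids={"1", "2"})
        assert sets.PMOb == {"1", "2"}
        assert sets.UPOb == {"GENX"}  # GENY appears only outside the query
        assert sets.UP == {"GENX", "GENY"}

    def test_query_matching_all_docs_keeps_all_tagged_genes(self, four_doc_corpus, xy_dict,
                                                            gda_fixture):
        sets = derive_workflow_sets(four_doc_corpus, xy_dict, gda_fixture,
                                    query_pmids={"1", "2", "3", "4"})
        assert sets.UPOb == {"GENX", "GENY"}

    def test_pp_absent_means_ppob_absent(self, four_doc_corpus, xy_dict, gda_fixture):
        sets = derive_workflow_sets(four_doc_corpus, xy_dict, gda_fixture, query_pmids={"1"})
        assert sets.PP is None and sets.PPOb is None

    def test_pp_restricted_by_query(self, four_doc_corpus, xy_dict, gda_fixture):
        sets = derive_workflow_sets(four_doc_corpus, xy_dict, gda_fixture,
                                    query_pmids={"1", "3"}, pp_pmids={"1", "2"})
        assert sets.PPOb == {"1"}

    def test_empty_query_is_an_error(self, four_doc_corpus, xy_dict, gda_fixture):
        with pytest.raises(ValidationError, match="query"):
            derive_workflow_sets(four_doc_corpus, xy_dict, gda_fixture, query_pmids=set())

    def test_subset_chain_on_random_fixtures(self):
        rng = random.Random(23)
        for _ in range(100):
            spec = SyntheticCorpusSpec(
                cluster_sizes=tuple(rng.randint(2, 4) for _ in range(rng.randint(1, 3))),
                docs_per_cluster=rng.randint(1, 4),
                background_docs_per_gene=rng.randint(0, 3),
                seed=rng.randrange(10_000),
            )
            docs, dictionary, truth = generate_corpus(spec)
            gdas = generate_gda(truth, seed=spec.seed)
            query = {d.pmid for d in docs if rng.random() < 0.5} or {docs[0].pmid}
            sets = derive_workflow_sets(docs, dictionary, gdas, query_pmids=query)
            assert sets.PMOb <= sets.PM
            assert sets.UPOb <= sets.UP
            assert sets.DGNOb <= sets.DGN


class TestIntersectGeneSets:
    def test_plain_intersection_sorted(self):
        assert intersect_gene_sets({"LEP", "FTO", "TNF"}, {"FTO", "TNF", "ADIPOQ"}) == ["FTO", "TNF"]

    def test_disjoint_and_identity(self):
        assert intersect_gene_sets({"A"}, {"B"}) == []
        assert intersect_gene_sets({"A", "B"}, {"B", "A"}) == ["A", "B"]

    def test_agrees_with_naive_intersection_on_random_sets(self):
        rng = random.Random(5)
        genes = [f"G{i}" for i in range(40)]
        for _ in range(50):
            a = {g for g in genes if rng.random() < 0.4}
            b = {g for g in genes if rng.random() < 0.4}
            assert intersect_gene_sets(a, b) == sorted({g for g in genes if g in a and g in b})


class TestGDAIncidence:
    def test_postings_per_gene(self):
        rows = [("G1", "d", "D", "p1"), ("G1", "d", "D", "p2"), ("G2", "d", "D", "p1")]
        gdas = GeneDiseaseAssociations(
            pd.DataFrame(rows, columns=["gene", "disease_id", "disease_name", "pmid"]))
        idx = gda_incidence(gdas)
        assert idx.postings["G1"] == {"p1", "p2"}
        assert idx.postings["G2"] == {"p1"}

    def test_duplicate_rows_count_once(self):
        rows = [("G1", "d", "D", "p1"), ("G1", "d", "D", "p1")]
        gdas = GeneDiseaseAssociations(
            pd.DataFrame(rows, columns=["gene", "disease_id", "disease_name", "pmid"]))
        assert gda_incidence(gdas).postings["G1"] == {"p1"}

    def test_empty_table_gives_empty_index(self):
        gdas = GeneDiseaseAssociations(
            pd.DataFrame(columns=["gene", "disease_id", "disease_name", "pmid"]))
        assert len(gda_incidence(gdas)) == 0

    def test_network_from_gda_equals_network_from_hand_built_index(self):
        docs, _, truth = generate_corpus(SyntheticCorpusSpec(cluster_sizes=(3, 3), seed=9))
        gdas = generate_gda(truth, seed=9, docs=docs)
        postings = {}
        for row in gdas.table.itertuples(index=False):
            postings.setdefault(row.gene, set()).add(row.pmid)
        hand = IncidenceIndex(
            namespace="gene",
            postings={g: frozenset(p) for g, p in postings.items()},
            scanned_pmids=frozenset(gdas.table["pmid"]),
        )
        via_gda = build_network(gda_incidence(gdas), min_docs=5, k_threshold=0.2)
        via_hand = build_network(hand, min_docs=5, k_threshold=0.2)
        assert via_gda.nodes == via_hand.nodes and via_gda.edges == via_hand.edges


class TestGeneReferenceCounts:
    def test_distinct_pmid_and_disease_counts(self, gda_fixture):
        table = gene_reference_counts(gda_fixture)
        fto = table[table["gene"] == "FTO"].iloc[0]
        assert (fto["n_pmids"], fto["n_diseases"]) == (3, 2)
        assert list(table["gene"]) == ["FTO", "LEP"]  # descending by PMID count

    def test_disease_filter_restricts_pmid_counts(self, gda_fixture):
        table = gene_reference_counts(gda_fixture, disease_filter="C0028754")
        fto = table[table["gene"] == "FTO"].iloc[0]
        assert fto["n_pmids"] == 2  # the Diabetes-only PMID no longer counts
        assert fto["n_diseases"] == 2

    def test_absent_gene_not_reported(self, gda_fixture):
        assert "MC4R" not in set(gene_reference_counts(gda_fixture)["gene"])


class TestCompareGeneLists:
    def test_recall_is_hit_fraction_of_reference(self):
        reference = {f"R{i}" for i in range(8)}
        automated = {"R0", "R1", "R2", "X1", "X2"}
        result = compare_gene_lists(automated, reference)
        assert result["recall"] == pytest.approx(3 / 8)
        assert result["only_automated"] == ["X1", "X2"]
        assert len(result["only_reference"]) == 5

    def test_identical_lists(self):
        result = compare_gene_lists({"A", "B"}, {"A", "B"})
        assert result["recall"] == 1.0 and result["jaccard"] == 1.0
        assert result["only_automated"] == [] and result["only_reference"] == []

    def test_disjoint_lists(self):
        result = compare_gene_lists({"A"}, {"B"})
        assert result["recall"] == 0.0 and result["jaccard"] == 0.0

    def test_empty_reference_rejected(self):
        with pytest.raises(ValidationError):
            compare_gene_lists({"A"}, set())

    def test_recall_invariant_under_extra_nonreference_genes(self):
        reference = {"A", "B", "C"}
        automated = {"A", "X"}
        before = compare_gene_lists(automated, reference)["recall"]
        after = compare_gene_lists(automated | {"Y", "Z"}, reference)["recall"]
        assert before == after


class TestRunPipeline:
    def _write_inputs(self, tmp_path, spec):
        docs, dictionary, truth = generate_corpus(spec)
        write_corpus_tsv(docs, tmp_path / "corpus.tsv")
        with open(tmp_path / "genes.tsv", "w") as fh:
            for term_id in dictionary.entries:
                fh.write("\t".join((term_id, *dictionary.synonyms(term_id))) + "\n")
        generate_gda(truth, seed=spec.seed, docs=docs).table.to_csv(
            tmp_path / "gda.tsv", sep="\t", index=False)
        return truth

    def test_pipeline_recovers_planted_groups_and_writes_artifacts(self, tmp_path):
        spec = SyntheticCorpusSpec(cluster_sizes=(8, 5, 3, 3), seed=1)
        truth = self._write_inputs(tmp_path, spec)
        cfg = RunConfig(corpus=str(tmp_path / "corpus.tsv"),
                        dictionary=str(tmp_path / "genes.tsv"),
                        gda=str(tmp_path / "gda.tsv"),
                        output_dir=str(tmp_path / "out"))
        result = run_pipeline(cfg)
        assert sorted(map(sorted, result["clusters"])) == sorted(map(sorted, truth.communities))
        for artifact in ("gene_index.tsv", "mesh_index.tsv", "gene_edges.tsv",
                         "gene_network.graphml", "gene_clusters.tsv", "manifest.json"):
            assert (tmp_path / "out" / artifact).exists()
        intersection = json.loads((tmp_path / "out" / "gene_intersection.json").read_text())
        assert intersection["intersection"] == sorted(truth.genes)

    def test_rerun_produces_identical_manifest(self, tmp_path):
        spec = SyntheticCorpusSpec(cluster_sizes=(3, 3), seed=2)
        self._write_inputs(tmp_path, spec)
        cfg = dict(corpus=str(tmp_path / "corpus.tsv"), dictionary=str(tmp_path / "genes.tsv"),
                   gda=str(tmp_path / "gda.tsv"))
        run_pipeline(RunConfig(output_dir=str(tmp_path / "out1"), **cfg))
        run_pipeline(RunConfig(output_dir=str(tmp_path / "out2"), **cfg))
        assert ((tmp_path / "out1" / "manifest.json").read_bytes()
                == (tmp_path / "out2" / "manifest.json").read_bytes())

    def test_missing_corpus_fails_validation_before_any_work(self, tmp_path):
        cfg = RunConfig(corpus=str(tmp_path / "nope.tsv"), dictionary=str(tmp_path / "nope2.tsv"),
                        output_dir=str(tmp_path / "out"))
        with pytest.raises(ValidationError, match="corpus"):
            run_pipeline(cfg)
        assert not (tmp_path / "out").exists()

    def test_mesh_descriptor_query_restricts_network(self, tmp_path):
        docs = [
            Document(pmid="1", abstract="GENX and GENY together", mesh_terms=("Obesity",)),
            Document(pmid="2", abstract="GENX and GENY together", mesh_terms=("Obesity",)),
            Document(pmid="3", abstract="GENX and GENY together", mesh_terms=("Other",)),
        ]
        write_corpus_tsv(docs, tmp_path / "corpus.tsv")
        (tmp_path / "genes.tsv").write_text("GENX\nGENY\n")
        cfg = RunConfig(corpus=str(tmp_path / "corpus.tsv"),
                        dictionary=str(tmp_path / "genes.tsv"),
                        output_dir=str(tmp_path / "out"), query="Obesity", min_docs=1)
        result = run_pipeline(cfg)
        assert result["n_nodes"] == 2
        edges = pd.read_csv(tmp_path / "out" / "gene_edges.tsv", sep="\t")
        assert list(edges["C"]) == [2]  # PMID 3 excluded by the query

    def test_config_round_trip_from_yaml(self, tmp_path):
        (tmp_path / "cfg.yaml").write_text(
            "corpus: c.tsv\ndictionary: d.tsv\noutput_dir: out\nmin_docs: 3\nk_threshold: 0.3\n")
        cfg = RunConfig.from_file(tmp_path / "cfg.yaml")
        assert cfg.min_docs == 3 and cfg.k_threshold == 0.3

    def test_unknown_config_key_rejected(self, tmp_path):
        (tmp_path / "cfg.yaml").write_text("corpus: c\ndictionary: d\noutput_dir: o\nbogus: 1\n")
        with pytest.raises(ValidationError, match="bogus"):
            RunConfig.from_file(tmp_path / "cfg.yaml")
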