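import math

import numpy as np
import pytest

from helpers import (
    make_term_matrix,
    naive_log_entropy,
    random_count_matrix,
    space_from_vectors,
    tiny_config,
)

from litcohesion import corpus_lsi as cl, synthetic_data as sd
from litcohesion.errors import (
    CohesionUndefinedError,
    ConfigurationError,
    ParseError,
    PipelineError,
    UndefinedSimilarityError,
)


# ---------------------------------------------------------------------------
# read_gene2pubmed
# ---------------------------------------------------------------------------

class TestReadGene2Pubmed:
    def test_duplicate_rows_collapse(self, tmp_path):
        p = tmp_path / "g2p.tsv"
        p.write_text("10090\t1\t101\n10090\t1\t101\n10090\t2\t102\n")
        assert cl.read_gene2pubmed(p) == {"1": {101}, "2": {102}}

    def test_header_only_gives_empty_map(self, tmp_path):
        p = tmp_path / "g2p.tsv"
        p.write_text("#tax_id\tGeneID\tPubMed_ID\n")
        assert cl.read_gene2pubmed(p) == {}

    def test_bad_pmid_names_line(self, tmp_path):
        p = tmp_path / "g2p.tsv"
        p.write_text("10090\t1\t101\n10090\t1\tabc\n")
        with pytest.raises(ParseError, match="line 2") as err:
            cl.read_gene2pubmed(p)
        assert err.value.line == 2

    def test_short_row_rejected(self, tmp_path):
        p = tmp_path / "g2p.tsv"
        p.write_text("10090\t1\n")
        with pytest.raises(ParseError):
            cl.read_gene2pubmed(p)


# ---------------------------------------------------------------------------
# build_documents
# ---------------------------------------------------------------------------

class TestBuildDocuments:
    def test_texts_join_in_ascending_pmid_order(self):
        corpus = cl.build_documents({"g1": {102, 101}}, {101: "a b", 102: "c"})
        assert corpus.documents["g1"] == "a b c"

    def test_gene_without_text_excluded(self, caplog):
        with caplog.at_level("WARNING"):
            corpus = cl.build_documents({"g1": {101}, "g2": {999}}, {101: "text"})
        assert "g2" not in corpus
        assert corpus.genes == ["g1"]
        assert any("excluded" in r.message for r in caplog.records)

    def test_shared_pmid_text_in_both_documents(self):
        corpus = cl.build_documents({"g1": {101}, "g2": {101}}, {101: "shared"})
        assert corpus.documents["g1"] == corpus.documents["g2"] == "shared"


# ---------------------------------------------------------------------------
# tokenize
# ---------------------------------------------------------------------------

class TestTokenize:
    def test_rule_application(self):
        assert cl.tokenize("Sirt3 regulates NAD+ metabolism") == [
            "sirt3", "regulates", "nad", "metabolism"]

    def test_stopwords_and_numbers_removed(self):
        assert cl.tokenize("a an of 42") == []

    def test_empty(self):
        assert cl.tokenize("") == []

    def test_custom_stopwords(self):
        assert cl.tokenize("alpha beta", stopwords={"beta"}) == ["alpha"]


# ---------------------------------------------------------------------------
# build_term_matrix
# ---------------------------------------------------------------------------

def _corpus_from_docs(docs: dict) -> cl.GeneCorpus:
    return cl.GeneCorpus(
        documents=dict(docs),
        pmids={g: frozenset({1}) for g in docs},
        genes=list(docs),
    )


class TestBuildTermMatrix:
    def test_frequency_filter(self):
        corpus = _corpus_from_docs({"g1": "xxx yyy", "g2": "xxx zzz"})
        tgm = cl.build_term_matrix(corpus, min_gene_frequency=2)
        assert tgm.terms == ["xxx"]
        assert tgm.counts.toarray().tolist() == [[1.0, 1.0]]

    def test_filter_off(self):
        corpus = _corpus_from_docs({"g1": "xxx yyy", "g2": "xxx zzz"})
        tgm = cl.build_term_matrix(corpus, min_gene_frequency=1)
        assert tgm.terms == ["xxx", "yyy", "zzz"]

    def test_count_semantics(self):
        corpus = _corpus_from_docs({"g1": "abc abc abc", "g2": "def"})
        tgm = cl.build_term_matrix(corpus, min_gene_frequency=1)
        assert tgm.counts.toarray()[tgm.terms.index("abc"), 0] == 3

    def test_empty_vocabulary_is_error(self):
        corpus = _corpus_from_docs({"g1": "aaa", "g2": "bbb"})
        with pytest.raises(PipelineError, match="vocabulary"):
            cl.build_term_matrix(corpus, min_gene_frequency=2)


# ---------------------------------------------------------------------------
# log_entropy_weight
# ---------------------------------------------------------------------------

class TestLogEntropyWeight:
    def test_maximal_entropy_row_is_zero(self):
        n = 6
        counts = np.vstack([np.ones(n), np.arange(1, n + 1)])
        w = cl.log_entropy_weight(make_term_matrix(counts)).counts.toarray()
        assert np.allclose(w[0], 0.0)

    def test_minimal_entropy_term(self):
        counts = np.array([[5.0, 0, 0, 0], [1, 1, 2, 1]])
        w = cl.log_entropy_weight(make_term_matrix(counts)).counts.toarray()
        assert w[0, 0] == pytest.approx(math.log2(6), abs=1e-12)

    def test_worked_row(self):
        # counts (2,1,1,0) over n=4 genes; hand-derived g = 0.25
        counts = np.array([[2.0, 1, 1, 0], [1, 1, 1, 1]])
        expected = naive_log_entropy(counts)
        w = cl.log_entropy_weight(make_term_matrix(counts)).counts.toarray()
        assert np.allclose(w, expected, atol=1e-12)
        assert np.allclose(
            w[0], 0.25 * np.array([math.log2(3), 1.0, 1.0, 0.0]), atol=1e-12)

    def test_matches_naive_oracle_on_random_matrices(self):
        rng = np.random.default_rng(42)
        for _ in range(5):
            counts = random_count_matrix(rng, 50, 20)
            w = cl.log_entropy_weight(make_term_matrix(counts)).counts.toarray()
            assert np.max(np.abs(w - naive_log_entropy(counts))) < 1e-10

    def test_single_gene_is_error(self):
        with pytest.raises(ConfigurationError):
            cl.log_entropy_weight(make_term_matrix(np.array([[1.0], [2.0]])))

    def test_global_weights_in_unit_interval(self):
        rng = np.random.default_rng(7)
        g = cl.global_weights(make_term_matrix(random_count_matrix(rng, 40, 15)))
        assert np.all((g >= 0) & (g <= 1))


# ---------------------------------------------------------------------------
# truncated_svd
# ---------------------------------------------------------------------------

def _column_cosines(x: np.ndarray) -> np.ndarray:
    xn = x / np.linalg.norm(x, axis=0, keepdims=True)
    return xn.T @ xn


class TestTruncatedSvd:
    def test_full_rank_is_lossless(self):
        rng = np.random.default_rng(0)
        counts = random_count_matrix(rng, 30, 12, duplicate_last_gene=True)
        tgm = cl.log_entropy_weight(make_term_matrix(counts))
        space = cl.truncated_svd(tgm, k=11, seed=0)
        un = space.unit_vectors()
        assert np.max(np.abs(un @ un.T - _column_cosines(tgm.counts.toarray()))) < 1e-8

    def test_rank_one_matrix(self):
        u = np.array([1.0, 2, 3, 4, 5])
        v = np.array([2.0, 1, 3])
        x = np.outer(u, v)
        space = cl.truncated_svd(make_term_matrix(x, weighted=True), k=1, seed=0)
        assert space.singular_values[0] ** 2 == pytest.approx(
            np.sum(x ** 2), rel=1e-12)
        s_full = np.linalg.svd(x, compute_uv=False)
        assert s_full[1] == pytest.approx(0.0, abs=1e-10)

    def test_energy_matches_dense_oracle(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((200, 100))
        space = cl.truncated_svd(make_term_matrix(np.abs(x), weighted=True),
                                 k=30, seed=0)
        s_oracle = np.linalg.svd(np.abs(x), compute_uv=False)
        best_rank30_energy = np.sum(s_oracle[:30] ** 2)
        assert np.sum(space.singular_values ** 2) == pytest.approx(
            best_rank30_energy, rel=1e-6)

    def test_clamp_warns(self, caplog):
        rng = np.random.default_rng(1)
        tgm = make_term_matrix(random_count_matrix(rng, 20, 8), weighted=True)
        with caplog.at_level("WARNING"):
            space = cl.truncated_svd(tgm, k=500, seed=0)
        assert space.k == 7
        assert any("clamping" in r.message for r in caplog.records)

    def test_singular_values_sorted_descending(self):
        rng = np.random.default_rng(5)
        tgm = make_term_matrix(random_count_matrix(rng, 40, 20), weighted=True)
        space = cl.truncated_svd(tgm, k=10, seed=0)
        assert np.all(np.diff(space.singular_values) <= 0)
        assert np.all(space.singular_values >= 0)


# ---------------------------------------------------------------------------
# cosine / pairwise_cosines
# ---------------------------------------------------------------------------

class TestCosine:
    def test_self_similarity(self):
        space = space_from_vectors(np.array([[1.0, 2, 3], [1.0, 2, 3]]))
        assert cl.cosine(space, "gene000", "gene001") == pytest.approx(1.0)

    def test_orthogonality(self):
        space = space_from_vectors(np.array([[1.0, 0], [0, 1.0]]))
        assert cl.cosine(space, "gene000", "gene001") == pytest.approx(0.0)

    def test_closed_form(self):
        space = space_from_vectors(np.array([[1.0, 1, 0], [1.0, 0, 0]]))
        assert cl.cosine(space, "gene000", "gene001") == pytest.approx(
            1 / math.sqrt(2))

    def test_zero_norm_error_names_gene(self):
        space = space_from_vectors(np.array([[0.0, 0], [1.0, 0]]))
        with pytest.raises(UndefinedSimilarityError, match="gene000"):
            cl.cosine(space, "gene000", "gene001")


class TestPairwiseCosines:
    @pytest.mark.parametrize("n_genes,n_pairs", [(3, 3), (100, 4950)])
    def test_pair_counts(self, n_genes, n_pairs):
        rng = np.random.default_rng(0)
        space = space_from_vectors(rng.standard_normal((n_genes, 5)))
        cs = cl.pairwise_cosines(space, space.genes)
        assert cs.values.size == n_pairs
        assert cs.coverage == 1.0

    def test_missing_genes_dropped_with_coverage(self):
        rng = np.random.default_rng(1)
        space = space_from_vectors(rng.standard_normal((8, 4)))
        requested = list(space.genes) + ["missing_a", "missing_b"]
        cs = cl.pairwise_cosines(space, requested)
        assert cs.values.size == 28
        assert cs.coverage == pytest.approx(0.8)

    def test_fewer_than_two_in_corpus(self):
        rng = np.random.default_rng(2)
        space = space_from_vectors(rng.standard_normal((4, 3)))
        with pytest.raises(CohesionUndefinedError):
            cl.pairwise_cosines(space, ["gene000", "nope"])


# ---------------------------------------------------------------------------
# corpus-level properties
# ---------------------------------------------------------------------------

def _mean_within_module_cosine(signal_term_fraction: float, seed: int = 0) -> float:
    cfg = tiny_config(signal_term_fraction=signal_term_fraction, seed=seed)
    corpus, truth = sd.generate_corpus(cfg)
    space = cl.build_space(corpus, rank=60, seed=seed)
    means = []
    for members in truth.modules.values():
        cs = cl.pairwise_cosines(space, members)
        means.append(float(cs.values.mean()))
    return float(np.mean(means))


def test_within_module_cosine_increases_with_signal():
    means = [_mean_within_module_cosine(s) for s in (0.0, 0.25, 0.5, 0.75)]
    assert all(b > a for a, b in zip(means, means[1:])), means


def test_corpus_to_space_determinism():
    cfg = tiny_config(seed=9)
    corpus1, _ = sd.generate_corpus(cfg)
    corpus2, _ = sd.generate_corpus(cfg)
    assert corpus1.documents == corpus2.documents
    space1 = cl.build_space(corpus1, rank=40, seed=9)
    space2 = cl.build_space(corpus2, rank=40, seed=9)
    assert space1.genes == space2.genes
    assert np.array_equal(space1.vectors, space2.vectors)


def test_space_save_load_roundtrip(tmp_path, tiny_space):
    path = tmp_path / "space.npz"
    tiny_space.save(path, params={"rank": 60})
    loaded = cl.ConceptSpace.load(path)
    assert loaded.genes == tiny_space.genes
    assert np.array_equal(loaded.vectors, tiny_space.vectors)
    assert (tmp_path / "space.npz.json").exists()
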