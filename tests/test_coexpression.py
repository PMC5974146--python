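"""Meta-Pearson correlation combination and KNN co-expression scoring."""

import math

import numpy as np
import pytest

from plantmito import coexpression as cx
from plantmito.coexpression import (ExpressionDataset, KNNConfig,
                                    MetaCorrelationMatrix, knn_scores,
                                    log2_transform, map_to_reference,
                                    meta_combine, pearson_matrix)
from plantmito.seqdata import ProteinRecord


def _dataset(matrix, dataset_id="d", already_logged=True):
    matrix = np.asarray(matrix, dtype=float)
    genes = [f"g{i}" for i in range(matrix.shape[0])]
    return ExpressionDataset(dataset_id, genes, matrix, matrix.shape[1],
                             already_logged=already_logged)


class TestLog2Transform:
    def test_zero_maps_to_zero(self):
        d = _dataset([[0.0, 3.0]], already_logged=False)
        out = log2_transform(d)
        assert out.matrix[0, 0] == 0.0
        assert out.matrix[0, 1] == 2.0  # log2(3+1)

    def test_already_logged_is_identity(self):
        d = _dataset([[-1.0, 2.0]], already_logged=True)
        assert log2_transform(d) is d

    def test_negative_values_rejected(self):
        d = _dataset([[-1.0, 2.0]], already_logged=False)
        with pytest.raises(cx.ExpressionError):
            log2_transform(d)


class TestPearsonMatrix:
    def test_self_correlation_is_one(self):
        r = pearson_matrix(_dataset([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]]))
        assert r[0, 0] == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        r = pearson_matrix(_dataset([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]]))
        assert r[0, 1] == pytest.approx(-1.0)

    def test_hand_computed_pair(self):
        # direct Pearson formula on (1,2,4) vs (1,3,5): cov 2, sds
        # sqrt(14/9) and sqrt(8/3) -> r = 0.98198...
        r = pearson_matrix(_dataset([[1.0, 2.0, 4.0], [1.0, 3.0, 5.0]]))
        assert r[0, 1] == pytest.approx(0.9819805060619656, abs=1e-12)

    def test_zero_variance_gene_flagged_missing(self):
        r = pearson_matrix(_dataset([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]]))
        assert np.isnan(r[0, 1]) and np.isnan(r[0, 0])
        assert r[1, 1] == pytest.approx(1.0)


class TestMetaCombine:
    def test_single_dataset_identity(self):
        r = np.array([[1.0, 0.42], [0.42, 1.0]])
        meta = meta_combine([r], [10], ["a", "b"])
        assert meta.values[0, 1] == pytest.approx(0.42, abs=1e-9)
        assert meta.coverage[0, 1] == 1

    def test_perfect_correlation_fixed_point(self):
        r = np.ones((2, 2))
        meta = meta_combine([r, r], [10, 20], ["a", "b"])
        assert meta.values[0, 1] == pytest.approx(1.0, abs=1e-5)

    def test_two_dataset_hand_case(self):
        # z = (7*atanh(0.5) + 17*atanh(0.8)) / 24 = 0.9384 -> tanh = 0.7345
        r1 = np.array([[1.0, 0.5], [0.5, 1.0]])
        r2 = np.array([[1.0, 0.8], [0.8, 1.0]])
        meta = meta_combine([r1, r2], [10, 20], ["a", "b"])
        assert meta.values[0, 1] == pytest.approx(0.7345, abs=5e-4)

    def test_symmetric_and_order_invariant(self):
        rng = np.random.default_rng(4)
        mats, ns = [], []
        for n in (8, 15, 30):
            x = rng.normal(size=(4, n))
            mats.append(np.corrcoef(x))
            ns.append(n)
        genes = list("abcd")
        meta = meta_combine(mats, ns, genes)
        np.testing.assert_allclose(meta.values, meta.values.T)
        rev = meta_combine(mats[::-1], ns[::-1], genes)
        np.testing.assert_allclose(meta.values, rev.values)

    def test_equal_r_equal_n_fixed_point(self):
        r = np.array([[1.0, 0.37], [0.37, 1.0]])
        meta = meta_combine([r, r, r], [12, 12, 12], ["a", "b"])
        assert meta.values[0, 1] == pytest.approx(0.37, abs=1e-9)

    def test_uncovered_pair_missing(self):
        r1 = np.array([[1.0, np.nan], [np.nan, 1.0]])
        meta = meta_combine([r1], [10], ["a", "b"])
        assert np.isnan(meta.values[0, 1])
        assert meta.coverage[0, 1] == 0

    def test_all_tiny_samples_rejected(self):
        r = np.eye(2)
        with pytest.raises(cx.ExpressionError):
            meta_combine([r, r], [3, 2], ["a", "b"])


def _meta_from_query_corrs(corrs):
    """Meta matrix with one query gene q and training genes t00..tNN."""
    genes = ["q"] + [f"t{i:02d}" for i in range(len(corrs))]
    n = len(genes)
    values = np.eye(n)
    for i, r in enumerate(corrs, start=1):
        values[0, i] = values[i, 0] = r
    return MetaCorrelationMatrix(genes, values, np.ones((n, n), dtype=int))


class TestKNNScores:
    def test_saturated_positives(self):
        meta = _meta_from_query_corrs(np.linspace(0.9, 0.1, 8))
        config = KNNConfig([f"t{i:02d}" for i in range(8)], ["positive"] * 8,
                           k_percents=(25.0, 50.0))
        np.testing.assert_array_equal(knn_scores("q", meta, config), [1.0, 1.0])

    def test_top5_fraction_hand_case(self):
        # top-5 neighbors labeled +,-,+,+,- -> score 0.6 at k=5
        meta = _meta_from_query_corrs(np.linspace(0.9, 0.1, 10))
        labels = ["positive", "negative", "positive", "positive", "negative",
                  "negative", "negative", "negative", "negative", "negative"]
        config = KNNConfig([f"t{i:02d}" for i in range(10)], labels,
                           k_percents=(50.0,))
        assert knn_scores("q", meta, config)[0] == pytest.approx(0.6)

    def test_default_config_gives_five_scores(self):
        meta = _meta_from_query_corrs(np.linspace(0.9, 0.1, 10))
        config = KNNConfig([f"t{i:02d}" for i in range(10)], ["positive"] * 10)
        assert knn_scores("q", meta, config).shape == (5,)

    def test_neighbor_counts_match_published_percentages(self):
        config = KNNConfig([f"g{i}" for i in range(2000)], ["positive"] * 2000)
        assert config.neighbor_counts() == [5, 10, 20, 40, 80]

    def test_query_never_counts_itself(self):
        genes = ["q"] + [f"t{i:02d}" for i in range(4)]
        n = len(genes)
        values = np.full((n, n), 0.2)
        np.fill_diagonal(values, 1.0)
        meta = MetaCorrelationMatrix(genes, values, np.ones((n, n), dtype=int))
        config = KNNConfig(genes, ["positive"] + ["negative"] * 4,
                           k_percents=(80.0,))
        # q is itself a positive training gene; with self excluded the top-4
        # neighbors are all negative
        assert knn_scores("q", meta, config)[0] == 0.0

    def test_monotone_in_labels(self):
        rng = np.random.default_rng(9)
        corrs = rng.uniform(-1, 1, 12)
        meta = _meta_from_query_corrs(corrs)
        genes = [f"t{i:02d}" for i in range(12)]
        labels = ["negative"] * 12
        base = knn_scores("q", meta, KNNConfig(genes, labels))
        for flip in range(12):
            flipped = list(labels)
            flipped[flip] = "positive"
            up = knn_scores("q", meta, KNNConfig(genes, flipped))
            assert (up >= base).all()

    def test_agrees_with_brute_force_oracle_on_50_genes(self):
        rng = np.random.default_rng(11)
        for trial in range(5):
            genes = [f"t{i:02d}" for i in range(50)]
            all_genes = ["q"] + genes
            n = 51
            values = np.eye(n)
            corrs = rng.uniform(-1, 1, 50)
            # some uncovered pairs
            corrs[rng.choice(50, 5, replace=False)] = np.nan
            values[0, 1:] = values[1:, 0] = corrs
            meta = MetaCorrelationMatrix(all_genes, values,
                                         np.isfinite(values).astype(int))
            labels = rng.choice(["positive", "negative"], 50).tolist()
            config = KNNConfig(genes, labels)
            got = knn_scores("q", meta, config)
            # oracle: explicit full sort on (covered desc-corr, gene id)
            key = sorted(
                range(50),
                key=lambda i: (np.isnan(corrs[i]),
                               -(corrs[i] if not np.isnan(corrs[i]) else 0.0),
                               genes[i]))
            for j, k in enumerate(config.neighbor_counts()):
                top = [labels[i] for i in key[:k]]
                expect = sum(lab == "positive" for lab in top) / k
                assert got[j] == pytest.approx(expect)

    def test_empty_training_rejected(self):
        with pytest.raises(cx.ExpressionError):
            KNNConfig([], [])


class TestMapping:
    def test_lookup_attaches_gene_id(self, tmp_path):
        path = tmp_path / "map.tsv"
        path.write_text("p1\tAT1G01010\n")
        records = map_to_reference(
            [ProteinRecord("p1", "ACDE"), ProteinRecord("p2", "ACDE")], path)
        assert records[0].gene_id == "AT1G01010"
        assert records[1].gene_id is None

    def test_conflicting_rows_rejected(self, tmp_path):
        path = tmp_path / "map.tsv"
        path.write_text("p1\tAT1G01010\np1\tAT2G02020\n")
        with pytest.raises(cx.MappingError):
            map_to_reference([ProteinRecord("p1", "ACDE")], path)


def test_expression_manifest_round_trip(tmp_path):
    rng = np.random.default_rng(6)
    d = _dataset(rng.normal(size=(5, 12)), dataset_id="DS00")
    cx.write_expression(tmp_path / "DS00.tsv", d)
    (tmp_path / "manifest.yaml").write_text(
        "- dataset_id: DS00\n  path: DS00.tsv\n  n_samples: 12\n"
        "  already_logged: true\n")
    back = cx.read_manifest(tmp_path / "manifest.yaml")
    assert len(back) == 1 and back[0].dataset_id == "DS00"
    np.testing.assert_allclose(back[0].matrix, d.matrix, atol=1e-12)


def test_meta_matrix_text_round_trip(tmp_path):
    rng = np.random.default_rng(8)
    x = rng.normal(size=(4, 10))
    meta = cx.build_meta_matrix([_dataset(x)])
    cx.write_meta_matrix(tmp_path / "meta.tsv", meta)
    back = cx.read_meta_matrix(tmp_path / "meta.tsv")
    assert back.genes == meta.genes
    np.testing.assert_allclose(back.values, meta.values, atol=1e-10)
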