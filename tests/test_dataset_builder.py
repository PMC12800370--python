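"""Feature fusion, constrained negative sampling, CV splits, standardization."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from synlethal.containers import EmbeddingTable, GeneProteinMap, canonical_pair
from synlethal.dataset_builder import (
    GeneFeatureTable,
    Standardizer,
    build_balanced_dataset,
    fuse_features,
    resolve_gene_map,
    sample_negatives,
    split_cv,
)


def make_tables(protein_ids, d_seq=4, d_ppi=3, d_struct=2, seed=0):
    rng = np.random.default_rng(seed)
    return (
        EmbeddingTable(protein_ids, rng.standard_normal((len(protein_ids), d_seq))),
        EmbeddingTable(protein_ids, rng.standard_normal((len(protein_ids), d_ppi))),
        EmbeddingTable(protein_ids, rng.standard_normal((len(protein_ids), d_struct))),
    )


def random_features(genes, dim=6, seed=0):
    rng = np.random.default_rng(seed)
    return GeneFeatureTable(
        EmbeddingTable(list(genes), rng.standard_normal((len(genes), dim))),
        {"seq": dim, "ppi": 0, "struct": 0},
    )


class TestFuseFeatures:
    def test_full_overlap_shapes(self):
        seq, ppi, struct = make_tables(["p1", "p2", "p3"])
        gmap = GeneProteinMap({"g1": "p1", "g2": "p2", "g3": "p3"})
        fused = fuse_features(seq, ppi, struct, gmap)
        assert len(fused.genes) == 3
        assert fused.dim == 4 + 3 + 2
        np.testing.assert_array_equal(
            fused.table["g1"], np.concatenate([seq["p1"], ppi["p1"], struct["p1"]])
        )

    def test_missing_block_excludes_gene(self):
        seq, _, struct = make_tables(["p1", "p2"])
        ppi = EmbeddingTable(["p1"], np.ones((1, 3)))
        gmap = GeneProteinMap({"g1": "p1", "g2": "p2"})
        fused = fuse_features(seq, ppi, struct, gmap)
        assert fused.genes == ["g1"]
        assert fused.n_excluded == 1

    def test_valid_set_is_three_way_intersection(self):
        rng = np.random.default_rng(3)
        ids = [f"p{i}" for i in range(30)]
        subsets = [sorted(rng.choice(ids, 20, replace=False)) for _ in range(3)]
        seq = EmbeddingTable(subsets[0], rng.standard_normal((20, 4)))
        ppi = EmbeddingTable(subsets[1], rng.standard_normal((20, 3)))
        struct = EmbeddingTable(subsets[2], rng.standard_normal((20, 2)))
        gmap = GeneProteinMap({f"g{i}": f"p{i}" for i in range(30)})
        fused = fuse_features(seq, ppi, struct, gmap)
        expected = set(subsets[0]) & set(subsets[1]) & set(subsets[2])
        assert len(fused.genes) == len(expected)

    def test_empty_intersection_errors(self):
        seq, ppi, struct = make_tables(["p1"])
        with pytest.raises(ValueError):
            fuse_features(seq, ppi, struct, GeneProteinMap({"g9": "p9"}))


class TestResolveGeneMap:
    def test_longest_sequence_wins(self):
        entries = [("g1", "pA"), ("g1", "pB")]
        gmap = resolve_gene_map(entries, {"pA": "AA", "pB": "AAAA"})
        assert gmap.protein_for("g1") == "pB"

    def test_tie_breaks_to_smaller_id(self):
        gmap = resolve_gene_map(
            [("g1", "pB"), ("g1", "pA")], {"pA": "AA", "pB": "AA"}
        )
        assert gmap.protein_for("g1") == "pA"


class TestSampleNegatives:
    def test_full_enumeration_case(self):
        out = sample_negatives({"a", "b", "c"}, {("a", "b")}, set(), 2, seed=0)
        assert sorted(out) == [("a", "c"), ("b", "c")]

    def test_infeasible_target_names_maximum(self):
        with pytest.raises(ValueError, match="only 0"):
            sample_negatives({"a", "b"}, {("a", "b")}, set(), 1, seed=0)

    def test_orientation_of_known_pairs_is_irrelevant(self):
        out = sample_negatives({"a", "b", "c"}, {("b", "a")}, set(), 2, seed=1)
        assert ("a", "b") not in out

    @pytest.mark.parametrize("seed", range(5))
    def test_disjoint_distinct_exact_count(self, seed):
        rng = np.random.default_rng(seed)
        genes = {f"g{i}" for i in range(30)}
        all_pairs = [
            canonical_pair(a, b) for a, b in itertools.combinations(sorted(genes), 2)
        ]
        P = set(map(tuple, rng.choice(all_pairs, 60, replace=False)))
        N = set(map(tuple, rng.choice(all_pairs, 20, replace=False))) - P
        out = sample_negatives(genes, P, N, 150, seed=seed)
        assert len(out) == 150
        assert len(set(out)) == 150
        assert not (set(out) & (P | N))

    def test_deterministic(self):
        genes = {f"g{i}" for i in range(20)}
        assert sample_negatives(genes, set(), set(), 50, seed=7) == sample_negatives(
            genes, set(), set(), 50, seed=7
        )


class TestBuildBalancedDataset:
    def _inputs(self, n_genes=30, n_pos=40, n_known=12, seed=0):
        rng = np.random.default_rng(seed)
        genes = [f"g{i:02d}" for i in range(n_genes)]
        pairs = [
            canonical_pair(a, b) for a, b in itertools.combinations(genes, 2)
        ]
        idx = rng.choice(len(pairs), n_pos + n_known, replace=False)
        P = {pairs[k] for k in idx[:n_pos]}
        N = {pairs[k] for k in idx[n_pos:]}
        return P, N, random_features(genes, seed=seed)

    def test_known_negatives_exhausted_before_sampling(self):
        P, N, feats = self._inputs(n_pos=40, n_known=12)
        ds = build_balanced_dataset(P, N, feats, ratio=(1, 1), seed=0)
        assert ds.report["n_known_negatives_used"] == 12
        assert ds.report["n_negatives_sampled"] == 28
        assert (ds.y == 0).sum() == 40

    def test_ratio_one_to_three(self):
        P, N, feats = self._inputs(n_pos=20, n_known=5)
        ds = build_balanced_dataset(P, N, feats, ratio=(1, 3), seed=0)
        assert (ds.y == 1).sum() == 20
        assert (ds.y == 0).sum() == 60

    def test_oversupplied_known_negatives_subsampled(self):
        P, N, feats = self._inputs(n_pos=10, n_known=25)
        ds = build_balanced_dataset(P, N, feats, ratio=(1, 1), seed=0)
        assert ds.report["n_negatives_sampled"] == 0
        assert (ds.y == 0).sum() == 10

    def test_feature_rows_reconstruct_from_gene_vectors(self):
        P, N, feats = self._inputs()
        ds = build_balanced_dataset(P, N, feats, ratio=(1, 1), seed=1)
        for i, (a, b) in enumerate(zip(ds.pairs["gene_a"], ds.pairs["gene_b"])):
            assert a < b  # canonical order
            np.testing.assert_array_equal(
                ds.X[i], np.concatenate([feats.table[a], feats.table[b]])
            )

    def test_reproducible_given_seed(self):
        P, N, feats = self._inputs()
        d1 = build_balanced_dataset(P, N, feats, ratio=(1, 1), seed=5)
        d2 = build_balanced_dataset(P, N, feats, ratio=(1, 1), seed=5)
        assert d1.pairs.equals(d2.pairs)
        np.testing.assert_array_equal(d1.X, d2.X)


class TestSplitCV:
    def _dataset(self, n_rows=1000, seed=0):
        rng = np.random.default_rng(seed)
        genes = [f"g{i:03d}" for i in range(200)]
        pairs = [
            canonical_pair(a, b) for a, b in itertools.combinations(genes, 2)
        ]
        idx = rng.choice(len(pairs), n_rows, replace=False)
        P = {pairs[k] for k in idx[: n_rows // 2]}
        N = {pairs[k] for k in idx[n_rows // 2 :]}
        return build_balanced_dataset(P, N, random_features(genes), (1, 1), seed=seed)

    def test_fold_sizes_640_160_200(self):
        ds = split_cv(self._dataset(1000), folds=5, seed=0)
        for fold in range(5):
            tr, va, te = ds.fold_indices(fold)
            assert abs(len(tr) - 640) <= 1
            assert abs(len(va) - 160) <= 1
            assert abs(len(te) - 200) <= 1

    def test_test_sets_partition_dataset(self):
        ds = split_cv(self._dataset(1000), folds=5, seed=1)
        tests = [set(ds.fold_indices(f)[2]) for f in range(5)]
        assert sum(len(t) for t in tests) == 1000
        assert set().union(*tests) == set(range(1000))

    def test_no_leakage_within_fold(self):
        ds = split_cv(self._dataset(500), folds=5, seed=2)
        for fold in range(5):
            tr, va, te = ds.fold_indices(fold)
            assert not (set(te) & set(tr))
            assert not (set(te) & set(va))
            assert not (set(tr) & set(va))

    def test_stratified_within_two_percent(self):
        ds = split_cv(self._dataset(1000), folds=5, seed=3)
        global_rate = ds.y.mean()
        for fold in range(5):
            for part in ds.fold_indices(fold):
                assert abs(ds.y[part].mean() - global_rate) <= 0.02

    def test_deterministic(self):
        d1 = split_cv(self._dataset(200), folds=5, seed=4)
        d2 = split_cv(self._dataset(200), folds=5, seed=4)
        assert d1.assignments.equals(d2.assignments)


class TestStandardizer:
    def test_train_rows_become_zero_mean_unit_sd(self):
        X = np.random.default_rng(0).standard_normal((50, 7)) * 3 + 5
        Z = Standardizer().fit_transform(X)
        np.testing.assert_allclose(Z.mean(axis=0), 0, atol=1e-9)
        np.testing.assert_allclose(Z.std(axis=0), 1, atol=1e-9)

    def test_constant_dimension_passes_through(self):
        X = np.column_stack([np.full(10, 3.0), np.arange(10.0)])
        scaler = Standardizer().fit(X)
        Z = scaler.transform(X)
        np.testing.assert_array_equal(Z[:, 0], 0.0)  # centered, unscaled
        assert scaler.scale_[0] == 1.0

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.integers(0, 10_000))
    def test_inverse_transform_roundtrip(self, seed):
        X = np.random.default_rng(seed).uniform(-10, 10, (20, 5))
        scaler = Standardizer().fit(X)
        np.testing.assert_allclose(
            scaler.inverse_transform(scaler.transform(X)), X, atol=1e-9
        )

    def test_dimension_mismatch(self):
        scaler = Standardizer().fit(np.ones((4, 3)))
        with pytest.raises(ValueError):
            scaler.transform(np.ones((4, 2)))
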