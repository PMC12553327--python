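import numpy as np
import pytest

import rfgrs
from rfgrs import (Forest, ForestConfig, LDBlockSpec, PhenotypeTable,
                   fit_forest, load_forest, oob_proba, predict_proba,
                   save_forest)

from conftest import make_genotypes


def traverse_oracle(forest: Forest, X: np.ndarray) -> np.ndarray:
    """Pure-Python re-implementation of probability-machine prediction."""
    out = np.zeros(X.shape[0])
    for i in range(X.shape[0]):
        total = 0.0
        for tree in forest.trees:
            node = 0
            while tree.feature[node] >= 0:
                f = tree.feature[node]
                if forest.is_categorical[f]:
                    go_left = X[i, f] == tree.split_val[node]
                else:
                    go_left = X[i, f] < tree.split_val[node]
                node = tree.left[node] if go_left else tree.right[node]
            total += tree.leaf_prop[node]
        out[i] = total / len(forest.trees)
    return out


def gini_gain(y_left, y_right):
    def gini(y):
        if len(y) == 0:
            return 0.0
        p = np.mean(y)
        return 2 * p * (1 - p)

    y_all = np.concatenate([y_left, y_right])
    n = len(y_all)
    return gini(y_all) - (len(y_left) * gini(y_left)
                          + len(y_right) * gini(y_right)) / n


@pytest.fixture
def signal_data(rng):
    spec = LDBlockSpec.uniform_blocks(20, rho=0.3, maf_range=(0.2, 0.5))
    G = rfgrs.simulate_genotypes(80, spec, seed=51)
    eta = 1.5 * (G.counts[:, 3].astype(float) - 1)
    y = (rng.random(80) < 1 / (1 + np.exp(-eta))).astype(np.int8)
    return G, PhenotypeTable(G.samples, y)


class TestFitting:
    def test_pure_tree_reproduces_training_labels(self, signal_data):
        G, ph = signal_data
        # drop duplicated feature rows with conflicting labels
        _, first = np.unique(G.counts, axis=0, return_index=True)
        rows = np.sort(first)
        G, ph = G.subset_samples(rows), ph.subset_samples(rows)
        cfg = ForestConfig(ntree=1, mtry=G.n_snps, min_node_size=1,
                           bootstrap=False, seed=1)
        f = fit_forest(G, ph, cfg)
        np.testing.assert_allclose(predict_proba(f, G), ph.y.astype(float))

    def test_deterministic_given_seed(self, signal_data):
        G, ph = signal_data
        cfg = ForestConfig(ntree=20, seed=7)
        fa, fb = fit_forest(G, ph, cfg), fit_forest(G, ph, cfg)
        for ta, tb in zip(fa.trees, fb.trees):
            np.testing.assert_array_equal(ta.feature, tb.feature)
            np.testing.assert_array_equal(ta.split_val, tb.split_val)
            np.testing.assert_array_equal(ta.leaf_prop, tb.leaf_prop)

    def test_single_weighted_feature_dominates_splits(self, signal_data):
        G, ph = signal_data
        w = np.zeros(G.n_snps)
        w[5] = 1.0
        f = fit_forest(G, ph, ForestConfig(ntree=10, mtry=4, split_weights=w,
                                           seed=3))
        for tree in f.trees:
            internal = tree.feature[tree.feature >= 0]
            assert (internal == 5).all()

    def test_uniform_weights_equal_unweighted(self, signal_data):
        G, ph = signal_data
        cfg_w = ForestConfig(ntree=10, seed=9, split_weights=np.ones(G.n_snps))
        cfg_u = ForestConfig(ntree=10, seed=9, split_weights=None)
        fw, fu = fit_forest(G, ph, cfg_w), fit_forest(G, ph, cfg_u)
        for tw, tu in zip(fw.trees, fu.trees):
            np.testing.assert_array_equal(tw.feature, tu.feature)
            np.testing.assert_array_equal(tw.split_val, tu.split_val)

    def test_all_one_class_gives_degenerate_stumps(self):
        G = make_genotypes([[0, 1], [1, 2], [2, 0], [0, 0]])
        ph = PhenotypeTable(G.samples, [1, 1, 1, 1])
        f = fit_forest(G, ph, ForestConfig(ntree=5, seed=1))
        assert all(t.n_nodes == 1 for t in f.trees)
        np.testing.assert_allclose(predict_proba(f, G), 1.0)

    def test_mtry_exceeding_features_rejected(self, signal_data):
        G, ph = signal_data
        with pytest.raises(ValueError, match="mtry"):
            fit_forest(G, ph, ForestConfig(ntree=1, mtry=G.n_snps + 1))

    def test_chosen_splits_maximize_gini_gain(self):
        """Every internal node's split must equal the exhaustive argmax."""
        rng = np.random.default_rng(77)
        counts = rng.integers(0, 3, size=(18, 6)).astype(np.int8)
        G = make_genotypes(counts)
        y = (counts[:, 2] == 1).astype(np.int8)
        y[:3] ^= 1  # a bit of noise so trees are nontrivial
        ph = PhenotypeTable(G.samples, y)
        f = fit_forest(G, ph, ForestConfig(ntree=1, mtry=6, min_node_size=1,
                                           bootstrap=False, seed=5))
        tree = f.trees[0]
        X = counts.astype(float)

        # reconstruct each node's sample set by routing all samples
        node_members = {0: list(range(18))}
        stack = [0]
        while stack:
            node = stack.pop()
            if tree.feature[node] < 0:
                continue
            fidx, sval = tree.feature[node], tree.split_val[node]
            members = node_members[node]
            left = [i for i in members if X[i, fidx] == sval]
            right = [i for i in members if X[i, fidx] != sval]
            node_members[tree.left[node]] = left
            node_members[tree.right[node]] = right
            stack += [tree.left[node], tree.right[node]]

            # exhaustive enumeration over all features x partitions
            best = 0.0
            for cand in range(6):
                for cat in (0.0, 1.0, 2.0):
                    l = y[[i for i in members if X[i, cand] == cat]]
                    r = y[[i for i in members if X[i, cand] != cat]]
                    if len(l) and len(r):
                        best = max(best, gini_gain(l, r))
            chosen = gini_gain(y[left], y[right])
            assert chosen == pytest.approx(best, abs=1e-12)


class TestPrediction:
    def test_matches_traversal_oracle_bitwise(self, signal_data):
        G, ph = signal_data
        f = fit_forest(G, ph, ForestConfig(ntree=30, seed=13))
        G_new = rfgrs.simulate_genotypes(
            10, LDBlockSpec.uniform_blocks(20, rho=0.3, maf_range=(0.2, 0.5)),
            seed=99)
        pred = predict_proba(f, G_new)
        oracle = traverse_oracle(f, G_new.counts.astype(float))
        np.testing.assert_array_equal(pred, oracle)

    def test_single_tree_forest_returns_leaf_proportions(self, signal_data):
        G, ph = signal_data
        f = fit_forest(G, ph, ForestConfig(ntree=1, seed=2))
        pred = predict_proba(f, G)
        assert set(np.round(pred, 12)) <= set(np.round(f.trees[0].leaf_prop, 12))

    def test_schema_error_on_missing_snp(self, signal_data):
        G, ph = signal_data
        f = fit_forest(G, ph, ForestConfig(ntree=2, seed=2))
        with pytest.raises(rfgrs.SchemaError):
            predict_proba(f, G.subset_snps(G.snp_ids[:5]))

    def test_covariates_enter_prediction(self, rng):
        G = make_genotypes(rng.integers(0, 3, (60, 3)).astype(np.int8))
        cov = rng.standard_normal((60, 1))
        y = (cov[:, 0] > 0).astype(np.int8)
        ph = PhenotypeTable(G.samples, y, covariates=cov,
                            covariate_names=["c"])
        f = fit_forest(G, ph, ForestConfig(ntree=50, seed=4))
        pred = predict_proba(f, G, covariates=cov)
        assert rfgrs.auc(y, pred) > 0.9
        with pytest.raises(rfgrs.SchemaError, match="covariate"):
            predict_proba(f, G)


class TestOob:
    def test_every_sample_gets_oob_trees(self, signal_data):
        G, ph = signal_data
        G2 = G.subset_samples(range(80))
        f = fit_forest(G2, ph, ForestConfig(ntree=200, seed=6))
        oob = oob_proba(f)
        assert not np.isnan(oob).any()
        assert ((oob >= 0) & (oob <= 1)).all()

    def test_single_oob_tree_equals_its_leaf_value(self, signal_data):
        G, ph = signal_data
        f = fit_forest(G, ph, ForestConfig(ntree=3, seed=8))
        oob = oob_proba(f)
        counts_out = (f.inbag == 0).sum(axis=0)
        singles = np.flatnonzero(counts_out == 1)
        if singles.size == 0:
            pytest.skip("no sample OOB for exactly one tree at this seed")
        i = singles[0]
        t = int(np.flatnonzero(f.inbag[:, i] == 0)[0])
        single_tree = Forest(trees=[f.trees[t]], snp_ids=f.snp_ids,
                             covariate_names=[], is_categorical=f.is_categorical,
                             config=f.config, inbag=None)
        expected = predict_proba(single_tree, G.subset_samples([i]))
        assert oob[i] == pytest.approx(expected[0], abs=0)

    def test_oob_requires_bootstrap(self, signal_data):
        G, ph = signal_data
        f = fit_forest(G, ph, ForestConfig(ntree=2, bootstrap=False, seed=1))
        with pytest.raises(ValueError, match="bootstrap"):
            oob_proba(f)

    def test_oob_error_vanishes_on_deterministic_signal(self, rng):
        """One SNP fully determines y; OOB misclassification goes to zero."""
        spec = LDBlockSpec.uniform_blocks(10, rho=0.0, maf_range=(0.3, 0.5))
        G = rfgrs.simulate_genotypes(500, spec, seed=61)
        y = (G.counts[:, 4] >= 1).astype(np.int8)
        ph = PhenotypeTable(G.samples, y)
        f = fit_forest(G, ph, ForestConfig(ntree=200, seed=62))
        oob = oob_proba(f)
        miss = np.mean((oob > 0.5).astype(int) != y)
        assert miss < 0.01


class TestSerialization:
    def test_roundtrip_predictions_bitwise(self, signal_data, tmp_path):
        G, ph = signal_data
        f = fit_forest(G, ph, ForestConfig(ntree=25, seed=3))
        save_forest(f, tmp_path / "forest.npz")
        back = load_forest(tmp_path / "forest.npz")
        np.testing.assert_array_equal(predict_proba(f, G),
                                      predict_proba(back, G))
        assert back.snp_ids == f.snp_ids

    def test_rejects_foreign_files(self, tmp_path):
        np.savez(tmp_path / "junk.npz", meta=np.frombuffer(b"{}", np.uint8))
        with pytest.raises(ValueError):
            load_forest(tmp_path / "junk.npz")
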