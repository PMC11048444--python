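"""Treelet construction: local PCA, merge order, incremental updates."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hpca import tree as tr


class TestSimilarity:
    def test_self_and_negation(self, rng):
        v = rng.standard_normal(50)
        assert tr.similarity(v, v) == pytest.approx(1.0)
        assert tr.similarity(v, -v) == pytest.approx(-1.0)

    def test_matches_textbook_formula(self):
        x = np.array([1.0, 2.0, 3.0])
        y = np.array([1.0, 2.0, 4.0])
        cov = np.mean((x - x.mean()) * (y - y.mean()))
        expected = cov / (x.std() * y.std())
        assert tr.similarity(x, y) == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            tr.similarity(np.ones(10), np.arange(10.0))


class TestLocalPCA2:
    def test_identical_inputs_degenerate_difference(self, rng):
        v = rng.standard_normal(40)
        node = tr.local_pca2(v, 2 * v + 1)
        assert node.eigenvalues == pytest.approx((2.0, 0.0))
        assert node.diff_degenerate
        assert np.allclose(node.diff_scores, 0)

    def test_anticorrelated_inputs_degenerate_sum(self, rng):
        v = rng.standard_normal(40)
        node = tr.local_pca2(v, -v)
        assert node.eigenvalues == pytest.approx((2.0, 0.0))
        assert node.sum_degenerate

    def test_uncorrelated_isotropic(self):
        n = 1000
        x = np.tile([1.0, -1.0], n // 2)
        y = np.repeat([1.0, -1.0], n // 2)
        node = tr.local_pca2(x, y)
        assert node.eigenvalues == pytest.approx((1.0, 1.0), abs=1e-10)

    def test_eigenvalues_match_2x2_oracle(self, rng):
        """r=0.6 construction: eigen-decomposing [[1, r], [r, 1]] gives
        (1.6, 0.4) and the sum variable is the leading combination."""
        n = 10_000
        a = rng.standard_normal(n)
        b = rng.standard_normal(n)
        x = a
        y = 0.6 * a + np.sqrt(1 - 0.36) * b
        node = tr.local_pca2(x, y)
        r = node.merge_similarity
        w = np.linalg.eigvalsh([[1.0, r], [r, 1.0]])
        assert node.eigenvalues == pytest.approx((w[1], w[0]), abs=1e-12)
        assert node.eigenvalues[0] == pytest.approx(1.6, abs=0.05)
        xs_expected = (x - x.mean()) / x.std() + (y - y.mean()) / y.std()
        assert abs(np.corrcoef(node.sum_scores, xs_expected)[0, 1]) > 0.999999
        # positive loading on the first input
        assert np.corrcoef(node.sum_scores, x)[0, 1] > 0

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_eigen_identities_and_orthogonality(self, seed):
        """At any node: lambda1 = 1+|r|, lambda2 = 1-|r|, lambda1+lambda2 = 2,
        and the sum/difference variables are uncorrelated."""
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(30)
        y = rng.standard_normal(30) + rng.uniform(-1, 1) * x
        node = tr.local_pca2(x, y)
        r = node.merge_similarity
        assert node.lambda1 == pytest.approx(1 + abs(r), abs=1e-10)
        assert node.lambda2 == pytest.approx(1 - abs(r), abs=1e-10)
        assert node.lambda1 + node.lambda2 == pytest.approx(2.0, abs=1e-10)
        assert np.dot(node.sum_scores, node.diff_scores) / 30 == pytest.approx(
            0.0, abs=1e-10
        )


class TestBuildTree:
    def test_duplicate_pairs_merge_first(self, rng):
        """Two orthogonal duplicate pairs: levels 1-2 join the duplicates
        (r=1), level 3 joins the two near-uncorrelated sums."""
        n = 400
        a = rng.standard_normal(n)
        b = rng.standard_normal(n)
        b -= a * (a @ b) / (a @ a)  # exactly orthogonal
        X = np.vstack([a, a, b, b])
        tree = tr.build_tree(X)
        assert tree.nodes[0].merged == (0, 1)
        assert tree.nodes[0].merge_similarity == pytest.approx(1.0, abs=1e-10)
        assert tree.nodes[1].merged == (2, 3)
        assert abs(tree.nodes[2].merge_similarity) < 0.2

    def test_level_count(self, rng):
        X = rng.standard_normal((64, 40))
        tree = tr.build_tree(X)
        assert tree.n_levels == 63
        assert len(tree.active_at(63)) == 1

    def test_two_variables(self, rng):
        x = rng.standard_normal(30)
        X = np.vstack([x, 0.5 * x + rng.standard_normal(30)])
        tree = tr.build_tree(X)
        assert tree.n_levels == 1
        # the sum variable is the leading PC of a positively correlated pair
        assert tree.nodes[0].lambda1 > 1

    def test_active_set_shrinks_by_one(self, rng):
        X = rng.standard_normal((12, 30))
        tree = tr.build_tree(X)
        for l in range(13 - 1):
            assert len(tree.active_at(l)) == 12 - l

    def test_each_variable_consumed_once(self, rng):
        X = rng.standard_normal((20, 25))
        tree = tr.build_tree(X)
        consumed = [v for node in tree.nodes for v in node.merged]
        assert len(consumed) == len(set(consumed))

    def test_incremental_equals_full_recomputation(self, rng):
        """Oracle: replaying the recorded merges with a from-scratch
        correlation matrix at every level reproduces the same merge choices
        and similarities."""
        X = rng.standard_normal((24, 40)) + 0.3 * rng.standard_normal((1, 40))
        tree = tr.build_tree(X)
        V, K = X.shape
        scores = {i: (X[i] - X[i].mean()) / X[i].std() for i in range(V)}
        active = set(range(V))
        for node in tree.nodes:
            # brute-force argmax over the current active set
            best = None
            for i in sorted(active):
                for j in sorted(active):
                    if i >= j:
                        continue
                    r = float(scores[i] @ scores[j]) / K
                    if best is None or r > best[0] + 1e-12:
                        best = (r, i, j)
            assert (best[1], best[2]) == node.merged
            assert best[0] == pytest.approx(node.merge_similarity, abs=1e-9)
            new = tr.local_pca2(scores[best[1]], scores[best[2]]).sum_scores
            nid = V - 1 + node.level
            active -= {best[1], best[2]}
            active.add(nid)
            scores[nid] = new

    def test_two_block_model_merges_within_blocks_first(self, two_block_subjects):
        """On noiseless two-block data the final merge joins the blocks and
        every earlier merge stays within one block."""
        X = np.hstack([s for s in two_block_subjects])
        tree = tr.build_tree(X)
        blocks = [set(range(10)), set(range(10, 20))]
        for node in tree.nodes[:-1]:
            leaves = tree.leaf_set(tree.n_leaves - 1 + node.level)
            assert leaves <= blocks[0] or leaves <= blocks[1]
        last = tree.leaf_set(tree.n_leaves - 1 + tree.n_levels)
        assert last == set(range(20))

    def test_zero_variance_row_rejected(self, rng):
        X = rng.standard_normal((5, 20))
        X[3] = 2.0
        with pytest.raises(ValueError, match="3"):
            tr.build_tree(X)

    def test_dendrogram_and_newick_export(self, rng):
        X = rng.standard_normal((6, 30))
        tree = tr.build_tree(X)
        table = tree.dendrogram()
        assert table.shape == (5, 4)
        assert table[-1, 3] == 6  # root cluster size
        nwk = tree.to_newick()
        assert nwk.endswith(";") and nwk.count("v") == 6
        import dendropy

        t = dendropy.Tree.get(data=nwk, schema="newick")
        assert len(t.leaf_nodes()) == 6
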