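import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_count_matrix, make_residuals
from invitrofidelity.containers import DataError, GeneSignature, ParameterError
from invitrofidelity.similarity import (
    cosine,
    crc_similarity,
    jaccard,
    origin_attribution,
    overlap_vs_reference,
    prevalence_set,
    subset_centroids,
    venn_counts,
)

gene_sets = st.sets(st.sampled_from([f"g{i}" for i in range(30)]), max_size=20)


class TestSetMetrics:
    def test_jaccard_closed_forms(self):
        assert jaccard({"a", "b", "c"}, {"b", "c", "d"}) == 0.5
        assert jaccard({"x"}, {"x"}) == 1.0
        assert jaccard({"x"}, {"y"}) == 0.0
        assert jaccard(set(), set()) == 0.0

    def test_overlap_closed_forms(self):
        assert overlap_vs_reference({"a", "b"}, {"b", "c", "d"}) == pytest.approx(1 / 3)
        assert overlap_vs_reference({"a", "b", "c", "d"}, {"b", "c"}) == 1.0
        assert overlap_vs_reference(set(), {"b"}) == 0.0

    def test_empty_reference_raises(self):
        with pytest.raises(ParameterError):
            overlap_vs_reference({"a"}, set())

    @given(gene_sets, gene_sets.filter(bool))
    @settings(derandomize=True, max_examples=200, deadline=None)
    def test_overlap_always_dominates_jaccard(self, a, b):
        assert overlap_vs_reference(a, b) >= jaccard(a, b) - 1e-12

    @given(gene_sets, gene_sets)
    @settings(derandomize=True, max_examples=100, deadline=None)
    def test_jaccard_symmetric_and_bounded(self, a, b):
        assert jaccard(a, b) == jaccard(b, a)
        assert 0.0 <= jaccard(a, b) <= 1.0


class TestCosine:
    def test_hand_arithmetic_example(self):
        assert cosine([1, 2, 2], [2, 1, 2]) == pytest.approx(8 / 9)

    def test_identity_and_orthogonality(self):
        assert cosine([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)
        assert cosine([1, 0], [0, 1]) == pytest.approx(0.0)

    def test_positive_scale_invariance(self, rng):
        u = rng.normal(size=20)
        v = rng.normal(size=20)
        base = cosine(u, v)
        assert abs(cosine(3.7 * u, v) - base) < 1e-12 * max(1, abs(base))
        assert abs(cosine(u, 41.0 * v) - base) < 1e-12 * max(1, abs(base))

    def test_zero_vector_raises(self):
        with pytest.raises(DataError):
            cosine([0, 0], [1, 2])


class TestOriginAttribution:
    def _sigs(self):
        line_a = GeneSignature("lineA_up", {"a1", "a2", "a3", "a4"}, source="bulk-line")
        line_b = GeneSignature("lineB_up", {"b1", "b2", "b3"}, source="bulk-line")
        return line_a, line_b

    def test_subset_of_line_a_is_attributed_to_a(self):
        line_a, line_b = self._sigs()
        clus = GeneSignature("c0", {"a1", "a2"})
        table, calls = origin_attribution([clus], (line_a, line_b))
        assert calls["c0"] == "lineA_up"
        assert table.scores.loc["c0", "lineA_up"] == 0.5
        assert table.scores.loc["c0", "lineB_up"] == 0.0

    def test_equal_overlap_is_ambiguous(self):
        line_a, line_b = self._sigs()
        clus = GeneSignature("c0", set())
        _, calls = origin_attribution([clus], (line_a, line_b))
        assert calls["c0"] == "ambiguous"

    def test_jaccard_metric_supported(self):
        line_a, line_b = self._sigs()
        clus = GeneSignature("c0", {"a1", "a2", "a3", "a4"})
        table, calls = origin_attribution([clus], (line_a, line_b), metric="jaccard")
        assert table.scores.loc["c0", "lineA_up"] == 1.0
        assert calls["c0"] == "lineA_up"


class TestSubsetCentroids:
    def test_single_cell_label_equals_that_cell(self, rng):
        values = rng.normal(size=(10, 5))
        res = make_residuals(values)
        labels = pd.Series(["solo", "rest", "rest", "rest", "rest"], index=res.cells)
        with pytest.warns(UserWarning, match="only"):
            cent = subset_centroids(res, labels, res.genes)
        assert np.allclose(cent.loc["solo"].values, values[:, 0])

    def test_matches_groupby_mean_oracle(self, rng):
        values = rng.normal(size=(20, 30))
        res = make_residuals(values)
        labels = pd.Series(
            [f"grp{i % 3}" for i in range(30)], index=res.cells
        )
        cent = subset_centroids(res, labels, res.genes)
        df = pd.DataFrame(values.T, index=res.cells, columns=res.genes)
        oracle = df.groupby(labels).mean()
        pd.testing.assert_frame_equal(
            cent.sort_index(), oracle.sort_index(), check_names=False
        )

    def test_empty_basis_raises(self, rng):
        res = make_residuals(rng.normal(size=(5, 6)))
        with pytest.raises(ParameterError):
            subset_centroids(res, pd.Series("x", index=res.cells), [])


class TestCrcSimilarity:
    def test_identical_centroid_scores_one(self, rng):
        basis = [f"g{i}" for i in range(8)]
        q = pd.DataFrame(rng.normal(size=(2, 8)), index=["q0", "q1"], columns=basis)
        r = pd.DataFrame(
            np.vstack([q.loc["q0"].values, rng.normal(size=8)]),
            index=["r0", "r1"],
            columns=basis,
        )
        table = crc_similarity(q, r, basis)
        assert table.scores.loc["q0", "r0"] == pytest.approx(1.0)

    def test_positive_scaling_leaves_scores_unchanged(self, rng):
        basis = [f"g{i}" for i in range(8)]
        q = pd.DataFrame(rng.normal(size=(1, 8)), index=["q0"], columns=basis)
        r = pd.DataFrame(rng.normal(size=(2, 8)), index=["r0", "r1"], columns=basis)
        t1 = crc_similarity(q, r, basis)
        t2 = crc_similarity(q * 5.0, r, basis)
        pd.testing.assert_frame_equal(t1.scores, t2.scores)

    def test_missing_basis_genes_dropped_with_warning(self, rng):
        basis = [f"g{i}" for i in range(8)]
        q = pd.DataFrame(rng.normal(size=(1, 8)), index=["q0"], columns=basis)
        r = pd.DataFrame(
            rng.normal(size=(1, 6)), index=["r0"], columns=basis[:6]
        )
        with pytest.warns(UserWarning, match="dropped 2"):
            table = crc_similarity(q, r, basis)
        assert table.gene_basis == basis[:6]

    def test_empty_union_raises(self, rng):
        q = pd.DataFrame(rng.normal(size=(1, 2)), index=["q0"], columns=["a", "b"])
        with pytest.raises(ParameterError):
            crc_similarity(q, q, [])


class TestPrevalence:
    def test_strict_threshold_boundary(self):
        X = np.zeros((2, 10), dtype=int)
        X[0, :4] = 1  # 40% of cells -> included at tau=0.30
        X[1, :3] = 1  # exactly 30% -> excluded (strict >)
        cm = make_count_matrix(X)
        ps = prevalence_set(cm, cm.cells, tau=0.30)
        assert ps.genes == frozenset({cm.genes[0]})

    def test_matches_dense_fraction_oracle(self, rng):
        X = (rng.uniform(size=(50, 20)) < 0.4).astype(int)
        cm = make_count_matrix(X)
        group = cm.cells[:15]
        ps = prevalence_set(cm, group, tau=0.25)
        oracle = {
            cm.genes[g]
            for g in range(50)
            if (X[g, :15] > 0).sum() / 15 > 0.25
        }
        assert ps.genes == frozenset(oracle)

    def test_monotone_in_tau(self, rng):
        X = rng.poisson(0.6, size=(40, 30))
        cm = make_count_matrix(X)
        lo = prevalence_set(cm, cm.cells, tau=0.2).genes
        hi = prevalence_set(cm, cm.cells, tau=0.5).genes
        assert hi <= lo

    def test_empty_group_raises(self, rng):
        cm = make_count_matrix(rng.poisson(1, size=(5, 5)))
        with pytest.raises(ParameterError):
            prevalence_set(cm, [], tau=0.3)


class TestVennCounts:
    def test_two_set_enumeration(self):
        got = venn_counts({"s1": {"a", "b"}, "s2": {"b", "c"}})
        assert got == {"s1": 1, "s2": 1, "s1&s2": 1}

    def test_identical_sets_all_in_intersection(self):
        got = venn_counts({"x": {"a", "b"}, "y": {"a", "b"}})
        assert got == {"x": 0, "y": 0, "x&y": 2}

    def test_three_disjoint_sets(self):
        got = venn_counts({"a": {1}, "b": {2}, "c": {3}})
        assert got["a"] == got["b"] == got["c"] == 1
        assert got["a&b"] == got["a&c"] == got["b&c"] == got["a&b&c"] == 0

    def test_region_sums_reconstruct_cardinalities(self, rng):
        sets = {
            name: set(rng.choice(50, rng.integers(0, 30), replace=False).tolist())
            for name in ["u", "v", "w"]
        }
        got = venn_counts(sets)
        assert sum(got.values()) == len(sets["u"] | sets["v"] | sets["w"])
        for name in sets:
            total = sum(v for k, v in got.items() if name in k.split("&"))
            assert total == len(sets[name])

    def test_more_than_three_sets_unsupported(self):
        with pytest.raises(ParameterError):
            venn_counts({str(i): {i} for i in range(4)})
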