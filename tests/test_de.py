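import itertools
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from conftest import make_assignment, make_count_matrix, make_residuals
from invitrofidelity.containers import ParameterError
from invitrofidelity.de import annotate_clusters, bh_adjust, extract_signature, wilcoxon_de


def exact_permutation_p(x, y):
    """Full enumeration of the two-sided rank-sum permutation distribution."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    center = len(x) * len(y) / 2
    ranks = stats.rankdata(pooled)
    obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2  # observed U for group x
    obs_dev = abs(obs - center)
    hits = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        u = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2
        if abs(u - center) >= obs_dev - 1e-12:
            hits += 1
        total += 1
    return hits / total


class TestBHAdjust:
    def test_stepup_arithmetic_example(self):
        got = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(got, [0.04, 0.04, 0.04, 0.04])

    def test_all_ones_stay_one(self):
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_single_p_unchanged(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_out_of_range_raises(self):
        with pytest.raises(ParameterError):
            bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    @settings(derandomize=True, max_examples=60, deadline=None)
    def test_permutation_equivariant_and_dominates_raw(self, ps):
        ps = np.asarray(ps)
        adj = bh_adjust(ps)
        assert (adj >= ps - 1e-12).all()
        assert (adj <= 1.0 + 1e-12).all()
        perm = np.random.default_rng(0).permutation(len(ps))
        assert np.allclose(bh_adjust(ps[perm]), adj[perm])

    @given(st.lists(st.floats(0.0001, 1), min_size=2, max_size=30))
    @settings(derandomize=True, max_examples=60, deadline=None)
    def test_monotone_on_sorted_input(self, ps):
        srt = np.sort(ps)
        adj = bh_adjust(srt)
        assert (np.diff(adj) >= -1e-12).all()


def _null_de(seed, n_genes=300, n_in=20, n_out=30):
    rng = np.random.default_rng(seed)
    n = n_in + n_out
    raw = rng.negative_binomial(5, 0.5, size=(n_genes, n))
    vals = rng.standard_normal((n_genes, n))
    cm = make_count_matrix(raw)
    res = make_residuals(vals, clip=np.sqrt(n))
    asn = make_assignment(
        {c: ("in" if i < n_in else "out") for i, c in enumerate(cm.cells)}
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return wilcoxon_de(cm, res, asn)


class TestWilcoxonDE:
    def test_small_group_p_matches_full_permutation_oracle(self, rng):
        for _ in range(5):
            x = rng.standard_normal(6)
            y = rng.standard_normal(6)
            vals = np.concatenate([x, y])[None, :]
            raw = np.ones((1, 12), dtype=int)
            cm = make_count_matrix(raw)
            res = make_residuals(vals, clip=10.0)
            asn = make_assignment(
                {c: ("in" if i < 6 else "out") for i, c in enumerate(cm.cells)}
            )
            de = wilcoxon_de(cm, res, asn)
            p = de[de.cluster == "in"].p_value.iloc[0]
            assert p == pytest.approx(exact_permutation_p(x, y), abs=0.01)

    def test_null_p_values_are_uniform(self):
        de = _null_de(0, n_genes=2000, n_in=50, n_out=100)
        p = de[de.cluster == "in"].p_value.values
        assert stats.kstest(p, "uniform").pvalue > 0.01

    def test_all_zero_gene_gets_p_one_and_zero_lfc(self):
        raw = np.vstack([np.zeros((1, 10), dtype=int), np.ones((1, 10), dtype=int)])
        vals = np.zeros((2, 10))
        cm = make_count_matrix(raw)
        res = make_residuals(vals, clip=1.0)
        asn = make_assignment(
            {c: ("in" if i < 5 else "out") for i, c in enumerate(cm.cells)}
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            de = wilcoxon_de(cm, res, asn)
        row = de[(de.cluster == "in") & (de.gene == cm.genes[0])].iloc[0]
        assert row.p_value == 1.0
        assert row.log2fc == 0.0

    def test_label_symmetry_two_sided_p_preserved(self, rng):
        raw = rng.poisson(3, size=(50, 30))
        vals = rng.standard_normal((50, 30))
        cm = make_count_matrix(raw)
        res = make_residuals(vals, clip=10.0)
        asn = make_assignment(
            {c: ("A" if i < 12 else "B") for i, c in enumerate(cm.cells)}
        )
        de = wilcoxon_de(cm, res, asn)
        a = de[de.cluster == "A"].set_index("gene")
        b = de[de.cluster == "B"].set_index("gene")
        assert np.allclose(a.p_value, b.p_value, atol=1e-12)
        assert np.allclose(a.log2fc, -b.log2fc, atol=1e-9)

    def test_adjusted_dominates_raw(self):
        de = _null_de(1)
        assert (de.p_adjusted >= de.p_value - 1e-12).all()

    def test_tiny_cluster_skipped_with_warning(self, rng):
        raw = rng.poisson(3, size=(10, 12))
        cm = make_count_matrix(raw)
        res = make_residuals(rng.standard_normal((10, 12)), clip=5.0)
        labels = {c: ("a" if i < 5 else "b") for i, c in enumerate(cm.cells)}
        labels[cm.cells[-1]] = "tiny"
        with pytest.warns(UserWarning, match="fewer than 2"):
            de = wilcoxon_de(cm, res, make_assignment(labels))
        assert set(de.cluster) == {"a", "b"}


class TestExtractSignature:
    def _frame(self):
        return pd.DataFrame(
            {
                "gene": ["g1", "g2", "g3", "g4"],
                "cluster": "c",
                "log2fc": [2.0, 2.0001, 5.0, 5.0],
                "p_value": [0.001] * 4,
                "p_adjusted": [0.001, 0.001, 0.01, 0.0099],
            }
        )

    def test_thresholds_are_strict(self):
        sig = extract_signature(self._frame(), "c", lfc_min=2.0, padj_max=0.01)
        # g1 fails lfc (exactly 2), g3 fails padj (exactly 0.01)
        assert sig.genes == frozenset({"g2", "g4"})

    def test_missing_cluster_raises(self):
        with pytest.raises(ParameterError):
            extract_signature(self._frame(), "nope")

    def test_monotone_in_both_thresholds(self):
        de = _null_de(2)
        base = extract_signature(de, "in", lfc_min=0.1, padj_max=0.5).genes
        tighter_lfc = extract_signature(de, "in", lfc_min=0.5, padj_max=0.5).genes
        tighter_p = extract_signature(de, "in", lfc_min=0.1, padj_max=0.1).genes
        assert tighter_lfc <= base and tighter_p <= base

    def test_planted_markers_recovered(self, rng):
        # 30 cells in-cluster with 20 planted up-genes at 16x
        n_genes, n_in, n_out = 300, 40, 80
        mu = np.full((n_genes, 1), 2.0)
        X_in = rng.poisson(mu * np.where(np.arange(n_genes)[:, None] < 20, 16, 1), (n_genes, n_in))
        X_out = rng.poisson(mu, (n_genes, n_out))
        X = np.hstack([X_in, X_out])
        cm = make_count_matrix(X)
        from invitrofidelity.normalize import pearson_residual_normalize

        res = pearson_residual_normalize(cm)
        asn = make_assignment(
            {c: ("in" if i < n_in else "out") for i, c in enumerate(cm.cells)}
        )
        de = wilcoxon_de(cm, res, asn)
        sig = extract_signature(de, "in")
        planted = set(cm.genes[:20])
        recall = len(sig.genes & planted) / 20
        assert recall >= 0.9


class TestAnnotateClusters:
    def _fixture(self, rng):
        # cluster "0" has ISC markers elevated, cluster "1" has TA markers
        X = rng.poisson(1.0, size=(30, 40))
        X[0:3, :20] += 20  # ISC markers in cluster 0
        X[5:7, 20:] += 20  # TA markers in cluster 1
        cm = make_count_matrix(X)
        vals = X.astype(float)
        asn = make_assignment(
            {c: ("0" if i < 20 else "1") for i, c in enumerate(cm.cells)}
        )
        markers = {
            "ISC": [cm.genes[0], cm.genes[1], cm.genes[2]],
            "TA": [cm.genes[5], cm.genes[6]],
        }
        return cm, vals, asn, markers

    def test_marker_elevated_cluster_gets_its_label(self, rng):
        cm, vals, asn, markers = self._fixture(rng)
        labels, scores = annotate_clusters(cm, vals, cm.genes, asn, markers)
        assert labels["0"] == "ISC" and labels["1"] == "TA"
        assert set(scores.columns) == {"ISC", "TA"}

    def test_identical_marker_lists_tie_break_lexicographic_with_warning(self, rng):
        cm, vals, asn, markers = self._fixture(rng)
        markers = {"zeta": markers["ISC"], "alpha": markers["ISC"]}
        with pytest.warns(UserWarning, match="identical marker lists"):
            labels, _ = annotate_clusters(cm, vals, cm.genes, asn, markers)
        assert labels["0"] == "alpha"

    def test_flat_expression_unassigned_above_floor(self, rng):
        X = np.ones((10, 20), dtype=int)
        cm = make_count_matrix(X)
        asn = make_assignment(
            {c: ("0" if i < 10 else "1") for i, c in enumerate(cm.cells)}
        )
        markers = {"t1": [cm.genes[0]], "t2": [cm.genes[1]]}
        labels, _ = annotate_clusters(
            cm, X.astype(float), cm.genes, asn, markers, floor=0.5
        )
        assert (labels == "unassigned").all()

    def test_no_markers_in_universe_raises(self, rng):
        cm, vals, asn, _ = self._fixture(rng)
        with pytest.raises(ParameterError):
            annotate_clusters(cm, vals, cm.genes, asn, {"t": ["NOPE"]})
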