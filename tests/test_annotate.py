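import math

import numpy as np
import pytest

from hieranno.annotate import (
    UNASSIGNED,
    ActivityScoreResult,
    AnnotationConfig,
    AnnotationError,
    activity_score,
    assign,
    cluster_profile,
    expressed_genes,
    fisher_gate,
)
from hieranno.reference import CellTypeNode, GeneWeightTable


def flat_weights(genes, w=1.0):
    return GeneWeightTable(
        f={g: 1 for g in genes}, w={g: w for g in genes}, max_f=1, min_f=1
    )


def leaf(name, markers):
    return CellTypeNode(name, 1, markers={m.upper() for m in markers},
                        own_markers={m.upper() for m in markers})


class TestClusterProfile:
    def test_single_cell_clusters_reproduce_expression(self):
        values = np.array([[1.0, 2.0], [3.0, 4.0]])
        profile = cluster_profile(values, np.array([0, 1]), "average", genes=["A", "B"])
        np.testing.assert_allclose(profile.values, values)

    def test_hand_zscore_across_two_clusters(self):
        values = np.array([[2.0, 2.0, 4.0, 4.0]])
        profile = cluster_profile(values, np.array([0, 0, 1, 1]), "z", genes=["A"])
        np.testing.assert_allclose(profile.values[0], [-1.0, 1.0])

    def test_z_mode_centers_each_gene_across_clusters(self):
        rng = np.random.default_rng(0)
        values = rng.normal(size=(20, 30))
        labels = rng.integers(0, 4, size=30)
        profile = cluster_profile(values, labels, "z", genes=[f"G{i}" for i in range(20)])
        np.testing.assert_allclose(profile.values.mean(axis=1), 0.0, atol=1e-9)

    def test_single_cluster_falls_back_to_average(self):
        values = np.ones((3, 5))
        profile = cluster_profile(values, np.zeros(5, dtype=int), "z", genes=list("ABC"))
        assert profile.mode == "average"
        np.testing.assert_allclose(profile.values[:, 0], 1.0)

    def test_means_kept_alongside_z(self):
        values = np.array([[2.0, 4.0]])
        profile = cluster_profile(values, np.array([0, 1]), "z", genes=["A"])
        np.testing.assert_allclose(profile.means[0], [2.0, 4.0])

    def test_labeling_must_cover_cells(self):
        with pytest.raises(AnnotationError):
            cluster_profile(np.ones((2, 4)), np.zeros(3, dtype=int), "average", genes=["A", "B"])


class TestActivityScore:
    def gene_index(self, genes):
        return {g.upper(): i for i, g in enumerate(genes)}

    def test_all_zero_expression_scores_zero(self):
        genes = ["A", "B"]
        node = leaf("t", genes)
        score = activity_score(np.zeros(2), node, flat_weights(["A", "B"]), 0.3,
                               self.gene_index(genes))
        assert score == 0.0

    def test_closed_form_four_markers(self):
        genes = ["A", "B", "C", "D"]
        node = leaf("t", genes)
        score = activity_score(np.ones(4), node, flat_weights(genes), 0.3,
                               self.gene_index(genes))
        assert score == pytest.approx(4 ** 0.7, abs=1e-10)

    def test_single_marker_weighting(self):
        node = leaf("t", ["A"])
        for r in (0.0, 0.3, 0.6, 1.0):
            score = activity_score(np.array([2.0]), node, flat_weights(["A"], w=1.5), r,
                                   {"A": 0})
            assert score == pytest.approx(3.0, abs=1e-12)

    def test_linearity_in_the_profile(self):
        rng = np.random.default_rng(1)
        genes = [f"G{i}" for i in range(8)]
        node = leaf("t", genes[:5])
        weights = GeneWeightTable(
            f={g.upper(): 1 for g in genes},
            w={g.upper(): float(w) for g, w in zip(genes, rng.uniform(1, 2, 8))},
            max_f=2, min_f=1,
        )
        column = rng.normal(size=8)
        idx = self.gene_index(genes)
        base = activity_score(column, node, weights, 0.6, idx)
        assert activity_score(3.0 * column, node, weights, 0.6, idx) == pytest.approx(
            3.0 * base, rel=1e-12
        )

    def test_markers_absent_from_matrix_still_count_in_n(self):
        node = leaf("t", ["A", "MISSING1", "MISSING2", "MISSING3"])
        score = activity_score(np.array([1.0]), node, flat_weights(["A"]), 0.3, {"A": 0})
        assert score == pytest.approx(1.0 / 4 ** 0.3, abs=1e-12)

    def test_no_markers_is_an_error(self):
        node = CellTypeNode("t", 1)
        with pytest.raises(AnnotationError):
            activity_score(np.ones(1), node, flat_weights(["A"]), 0.3, {"A": 0})


def hypergeom_tail_oracle(a, b, c, d):
    """Exact integer enumeration of P(overlap >= a) at fixed margins."""
    M, K, n = a + b + c + d, a + b, a + c
    denom = math.comb(M, n)
    num = sum(
        math.comb(K, x) * math.comb(M - K, n - x)
        for x in range(a, min(K, n) + 1)
    )
    return num / denom


def sets_for_table(a, b, c, d):
    universe = {f"g{i}" for i in range(a + b + c + d)}
    items = sorted(universe)
    markers = set(items[: a + b])
    expressed = set(items[:a]) | set(items[a + b : a + b + c])
    return expressed, markers, universe


class TestFisherGate:
    def test_no_overlap_gives_p_one(self):
        expressed, markers, universe = sets_for_table(0, 5, 10, 20)
        node = CellTypeNode("t", 1, markers=markers)
        assert fisher_gate(expressed, node, universe) == pytest.approx(1.0, abs=1e-12)

    def test_degenerate_margins(self):
        universe = {"a", "b", "c"}
        node = CellTypeNode("t", 1, markers=set(universe))
        assert fisher_gate(set(universe), node, universe) == pytest.approx(1.0)

    def test_specific_table_matches_enumeration(self):
        expressed, markers, universe = sets_for_table(5, 5, 10, 80)
        node = CellTypeNode("t", 1, markers=markers)
        p = fisher_gate(expressed, node, universe)
        assert p == pytest.approx(hypergeom_tail_oracle(5, 5, 10, 80), abs=1e-12)

    def test_matches_enumeration_on_small_tables(self):
        for total in (8, 12):
            for a in range(total + 1):
                for b in range(total - a + 1):
                    for c in range(total - a - b + 1):
                        d = total - a - b - c
                        expressed, markers, universe = sets_for_table(a, b, c, d)
                        node = CellTypeNode("t", 1, markers=markers)
                        p = fisher_gate(expressed, node, universe)
                        assert p == pytest.approx(
                            hypergeom_tail_oracle(a, b, c, d), abs=1e-12
                        )

    def test_empty_universe_is_an_error(self):
        node = CellTypeNode("t", 1, markers={"A"})
        with pytest.raises(AnnotationError):
            fisher_gate(set(), node, set())


def result(names, scores, pvalues):
    return ActivityScoreResult(
        cluster_id=0,
        names=list(names),
        scores=np.asarray(scores, dtype=float),
        pvalues=np.asarray(pvalues, dtype=float),
        n_markers=np.ones(len(names), dtype=int),
        r=0.3,
    )


class TestAssign:
    def test_winner_by_score_gated_by_its_own_p(self):
        name, score, p = assign(result(["a", "b"], [3.1, 2.0], [0.01, 0.001]))
        assert name == "a" and p == 0.01

    def test_best_score_failing_gate_is_unassigned(self):
        name, _, p = assign(result(["a", "b"], [5.0, 2.0], [0.2, 0.001]))
        assert name == UNASSIGNED and p == 0.2

    def test_score_tie_breaks_to_smaller_p(self):
        name, _, _ = assign(result(["a", "b"], [2.0, 2.0], [0.04, 0.01]))
        assert name == "b"

    def test_remaining_tie_breaks_lexicographically(self):
        name, _, _ = assign(result(["b", "a"], [2.0, 2.0], [0.01, 0.01]))
        assert name == "a"

    def test_never_returns_candidate_at_or_above_alpha(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            n = rng.integers(1, 6)
            res = result(
                [f"t{i}" for i in range(n)], rng.normal(size=n), rng.uniform(0, 1, n)
            )
            name, _, p = assign(res, alpha=0.05)
            if name != UNASSIGNED:
                assert p < 0.05

    def test_adding_weaker_candidate_never_changes_winner(self):
        base = result(["a", "b"], [3.0, 2.0], [0.01, 0.02])
        extended = result(["a", "b", "c"], [3.0, 2.0, 2.5], [0.01, 0.02, 0.001])
        assert assign(base)[0] == assign(extended)[0] == "a"


def test_expressed_genes_median_cut_is_strict():
    column = np.array([0.0, 1.0, 2.0, 3.0])
    assert expressed_genes(column, ["a", "b", "c", "d"], 0.5) == {"C", "D"}


def test_config_rejects_bad_alpha():
    with pytest.raises(ValueError):
        AnnotationConfig(alpha=1.5)
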