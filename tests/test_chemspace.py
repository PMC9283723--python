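"""SOM clustering, Fisher enrichment against an enumeration oracle, and
descriptor-group statistics."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cypselect.chemspace import (
    SOMGrid,
    assign_clusters,
    compare_descriptor_groups,
    fisher_enrichment,
    fingerprints_from_smiles,
    grid_shape_for,
    train_som,
)
from cypselect.config import ConfigurationError, SOMSpec
from cypselect.synthetic import fingerprint_matrix, generate_library


def hypergeom_tail_oracle(N, K, n_in, k_in):
    """Exact one-sided hypergeometric tails by rational enumeration."""
    total = comb(N, n_in)
    lo = max(0, n_in - (N - K))
    hi = min(n_in, K)
    p_ge = sum(Fraction(comb(K, j) * comb(N - K, n_in - j), total)
               for j in range(k_in, hi + 1))
    p_le = sum(Fraction(comb(K, j) * comb(N - K, n_in - j), total)
               for j in range(lo, k_in + 1))
    return float(p_ge), float(p_le)


class TestSOM:
    def test_same_seed_gives_identical_codebooks(self):
        rng = np.random.default_rng(0)
        X = rng.integers(0, 2, (50, 32)).astype(np.uint8)
        a = train_som(X, 2, 2, epochs=3, seed=5)
        b = train_som(X, 2, 2, epochs=3, seed=5)
        assert np.array_equal(a.codebook, b.codebook)

    def test_one_node_grid_collects_everything(self):
        rng = np.random.default_rng(1)
        X = rng.integers(0, 2, (20, 16)).astype(np.uint8)
        grid = train_som(X, 1, 1, epochs=2, seed=0)
        assert set(assign_clusters(X, grid)) == {0}

    def test_orthogonal_templates_map_to_distinct_nodes(self):
        # four disjoint 16-bit block templates, exact copies (no bit flips)
        templates = np.zeros((4, 64), dtype=np.uint8)
        for i in range(4):
            templates[i, 16 * i : 16 * (i + 1)] = 1
        X = np.repeat(templates, 10, axis=0)
        labels = np.repeat(np.arange(4), 10)
        grid = train_som(X, 2, 2, epochs=10, seed=3)
        nodes = assign_clusters(X, grid)
        mapping = {lab: set(nodes[labels == lab]) for lab in range(4)}
        assert all(len(v) == 1 for v in mapping.values())
        assert len(set().union(*mapping.values())) == 4

    def test_compound_equal_to_codebook_maps_there(self):
        codebook = np.eye(4, dtype=float)
        grid = SOMGrid(2, 2, "rect", codebook, 0)
        assert assign_clusters(np.eye(4)[2:3], grid)[0] == 2

    def test_equidistant_tie_breaks_to_lowest_node(self):
        codebook = np.zeros((8, 2))
        codebook[:] = 100.0          # push everything else far away
        codebook[3] = [0.0, 0.0]
        codebook[7] = [2.0, 0.0]
        grid = SOMGrid(2, 4, "rect", codebook, 0)
        assert assign_clusters(np.array([[1.0, 0.0]]), grid)[0] == 3

    def test_empty_matrix_raises(self):
        with pytest.raises(ConfigurationError):
            train_som(np.zeros((0, 8)), 2, 2)

    def test_dimension_mismatch_raises(self):
        grid = SOMGrid(1, 1, "rect", np.zeros((1, 8)), 0)
        with pytest.raises(ConfigurationError):
            assign_clusters(np.zeros((3, 4)), grid)

    def test_auto_grid_targets_expected_occupancy(self):
        rows, cols = grid_shape_for(5000, SOMSpec())
        assert 400 <= rows * cols <= 600  # ~10 compounds per node


class TestFisher:
    def test_two_of_two_actives_in_cluster_of_four(self):
        # C(4,2) tables: P(both actives in the pair) = 1/6
        assignment = np.array([0, 0, 1, 1])
        active = np.array([True, True, False, False])
        res = fisher_enrichment(assignment, active).set_index("cluster")
        assert res.at[0, "p_enrich"] == pytest.approx(1 / 6, abs=1e-15)

    def test_null_composition_has_near_zero_heat(self):
        assignment = np.repeat([0, 1], 50)
        active = np.tile([True, False], 50)  # both clusters at the library rate
        res = fisher_enrichment(assignment, active)
        assert np.allclose(res["odds_ratio"], 1.0)
        assert (res["heat"].abs() < 0.31).all()  # -log10 p stays near 0

    def test_conservation_of_counts(self):
        rng = np.random.default_rng(4)
        assignment = rng.integers(0, 7, 200)
        active = rng.random(200) < 0.3
        res = fisher_enrichment(assignment, active)
        assert res["n_in"].sum() == 200
        assert res["k_in"].sum() == active.sum()

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(st.data())
    def test_matches_enumeration_oracle(self, data):
        N = data.draw(st.integers(2, 12))
        flags = data.draw(st.lists(st.booleans(), min_size=N, max_size=N))
        assignment = data.draw(
            st.lists(st.integers(0, 2), min_size=N, max_size=N)
        )
        res = fisher_enrichment(np.array(assignment), np.array(flags))
        for _, r in res.iterrows():
            p_ge, p_le = hypergeom_tail_oracle(
                N, int(np.sum(flags)), int(r.n_in), int(r.k_in)
            )
            assert abs(r.p_enrich - p_ge) <= 1e-12
            assert abs(r.p_deplete - p_le) <= 1e-12

    def test_planted_cluster_attains_minimum_enrichment_p(self):
        plan = {c: 0.1 for c in range(10)}
        plan[0] = 0.9
        lib = generate_library(500, 10, plan, seed=17)
        ids, fp = fingerprint_matrix(lib)
        active = np.array([c.truth["CYP3A7"].direction != "inactive" for c in lib])
        grid = train_som(fp, 4, 3, epochs=5, seed=18)
        assignment = assign_clusters(fp, grid)
        res = fisher_enrichment(assignment, active)
        hottest = int(res.loc[res["p_enrich"].idxmin(), "cluster"])
        planted_nodes = assignment[np.array([c.cluster_label == 0 for c in lib])]
        assert hottest == int(np.bincount(planted_nodes).argmax())


class TestDescriptorGroups:
    def _table(self, shift=0.0, n=200, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {
                "group": np.repeat(["a", "b"], n),
                "x": np.concatenate(
                    [rng.normal(0, 1, n), rng.normal(shift, 1, n)]
                ),
            }
        )

    def test_null_anova_p_values_are_uniform(self):
        ps = []
        for seed in range(100):
            summary, _ = compare_descriptor_groups(self._table(seed=seed))
            ps.append(summary["anova_p"].iloc[0])
        from scipy import stats

        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_five_sigma_shift_is_significant(self):
        summary, pairwise = compare_descriptor_groups(self._table(shift=5.0))
        assert (summary["anova_p"] < 0.001).all()
        assert (pairwise["p_adj"] < 0.001).all()

    def test_identical_groups_have_tukey_p_near_one(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, 100)
        table = pd.DataFrame({"group": np.repeat(["a", "b"], 100),
                              "x": np.concatenate([x, x])})
        _, pairwise = compare_descriptor_groups(table)
        assert (pairwise["p_adj"] > 0.9).all()

    def test_constant_descriptor_is_degenerate(self):
        table = pd.DataFrame({"group": ["a", "a", "b", "b"], "x": [1.0] * 4})
        summary, pairwise = compare_descriptor_groups(table)
        assert summary["degenerate"].all()
        assert (summary["anova_p"] == 1.0).all()
        assert (pairwise["p_adj"] == 1.0).all()

    def test_binary_descriptor_reports_frequencies(self):
        table = pd.DataFrame(
            {"group": ["a"] * 4 + ["b"] * 4, "flag": [1, 1, 0, 0, 1, 0, 0, 0]}
        )
        summary, _ = compare_descriptor_groups(table)
        freqs = summary.set_index("group")["frequency"]
        assert freqs["a"] == pytest.approx(0.5)
        assert freqs["b"] == pytest.approx(0.25)


def test_smiles_fingerprints_shape_and_discrimination():
    fps = fingerprints_from_smiles(["c1ccccc1", "CCO", "c1ccccc1"], n_bits=1024)
    assert fps.shape == (3, 1024)
    assert set(np.unique(fps)) <= {0, 1}
    assert np.array_equal(fps[0], fps[2])
    assert not np.array_equal(fps[0], fps[1])
    with pytest.raises(ValueError):
        fingerprints_from_smiles(["not_a_smiles("])
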