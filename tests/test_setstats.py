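"""DE, markers, ternary statistics, pathway test, enrichment, GSEA."""

import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from blastoseq import simulate
from blastoseq.setstats import (
    benjamini_hochberg,
    derive_lineage_markers,
    differential_expression,
    gsea_preranked,
    hypergeometric_enrichment,
    pathway_relative_percentage_test,
    read_gmt,
    ternary_density_bias_test,
    ternary_fractions,
)


class TestBenjaminiHochberg:
    def test_hand_evaluated_step_up(self):
        np.testing.assert_allclose(
            benjamini_hochberg([0.01, 0.02, 0.03, 0.04]), [0.04] * 4
        )

    @pytest.mark.parametrize(
        "p", [[0.001, 0.5, 0.9, 0.04], [0.2, 0.2, 0.2, 0.2], [1.0, 0.5, 0.25, 0.125]]
    )
    def test_matches_direct_step_up_rule(self, p):
        # independent hand implementation of the step-up rule
        p = np.asarray(p)
        m = len(p)
        order = np.argsort(p)
        adj = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running = min(running, p[i] * m / rank)
            adj[i] = running
        np.testing.assert_allclose(benjamini_hochberg(p), adj, atol=1e-12)
        assert (benjamini_hochberg(p) >= p - 1e-15).all()


class TestDifferentialExpression:
    def test_identical_groups_are_null(self, toy_matrix):
        m = pd.concat([toy_matrix, toy_matrix.add_suffix("_b")], axis=1)
        de = differential_expression(
            m, list(toy_matrix.columns), [c + "_b" for c in toy_matrix.columns]
        )
        np.testing.assert_allclose(de["effect"], 0.0)
        np.testing.assert_allclose(de["p_value"], 1.0)

    def test_planted_effects_recovered_with_fdr_control(self):
        params = simulate.ExpressionSimParams(
            n_genes=2000, n_hvg=0, n_modules=0, pseudotime_genes=0, seed=1
        )
        matrix, _, truth = simulate.simulate_expression(params)
        a = [c for c, k in truth.cell_classes.items() if k == "A"]
        b = [c for c, k in truth.cell_classes.items() if k == "B"]
        de = differential_expression(matrix, a, b)
        planted = {
            g for g, r in truth.gene_roles.items() if r.startswith("signature")
        }
        hits = set(de.index[de["p_adjusted"] < 0.05])
        assert len(hits & planted) / len(planted) >= 0.9
        assert len(hits - planted) / max(len(hits), 1) <= 0.1

    def test_adjusted_p_dominates_raw(self, two_class_matrix):
        matrix, _, truth = two_class_matrix
        a = [c for c, k in truth.cell_classes.items() if k == "A"]
        b = [c for c, k in truth.cell_classes.items() if k == "B"]
        de = differential_expression(matrix, a, b)
        assert (de["p_adjusted"] >= de["p_value"] - 1e-15).all()

    def test_small_group_rejected(self, toy_matrix):
        with pytest.raises(ValueError, match=">= 3"):
            differential_expression(toy_matrix, ["c1", "c2"], ["c3", "c4"])


class TestMarkers:
    def test_direction_and_threshold_rules(self):
        de = pd.DataFrame(
            {
                "effect": [1.0, -1.0, 2.0, -2.0, 0.5],
                "p_adjusted": [0.04, 0.04, 0.2, 0.01, 0.06],
            },
            index=["up_sig", "down_sig", "up_ns", "down_sig2", "up_margin"],
        )
        up = derive_lineage_markers(de, "up")
        down = derive_lineage_markers(de, "down")
        assert up == ["up_sig"]
        assert set(down) == {"down_sig", "down_sig2"}
        assert set(up) & set(down) == set()

    def test_empty_result_gives_empty_set(self):
        de = pd.DataFrame({"effect": [], "p_adjusted": []})
        assert derive_lineage_markers(de, "up") == []


class TestTernary:
    def groups(self):
        return {
            "A": ["a1", "a2"],
            "B": ["b1", "b2"],
            "C": ["c1", "c2"],
        }

    def matrix(self, rows):
        cells = [c for g in self.groups().values() for c in g]
        return pd.DataFrame(
            rows, index=[f"g{i}" for i in range(len(rows))], columns=cells
        )

    def test_fraction_arithmetic_and_apex(self):
        m = self.matrix(
            [
                [2, 2, 1, 1, 1, 1],  # means 2,1,1 -> (0.5, 0.25, 0.25)
                [3, 3, 0, 0, 0, 0],  # only group A -> apex (1,0,0)
                [0, 0, 0, 0, 0, 0],  # dropped
            ]
        )
        coords = ternary_fractions(m, self.groups())
        np.testing.assert_allclose(coords.loc["g0"], [0.5, 0.25, 0.25])
        np.testing.assert_allclose(coords.loc["g1"], [1.0, 0.0, 0.0])
        assert "g2" not in coords.index
        assert coords.attrs["dropped"] == ["g2"]
        np.testing.assert_allclose(coords.sum(axis=1), 1.0, atol=1e-12)

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        m = self.matrix(rng.uniform(0, 10, size=(20, 6)))
        c1 = ternary_fractions(m, self.groups())
        c2 = ternary_fractions(m * 7.5, self.groups())
        np.testing.assert_allclose(c1.to_numpy(), c2.to_numpy(), atol=1e-12)

    def test_apex_bias_detected_and_null_calibrated(self):
        rng = np.random.default_rng(1)
        # identical groups: no apex bias expected
        base = rng.uniform(1, 5, size=(60, 6))
        m = self.matrix(base)
        res = ternary_density_bias_test(m, self.groups(), n_permutations=200, seed=3)
        apex_p = res.loc[["apex_0", "apex_1", "apex_2"], "p_value"]
        assert (apex_p > 0.05).all()
        # genes expressed only in group A pile onto apex A
        only_a = np.zeros((30, 6))
        only_a[:, :2] = rng.uniform(1, 5, size=(30, 2))
        m2 = self.matrix(only_a)
        res2 = ternary_density_bias_test(m2, self.groups(), n_permutations=200, seed=3)
        assert res2.loc["apex_0", "count"] == 30

    def test_permutation_p_reproducible(self):
        rng = np.random.default_rng(2)
        m = self.matrix(rng.uniform(0, 3, size=(25, 6)))
        r1 = ternary_density_bias_test(m, self.groups(), n_permutations=150, seed=9)
        r2 = ternary_density_bias_test(m, self.groups(), n_permutations=150, seed=9)
        pd.testing.assert_frame_equal(r1, r2)

    def test_too_few_permutations_rejected(self):
        m = self.matrix(np.ones((5, 6)))
        with pytest.raises(ValueError, match="100"):
            ternary_density_bias_test(m, self.groups(), n_permutations=50)


class TestPathwayRelativePercentage:
    def build(self, ratio):
        rng = np.random.default_rng(0)
        genes = [f"p{i}" for i in range(10)]
        a = np.tile(rng.uniform(2, 6, size=(10, 1)), (1, 20)) * ratio
        b = np.tile(a[:, :1] / ratio, (1, 20))
        m = pd.DataFrame(
            np.hstack([a, b]), index=genes,
            columns=[f"a{i}" for i in range(20)] + [f"b{i}" for i in range(20)],
        )
        return m, genes

    def test_identical_groups_give_fifty_percent(self):
        m, genes = self.build(ratio=1.0)
        res = pathway_relative_percentage_test(
            m, genes, [f"a{i}" for i in range(20)], [f"b{i}" for i in range(20)],
            n_permutations=200, seed=1,
        )
        np.testing.assert_allclose(res["relative_percentages"], 50.0)
        assert res["statistic"] == pytest.approx(0.0, abs=1e-9)
        assert res["p_value"] > 0.5

    def test_fourfold_pathway_shift_significant(self):
        m, genes = self.build(ratio=4.0)
        res = pathway_relative_percentage_test(
            m, genes, [f"a{i}" for i in range(20)], [f"b{i}" for i in range(20)],
            n_permutations=1000, seed=1,
        )
        np.testing.assert_allclose(res["relative_percentages"], 80.0)
        assert res["statistic"] == pytest.approx(300.0)
        assert res["p_value"] <= 0.05

    def test_swapping_groups_negates_statistic(self):
        rng = np.random.default_rng(5)
        genes = [f"p{i}" for i in range(8)]
        m = pd.DataFrame(
            rng.uniform(0.5, 4, size=(8, 12)), index=genes,
            columns=[f"c{i}" for i in range(12)],
        )
        ga, gb = [f"c{i}" for i in range(6)], [f"c{i}" for i in range(6, 12)]
        r1 = pathway_relative_percentage_test(m, genes, ga, gb, 100, seed=0)
        r2 = pathway_relative_percentage_test(m, genes, gb, ga, 100, seed=0)
        assert r1["statistic"] == pytest.approx(-r2["statistic"])

    def test_missing_pathway_rejected(self, toy_matrix):
        with pytest.raises(ValueError, match="pathway genes"):
            pathway_relative_percentage_test(
                toy_matrix, ["nope1", "nope2"], ["c1", "c2"], ["c3", "c4"]
            )


class TestHypergeometric:
    def test_complete_overlap_closed_form(self):
        universe = [f"g{i}" for i in range(20)]
        table = hypergeometric_enrichment(
            universe[:5], {"set": universe[:5]}, universe
        )
        assert table.loc[0, "p_value"] == pytest.approx(1 / comb(20, 5))

    def test_zero_overlap_gives_p_one(self):
        universe = [f"g{i}" for i in range(10)]
        table = hypergeometric_enrichment(
            universe[:2], {"set": universe[8:]}, universe
        )
        assert table.loc[0, "p_value"] == pytest.approx(1.0)

    def test_matches_exhaustive_enumeration(self):
        universe = [f"g{i}" for i in range(12)]
        rng = np.random.default_rng(7)
        for _ in range(10):
            set_size = rng.integers(2, 8)
            sel_size = rng.integers(2, 8)
            gs = list(rng.choice(universe, size=set_size, replace=False))
            sel = list(rng.choice(universe, size=sel_size, replace=False))
            table = hypergeometric_enrichment(sel, {"s": gs}, universe)
            obs = table.loc[0, "overlap"]
            # enumerate all possible selections of that size
            count = total = 0
            for draw in itertools.combinations(universe, sel_size):
                total += 1
                count += len(set(draw) & set(gs)) >= obs
            assert table.loc[0, "p_value"] == pytest.approx(
                count / total, abs=1e-12
            )

    def test_gmt_round_trip(self, tmp_path):
        p = tmp_path / "sets.gmt"
        p.write_text("glyco\tdesc\tg1\tg2\tg3\n" "tca\tdesc\tg4\tg5\n")
        sets = read_gmt(p)
        assert sets == {"glyco": ["g1", "g2", "g3"], "tca": ["g4", "g5"]}


class TestGSEA:
    def test_top_and_bottom_sets_hit_extreme_scores(self):
        genes = [f"g{i}" for i in range(10)]
        scores = np.linspace(5, -5, 10)
        top = gsea_preranked(genes, scores, genes[:2], n_permutations=100, seed=0)
        bottom = gsea_preranked(genes, scores, genes[-2:], n_permutations=100, seed=0)
        assert top.es == pytest.approx(1.0)
        assert bottom.es == pytest.approx(-1.0)

    def test_es_matches_bruteforce_running_sum(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            n = int(rng.integers(10, 51))
            genes = [f"g{i}" for i in range(n)]
            scores = np.sort(rng.normal(size=n))[::-1]
            k = int(rng.integers(2, n // 2))
            gs = set(rng.choice(genes, size=k, replace=False))
            res = gsea_preranked(genes, scores, gs, n_permutations=10, seed=0)
            # independent scan
            running = 0.0
            best = 0.0
            miss = 1.0 / (n - k)
            for g in genes:
                running += (1.0 / k) if g in gs else -miss
                if abs(running) > abs(best):
                    best = running
            assert res.es == pytest.approx(best, abs=1e-12)
            assert -1.0 <= res.es <= 1.0

    def test_p_value_in_valid_range_and_reproducible(self):
        genes = [f"g{i}" for i in range(30)]
        scores = np.linspace(3, -3, 30)
        r1 = gsea_preranked(genes, scores, genes[:5], 200, seed=4)
        r2 = gsea_preranked(genes, scores, genes[:5], 200, seed=4)
        assert r1.es == r2.es and r1.p_value == r2.p_value
        assert 1 / 201 <= r1.p_value <= 1.0

    def test_no_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            gsea_preranked(["a", "b"], [1.0, -1.0], {"zz"}, 100)
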