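import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from uprtriage import synthetic
from uprtriage.expression import (
    ClassifierConfig,
    GenesetScore,
    benjamini_hochberg,
    classify_upr_profile,
    cluster_profiles,
    differential_expression,
    geneset_score,
    reference_filter,
    rpkm,
    score_conditions,
    tg_normalized_induction,
)


class TestRpkm:
    def test_formula_value(self):
        assert rpkm(1000, 1000, 1e6) == pytest.approx(1000.0)

    def test_zero_count(self):
        assert rpkm(0, 500, 1e6) == 0.0

    def test_library_scaling(self):
        assert rpkm(100, 2000, 2e6) == pytest.approx(rpkm(100, 2000, 1e6) / 2.0)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            rpkm(10, 0, 1e6)
        with pytest.raises(ValueError):
            rpkm(10, 100, 0)

    def test_oracle_random_instances(self, rng):
        for _ in range(25):
            c = rng.integers(0, 10000)
            l = rng.integers(100, 100000)
            lib = rng.uniform(1e5, 1e8)
            expected = c / ((l / 1000) * (lib / 1e6))
            assert rpkm(c, l, lib) == pytest.approx(expected, rel=1e-12)


def _bh_brute_force(p):
    """Literal step-up: find largest k with p_(k) <= k q / m, for every q."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    for rank_pos, idx in enumerate(order):
        # adjusted p of the gene at sorted position rank_pos is the minimum
        # over j >= rank_pos of p_(j) * m / (j+1)
        adj[idx] = min(p[order[j]] * m / (j + 1) for j in range(rank_pos, m))
    return np.minimum(adj, 1.0)


class TestBenjaminiHochberg:
    def test_hand_example(self):
        # {0.01, 0.02, 0.03, 0.04}, m=4 -> all adjusted to 0.04
        np.testing.assert_allclose(
            benjamini_hochberg([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        assert benjamini_hochberg([0.3])[0] == pytest.approx(0.3)

    def test_monotone_in_rank(self, rng):
        p = rng.uniform(size=50)
        adj = benjamini_hochberg(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()

    @settings(max_examples=60, deadline=None)
    @given(
        p=st.lists(st.floats(0.0, 1.0), min_size=1, max_size=12),
    )
    def test_matches_brute_force(self, p):
        np.testing.assert_allclose(benjamini_hochberg(p), _bh_brute_force(p), rtol=1e-12)

    def test_matches_brute_force_exhaustive_small_m(self):
        grid = [0.001, 0.01, 0.04, 0.2, 0.5, 1.0]
        for m in (1, 2, 3):
            for combo in itertools.product(grid, repeat=m):
                np.testing.assert_allclose(
                    benjamini_hochberg(list(combo)), _bh_brute_force(list(combo))
                )


class TestDifferentialExpression:
    def test_identical_groups_zero_fc(self, rng):
        a = pd.DataFrame(rng.uniform(1, 10, size=(5, 3)), index=list("abcde"))
        out = differential_expression(a, a.copy())
        np.testing.assert_allclose(out["log2_fc"], 0.0)

    def test_degenerate_equal_p_one(self):
        a = pd.DataFrame([[2.0, 2.0]], index=["g"])
        out = differential_expression(a, a.copy())
        assert out["p_value"].iloc[0] == 1.0

    def test_matches_scipy_per_gene(self, rng):
        a = pd.DataFrame(rng.uniform(1, 10, size=(10, 4)))
        b = pd.DataFrame(rng.uniform(1, 10, size=(10, 4)))
        out = differential_expression(a, b)
        for i in range(10):
            p = stats.ttest_ind(a.iloc[i], b.iloc[i]).pvalue
            assert out["p_value"].iloc[i] == pytest.approx(p)

    def test_requires_replicates(self):
        a = pd.DataFrame([[1.0]], index=["g"])
        with pytest.raises(ValueError):
            differential_expression(a, a)


class TestReferenceFilter:
    def _table(self):
        return pd.DataFrame(
            {"Tg": [1.5, 1.6, 1.4, 3.0], "cmp": [2.0, 2.0, 2.0, 2.0]},
            index=["g_at_bound", "g_above", "g_below", "g_strong"],
        )

    def test_boundary_excluded(self):
        kept = reference_filter(self._table(), ["g_at_bound"], reference="Tg")
        assert kept == []

    def test_above_retained(self):
        kept = reference_filter(
            self._table(), ["g_above", "g_strong"], reference="Tg"
        )
        assert kept == ["g_above", "g_strong"]

    def test_all_below_empty_and_score_unusable(self):
        table = self._table()
        score = geneset_score(
            table, ["g_at_bound", "g_below"], "cmp", reference="Tg", min_genes=1
        )
        assert not score.usable
        assert np.isnan(score.median)


class TestTgNormalizedInduction:
    def test_reference_is_100(self):
        assert tg_normalized_induction(4.0, 4.0) == pytest.approx(100.0)

    def test_no_induction_is_0(self):
        assert tg_normalized_induction(1.0, 4.0) == pytest.approx(0.0)

    def test_formula_value(self):
        assert tg_normalized_induction(2.0, 4.0) == pytest.approx(50.0)

    def test_oracle_random_instances(self, rng):
        for _ in range(25):
            fc_r = rng.uniform(1.6, 10.0)
            fc_c = rng.uniform(0.1, 20.0)
            expected = 100.0 * np.log(fc_c) / np.log(fc_r)
            assert tg_normalized_induction(fc_c, fc_r) == pytest.approx(expected, rel=1e-12)

    @given(
        fc_c=st.floats(0.1, 50.0),
        fc_r=st.floats(1.51, 50.0),
        base=st.floats(1.5, 20.0),
    )
    def test_log_base_invariance(self, fc_c, fc_r, base):
        # computing the ratio in any log base gives the same percent
        via_base = 100.0 * (np.log(fc_c) / np.log(base)) / (np.log(fc_r) / np.log(base))
        assert tg_normalized_induction(fc_c, fc_r) == pytest.approx(via_base, rel=1e-9)


def _make_score(values, name="ATF6", condition="cmp"):
    values = np.asarray(values, dtype=float)
    return GenesetScore(condition, name, [f"g{i}" for i in range(len(values))], values)


class TestClassify:
    def test_constructed_preferential(self, rng):
        atf6 = _make_score(50 + rng.normal(0, 2, 6))
        xbp1 = _make_score(2 + rng.normal(0, 2, 6), "XBP1s")
        perk = _make_score(3 + rng.normal(0, 2, 6), "PERK")
        assert classify_upr_profile(atf6, xbp1, perk).call == "preferential_ATF6"

    def test_constructed_global(self):
        # means ~75/70/72 with heavy overlap: no arm separates
        atf6 = _make_score([62.0, 70.0, 74.0, 77.0, 81.0, 86.0])
        xbp1 = _make_score([59.0, 66.0, 69.0, 72.0, 75.0, 79.0], "XBP1s")
        perk = _make_score([60.0, 68.0, 71.0, 74.0, 77.0, 82.0], "PERK")
        assert classify_upr_profile(atf6, xbp1, perk).call == "global"

    def test_weak_none(self, rng):
        atf6 = _make_score(1 + rng.normal(0, 0.5, 6))
        xbp1 = _make_score(0 + rng.normal(0, 0.5, 6), "XBP1s")
        perk = _make_score(1 + rng.normal(0, 0.5, 6), "PERK")
        assert classify_upr_profile(atf6, xbp1, perk).call == "weak_none"

    def test_reference_against_itself_is_global(self, geneset_catalog):
        table, _ = synthetic.generate_expression_profiles(
            {"cmp": "inactive"}, geneset_catalog, seed=1, noise_sigma=0.0
        )
        arm = lambda name: geneset_catalog.loc[
            geneset_catalog["geneset"] == name, "gene_id"
        ].tolist()
        scores = {
            n: geneset_score(table, arm(n), "Tg", reference="Tg", geneset_name=n)
            for n in ("ATF6", "XBP1s", "PERK")
        }
        call = classify_upr_profile(scores["ATF6"], scores["XBP1s"], scores["PERK"])
        assert call.call == "global"
        assert all(v == pytest.approx(100.0) for v in call.summaries.values())

    def test_recovery_rate_over_planted_classes(self, geneset_catalog):
        # >= 95% of simulated compounds recover their planted class
        n_per_class = 70
        classes = {}
        for cls in ("global", "atf6_preferential", "inactive"):
            for i in range(n_per_class):
                classes[f"{cls}_{i}"] = cls
        table, truth = synthetic.generate_expression_profiles(
            pd.Series(classes), geneset_catalog, seed=42, noise_sigma=0.05
        )
        _, calls = score_conditions(table, geneset_catalog, reference="Tg")
        expected = {"global": "global", "atf6_preferential": "preferential_ATF6",
                    "inactive": "weak_none"}
        merged = calls.merge(
            truth.rename(columns={"condition": "condition"}), on="condition"
        )
        correct = (
            merged["call"] == merged["true_class"].map(expected)
        )
        assert correct.mean() >= 0.95


class TestGenesetScore:
    def test_all_at_reference_scores_100(self, geneset_catalog):
        table, _ = synthetic.generate_expression_profiles(
            {"cmp": "global"}, geneset_catalog,
            {"global": {"ATF6": 1.0, "XBP1s": 1.0, "PERK": 1.0}},
            seed=3, noise_sigma=0.0,
        )
        genes = geneset_catalog.loc[geneset_catalog["geneset"] == "ATF6", "gene_id"].tolist()
        score = geneset_score(table, genes, "cmp", reference="Tg", geneset_name="ATF6")
        assert score.median == pytest.approx(100.0)
        assert score.mean == pytest.approx(100.0)

    def test_planted_half_effect_recovered(self, geneset_catalog):
        table, _ = synthetic.generate_expression_profiles(
            {"cmp": "atf6_preferential"}, geneset_catalog, seed=4, noise_sigma=0.02
        )
        arm = lambda n: geneset_catalog.loc[
            geneset_catalog["geneset"] == n, "gene_id"
        ].tolist()
        atf6 = geneset_score(table, arm("ATF6"), "cmp", reference="Tg")
        xbp1 = geneset_score(table, arm("XBP1s"), "cmp", reference="Tg")
        assert atf6.median == pytest.approx(50.0, abs=5.0)
        assert abs(xbp1.median - 5.0) < 5.0


class TestClustering:
    def test_identical_rows_merge_first_at_zero(self):
        mat = pd.DataFrame(
            [[1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [9.0, 9.0, 9.0]],
            index=["a", "b", "c"],
        )
        z, _ = cluster_profiles(mat)
        assert z[0, 2] == pytest.approx(0.0)
        assert {int(z[0, 0]), int(z[0, 1])} == {0, 1}

    def test_planted_three_class_recovery_ari_one(self, geneset_catalog):
        classes = {}
        for cls in ("global", "atf6_preferential", "inactive"):
            for i in range(10):
                classes[f"{cls}_{i}"] = cls
        table, truth = synthetic.generate_expression_profiles(
            pd.Series(classes), geneset_catalog, seed=6, noise_sigma=0.05
        )
        mat = np.log2(table[list(classes)].T)
        _, labels = cluster_profiles(mat, n_clusters=3)
        from sklearn.metrics import adjusted_rand_score

        truth_labels = truth.set_index("condition").loc[mat.index, "true_class"]
        assert adjusted_rand_score(truth_labels, labels) == 1.0

    def test_merge_heights_permutation_invariant(self, rng, geneset_catalog):
        table, _ = synthetic.generate_expression_profiles(
            pd.Series({f"c{i}": "global" for i in range(8)}),
            geneset_catalog, seed=7, noise_sigma=0.1,
        )
        mat = np.log2(table.T)
        z1, _ = cluster_profiles(mat)
        perm = rng.permutation(len(mat))
        z2, _ = cluster_profiles(mat.iloc[perm])
        np.testing.assert_allclose(
            np.sort(z1[:, 2]), np.sort(z2[:, 2]), rtol=1e-9
        )

    def test_missing_values_rejected(self):
        mat = pd.DataFrame([[1.0, np.nan], [2.0, 3.0]])
        with pytest.raises(ValueError):
            cluster_profiles(mat)
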