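from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dosetx import doseresponse, fixtures, preprocess, simulate
from dosetx.doseresponse import (
    classify_signs,
    consistency_report,
    count_signs,
    enrichment_fold,
    exact_direction_test,
    fold_change_table,
    friedman_test,
    random_gene_set,
)


def fisher_two_sided_oracle(a, b, c, d):
    """Exhaustive 2x2 enumeration: sum P(table) over tables with P <= P(obs)."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = comb(n, c1)

    def prob(x):
        y = c1 - x
        if y < 0 or y > r2 or x > r1:
            return 0.0
        return comb(r1, x) * comb(r2, y) / denom

    p_obs = prob(a)
    return sum(prob(x) for x in range(0, c1 + 1) if prob(x) <= p_obs * (1 + 1e-9))


def binomial_tail_oracle(k, n):
    return sum(comb(n, i) for i in range(k, n + 1)) / 2.0 ** n


class TestFoldChange:
    def test_pooled_and_matched_hand_case(self, tiny_expr):
        fc_pooled = fold_change_table(tiny_expr, "pooled")
        fc_matched = fold_change_table(tiny_expr, "matched")
        x = tiny_expr.data
        for potency in (2, 3):
            drug = x[tiny_expr.sample_ids("drug", potency)].mean(axis=1)
            ctrl_all = x[tiny_expr.sample_ids("control")].mean(axis=1)
            ctrl_match = x[tiny_expr.sample_ids("control", potency)].mean(axis=1)
            assert np.allclose(fc_pooled[potency], drug - ctrl_all)
            assert np.allclose(fc_matched[potency], drug - ctrl_match)

    def test_identical_groups_give_zero(self, tiny_expr):
        data = tiny_expr.data.copy()
        data.loc[:, :] = 8.0
        from dosetx.datamodel import ExpressionMatrix
        expr = ExpressionMatrix(data, tiny_expr.samples)
        assert np.allclose(fold_change_table(expr, "pooled").to_numpy(), 0.0)

    def test_zero_noise_reproduces_planted_table(self, zero_noise_config):
        probe, _, truth = simulate.generate_probe_data(zero_noise_config)
        expr = preprocess.summarize_median_polish(probe)
        fc = fold_change_table(expr, "pooled")
        planted = truth.loc[truth["is_deg"], list(zero_noise_config.potencies)]
        assert np.allclose(fc.loc[planted.index], planted, atol=1e-12)


class TestClassification:
    @pytest.mark.parametrize(
        "fc, label",
        [(-0.05, "null"), (0.05, "null"), (-0.051, "down"), (0.051, "up"), (0.0, "null")],
    )
    def test_inclusive_null_band_boundary(self, fc, label):
        table = pd.DataFrame({2: [fc]}, index=["g"])
        assert classify_signs(table).loc["g", 2] == label

    def test_table3_2c_down_set_all_down(self):
        cls = classify_signs(fixtures.table3_fold_changes())
        down, _ = fixtures.deg_gene_sets()
        assert (cls.loc[down, 2] == "down").all()

    def test_negative_band_rejected(self):
        with pytest.raises(ValueError):
            classify_signs(pd.DataFrame({2: [0.0]}), null_band=-0.1)

    def test_counts_sum_to_set_size(self):
        cls = classify_signs(fixtures.table3_fold_changes())
        down, up = fixtures.deg_gene_sets()
        counts = count_signs(cls, down + up)
        assert (counts[["n_down", "n_null", "n_up"]].sum(axis=1) == 56).all()

    def test_all_null_counts(self):
        table = pd.DataFrame({2: np.zeros(10)}, index=[f"g{i}" for i in range(10)])
        counts = count_signs(classify_signs(table), list(table.index))
        assert counts.loc[2].tolist()[:3] == [0, 10, 0]

    def test_table3_pooled_3c_count_is_48_1_0(self):
        # exhaustive count over the packaged table; the published matched-
        # convention figure (47 vs 2) uses a different control reference
        cls = classify_signs(fixtures.table3_fold_changes())
        down, _ = fixtures.deg_gene_sets()
        counts = count_signs(cls, down)
        assert counts.loc[3, ["n_down", "n_null", "n_up"]].tolist() == [48, 1, 0]
        assert counts.loc[2, ["n_down", "n_null", "n_up"]].tolist() == [49, 0, 0]

    def test_unknown_gene_rejected(self):
        cls = classify_signs(fixtures.table3_fold_changes())
        with pytest.raises(KeyError):
            count_signs(cls, ["NOPE"])


class TestExactTests:
    def test_binomial_sign_three_zero(self):
        assert exact_direction_test(3, 0).p_value == pytest.approx(0.125)

    def test_fisher_vs_reference_2_0_vs_0_2(self):
        res = exact_direction_test(2, 0, "fisher_vs_reference", reference=(0, 2))
        assert res.p_value == pytest.approx(1 / 3)

    def test_binomial_matches_enumeration(self):
        for n in range(1, 30):
            for k in range(0, n + 1):
                p = exact_direction_test(k, n - k).p_value
                assert p == pytest.approx(binomial_tail_oracle(k, n), abs=1e-12)

    def test_fisher_balanced_matches_enumeration_totals_to_40(self):
        for total in range(1, 41):
            ref = (total // 2, total - total // 2)
            for k in range(0, total + 1):
                got = exact_direction_test(k, total - k, "fisher_vs_balanced").p_value
                want = fisher_two_sided_oracle(k, total - k, ref[0], ref[1])
                assert got == pytest.approx(want, abs=1e-9), (k, total)

    def test_fisher_reference_matches_enumeration(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            a, b, c, d = rng.integers(0, 13, 4)
            if a + b == 0:
                continue
            got = exact_direction_test(
                int(a), int(b), "fisher_vs_reference", reference=(int(c), int(d))
            ).p_value
            assert got == pytest.approx(fisher_two_sided_oracle(a, b, c, d), abs=1e-9)

    def test_symmetric_variants_invariant_under_direction_swap(self):
        # swapping (down, up) while mirroring the reference tests the
        # complementary direction and must give the same two-sided p
        for (a, b, c, d) in [(27, 7, 17, 17), (10, 3, 6, 7), (5, 5, 5, 5)]:
            p1 = exact_direction_test(a, b, "fisher_vs_reference", reference=(c, d)).p_value
            p2 = exact_direction_test(b, a, "fisher_vs_reference", reference=(d, c)).p_value
            assert p1 == pytest.approx(p2)
        # balanced variant with an even total is symmetric outright
        p1 = exact_direction_test(27, 7, "fisher_vs_balanced").p_value
        p2 = exact_direction_test(7, 27, "fisher_vs_balanced").p_value
        assert p1 == pytest.approx(p2)

    def test_printed_30c_counts_significant_vs_balanced(self):
        # 27 down vs 7 up among the 49-gene down-set
        res = exact_direction_test(27, 7, "fisher_vs_balanced")
        assert res.p_value == pytest.approx(
            fisher_two_sided_oracle(27, 7, 17, 17), abs=1e-9
        )

    def test_no_informative_genes_is_an_error(self):
        with pytest.raises(ValueError):
            exact_direction_test(0, 0)

    def test_type_one_error_below_six_percent(self):
        rng = np.random.default_rng(42)
        rejections = 0
        runs = 1000
        for _ in range(runs):
            fc = rng.normal(0, 0.2, 49)
            n_down = int((fc < -0.05).sum())
            n_up = int((fc > 0.05).sum())
            p = exact_direction_test(n_down, n_up).p_value
            rejections += p < 0.05
        assert rejections / runs <= 0.06


class TestFriedman:
    def test_identical_columns(self):
        x = np.tile(np.arange(5.0)[:, None], (1, 4))
        stat, df, p = friedman_test(x)
        assert stat == 0.0 and p == 1.0 and df == 3

    def test_hand_ranked_increasing_rows(self):
        x = np.array([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0], [0.0, 1.0, 2.0]])
        stat, df, p = friedman_test(x)
        assert stat == pytest.approx(6.0)
        assert df == 2
        assert p == pytest.approx(stats.chi2.sf(6.0, 2))

    def test_matches_scipy_for_three_plus_conditions(self):
        rng = np.random.default_rng(3)
        for k in (3, 5, 12):
            x = rng.normal(size=(15, k))
            stat, df, p = friedman_test(x)
            ref_stat, ref_p = stats.friedmanchisquare(*[x[:, j] for j in range(k)])
            assert stat == pytest.approx(ref_stat)
            assert p == pytest.approx(ref_p)

    def test_two_conditions_closed_form(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(12, 2))
        stat, df, p = friedman_test(x)
        r1 = (np.argsort(np.argsort(x, axis=1), axis=1)[:, 0] + 1).sum()
        r2 = 3 * 12 - r1
        assert stat == pytest.approx((r1 - r2) ** 2 / 12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            friedman_test(np.zeros((1, 3)))
        with pytest.raises(ValueError):
            friedman_test(np.array([[1.0, np.nan], [np.nan, np.nan]]))


class TestRandomSet:
    def test_disjoint_seeded_and_sized(self):
        universe = [f"g{i}" for i in range(200)]
        exclude = universe[:56]
        got = random_gene_set(universe, exclude, size=49, seed=7)
        assert len(got) == 49
        assert not set(got) & set(exclude)
        assert got == random_gene_set(universe, exclude, size=49, seed=7)

    def test_whole_remainder(self):
        universe = [f"g{i}" for i in range(60)]
        got = random_gene_set(universe, universe[:10], size=50, seed=0)
        assert sorted(got) == sorted(universe[10:])

    def test_insufficient_universe(self):
        with pytest.raises(ValueError):
            random_gene_set(["a", "b"], ["a"], size=2)


class TestConsistencyReport:
    def test_planted_data_flags_strong_potencies_not_random(self, small_planted):
        probe, design, truth, expr = small_planted
        fc = fold_change_table(expr, "matched")
        cls = classify_signs(fc)
        down = truth.index[truth["direction"] == "down"].tolist()
        up = truth.index[truth["direction"] == "up"].tolist()
        rand = random_gene_set(expr.gene_ids, down + up, size=49, seed=1)
        rep = consistency_report(cls, down, up, rand, random_seed=1)
        assert 2 in rep.flagged_potencies and 3 in rep.flagged_potencies
        assert (rep.tests["p_random"] > 0.05).all()
        assert rep.counts["down"].loc[2, "n_down"] >= 45

    def test_null_data_flags_nothing(self):
        cfg = simulate.GeneratorConfig(n_genes=300, seed=21,
                                       effect_table=pd.DataFrame())
        probe, design, truth = simulate.generate_probe_data(cfg)
        expr = preprocess.preprocess_probe_data(probe)
        cls = classify_signs(fold_change_table(expr, "matched"))
        genes = list(expr.gene_ids)
        rep = consistency_report(cls, genes[:49], genes[49:56], genes[56:105])
        assert rep.flagged_potencies == []

    def test_up_set_all_up_significant(self):
        cls = classify_signs(fixtures.table3_fold_changes())
        down, up = fixtures.deg_gene_sets()
        counts = count_signs(cls, up)
        assert counts.loc[2, ["n_down", "n_null", "n_up"]].tolist() == [0, 0, 7]
        assert exact_direction_test(7, 0).p_value < 0.05
        # small-n higher potencies: sign test cannot reach significance
        for potency in (4, 5, 9):
            c = counts.loc[potency]
            if c["n_down"] + c["n_up"] > 0:
                p = exact_direction_test(int(c["n_up"]), int(c["n_down"])).p_value
                assert p > 0.05


class TestEnrichment:
    def test_fold_arithmetic(self):
        fold, _ = enrichment_fold(3, 50, 10, 1000)
        assert fold == pytest.approx(6.0)

    def test_zero_hits(self):
        fold, p = enrichment_fold(0, 50, 10, 1000)
        assert fold == 0.0 and p == 1.0

    def test_p_matches_enumeration(self):
        N, K, m = 20, 6, 8
        denom = comb(N, m)
        for k in range(0, min(m, K) + 1):
            want = sum(comb(K, i) * comb(N - K, m - i) for i in range(k, min(m, K) + 1)) / denom
            _, p = enrichment_fold(k, m, K, N)
            if k == 0:
                assert p == 1.0
            else:
                assert p == pytest.approx(want, abs=1e-12)

    def test_bounds_checked(self):
        with pytest.raises(ValueError):
            enrichment_fold(5, 4, 10, 100)
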