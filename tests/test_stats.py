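"""NB GLM, FDR, volcano, mixed model, Ward clustering, efficiency summaries."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from somacount import (
    bh_fdr,
    classify_efficiency,
    fit_nb_glm,
    fit_volume_mixed_model,
    labeling_efficiency,
    rate_ratio_table,
    tukey_box_stats,
    volcano_table,
    ward_two_way,
)

from _oracles import (
    bh_adjust_bruteforce,
    linkage_to_merges,
    nb_loglik_grid_best,
    ward_bruteforce,
)


class TestNBFit:
    def test_no_effect_gives_rate_ratio_one(self):
        fit = fit_nb_glm([7] * 6 + [7] * 6, ["WT"] * 6 + ["CKO"] * 6, "WT")
        assert fit.rate_ratio("CKO") == pytest.approx(1.0, abs=1e-9)

    def test_rate_ratio_equals_sample_mean_ratio(self):
        counts = [8, 10, 12, 10, 4, 5, 6, 5]  # means 10 and 5
        geno = ["WT"] * 4 + ["CKO"] * 4
        fit = fit_nb_glm(counts, geno, "WT")
        assert fit.rate_ratio("CKO") == pytest.approx(0.5, rel=1e-8)
        assert math.exp(fit.coefficients[0]) == pytest.approx(10.0, rel=1e-8)

    def test_mle_beats_likelihood_grid(self):
        # brute-force grid around the sample means confirms the MLE property
        counts = np.array([3, 7, 5, 9, 1, 2, 4, 2])
        groups = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        geno = ["WT"] * 4 + ["CKO"] * 4
        fit = fit_nb_glm(counts.tolist(), geno, "WT")
        mu_grid = np.linspace(0.5, 12.0, 47)
        theta_grid = np.geomspace(0.5, 500.0, 25)
        mu0, mu1, _, best_ll = nb_loglik_grid_best(
            counts.astype(float), groups, mu_grid, theta_grid
        )
        assert fit.log_likelihood >= best_ll - 1e-6
        assert abs(mu0 - counts[:4].mean()) <= (mu_grid[1] - mu_grid[0])
        assert abs(mu1 - counts[4:].mean()) <= (mu_grid[1] - mu_grid[0])

    def test_matches_statsmodels_mle(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(1)
        # overdispersed gamma-Poisson counts so theta is finite and estimable
        y = np.concatenate(
            [rng.poisson(rng.gamma(5.0, 40 / 5.0, 8)),
             rng.poisson(rng.gamma(5.0, 22 / 5.0, 8))]
        )
        geno = ["WT"] * 8 + ["CKO"] * 8
        fit = fit_nb_glm(y.tolist(), geno, "WT")
        X = sm.add_constant((np.arange(16) >= 8).astype(float))
        ext = sm.NegativeBinomial(y, X).fit(disp=0)
        assert fit.coefficients == pytest.approx(np.asarray(ext.params[:2]), abs=1e-5)
        assert fit.theta == pytest.approx(1.0 / ext.params[-1], rel=1e-3)
        assert fit.standard_errors == pytest.approx(np.asarray(ext.bse[:2]), rel=1e-4)

    def test_poisson_data_flagged_poisson_limit(self):
        rng = np.random.default_rng(3)
        y = np.concatenate([rng.poisson(30, 40), rng.poisson(30, 40)])
        geno = ["WT"] * 40 + ["CKO"] * 40
        fit = fit_nb_glm(y.tolist(), geno, "WT")
        assert "poisson_limit" in fit.flags
        assert math.isinf(fit.theta)

    def test_all_zero_group_flagged_separated(self):
        fit = fit_nb_glm([5, 6, 7, 0, 0, 0], ["WT"] * 3 + ["CKO"] * 3, "WT")
        assert "separated" in fit.flags
        assert not fit.converged
        assert fit.coefficients[1] == -math.inf

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fit_nb_glm([1, -2, 3, 4], ["WT", "WT", "CKO", "CKO"], "WT")


class TestBHFDR:
    def test_hand_example(self):
        assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_single_p_unchanged(self):
        assert bh_fdr([0.2]) == pytest.approx([0.2])

    def test_adjusted_at_least_raw(self):
        rng = np.random.default_rng(0)
        p = rng.random(50)
        adj = bh_fdr(p)
        assert np.all(adj >= p - 1e-12) and np.all(adj <= 1.0)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=8))
    def test_matches_bruteforce_definition(self, p):
        assert bh_fdr(p) == pytest.approx(bh_adjust_bruteforce(p), abs=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])


class TestRateRatioTable:
    @staticmethod
    def _fits(n_regions=4, seed=0, delta=0.0):
        rng = np.random.default_rng(seed)
        fits = {}
        for r in range(1, n_regions + 1):
            y = np.concatenate(
                [rng.poisson(50, 8), rng.poisson(50 * math.exp(delta), 8)]
            )
            fits[r] = fit_nb_glm(y.tolist(), ["WT"] * 8 + ["CKO"] * 8, "WT")
        return fits

    def test_null_fit_ci_straddles_one(self):
        fit = fit_nb_glm([7] * 6 + [7] * 6, ["WT"] * 6 + ["CKO"] * 6, "WT")
        table, _ = rate_ratio_table({1: fit})
        row = table.iloc[0]
        assert row.ci_low <= 1.0 <= row.ci_high
        assert row.rate_ratio == pytest.approx(1.0, abs=1e-9)

    def test_log_worth_of_fdr_001_is_2(self):
        table, _ = rate_ratio_table(self._fits())
        table["fdr_p"] = 0.01
        assert -np.log10(table["fdr_p"]).iloc[0] == pytest.approx(2.0)
        # and the significance rule log_worth >= 2 <=> fdr_p <= 0.01 holds
        table2, _ = rate_ratio_table(self._fits(delta=-2.0))
        assert (
            (table2["log_worth"] >= 2 - 1e-12) == (table2["fdr_p"] <= 0.01)
        ).all()

    def test_separated_fit_excluded_and_listed(self):
        fits = self._fits(n_regions=2)
        fits[99] = fit_nb_glm([5, 5, 0, 0], ["WT", "WT", "CKO", "CKO"], "WT")
        table, exclusions = rate_ratio_table(fits)
        assert 99 not in table["region_id"].tolist()
        assert exclusions == [{"region_id": 99, "reason": "separated"}]

    def test_fdr_p_at_least_p(self):
        table, _ = rate_ratio_table(self._fits(n_regions=6, delta=-0.5))
        assert (table["fdr_p"] >= table["p"] - 1e-12).all()

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            rate_ratio_table({})


class TestVolcano:
    def test_columns_and_reference_lines(self):
        fits = TestRateRatioTable._fits(n_regions=3)
        table, _ = rate_ratio_table(fits, major_of={1: 10, 2: 10, 3: 11})
        volcano, meta = volcano_table(table)
        assert list(volcano.columns) == [
            "region_id", "major_region", "contrast", "rate_ratio",
            "log_worth", "significant",
        ]
        assert meta["rate_ratio_line"] == 1.0
        assert meta["log_worth_line"] == pytest.approx(2.0)

    def test_small_fdr_is_significant(self):
        fits = TestRateRatioTable._fits(n_regions=2, delta=-3.0, seed=5)
        table, _ = rate_ratio_table(fits)
        volcano, _ = volcano_table(table)
        assert volcano["significant"].all()

    def test_empty_results(self):
        volcano, meta = volcano_table(pd.DataFrame())
        assert volcano.empty and "log_worth_line" in meta


class TestMixedModel:
    @staticmethod
    def _table(genotype_shift=0.0, interaction=0.0, noise=0.0, animal_sd=0.0,
               n_animals=4, n_regions=3, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for g_idx, g in enumerate(["WT", "CKO"]):
            for a in range(n_animals):
                u = rng.normal(0, animal_sd) if animal_sd else 0.0
                for r in range(n_regions):
                    y = (3.0 + 0.4 * r + genotype_shift * g_idx
                         + interaction * g_idx * r + u
                         + (rng.normal(0, noise) if noise else 0.0))
                    rows.append(
                        {"animal_id": f"{g}{a}", "genotype": g,
                         "region_id": r, "mean_log10_volume": y}
                    )
        return pd.DataFrame(rows)

    def test_zero_noise_pure_region_effects(self):
        res = fit_volume_mixed_model(self._table())
        geno_terms = [
            v for k, v in res.fixed_effects.items() if "genotype" in k
        ]
        assert max(abs(v) for v in geno_terms) < 1e-6
        assert res.interaction_p == pytest.approx(1.0)

    def test_recovers_genotype_shift(self):
        res = fit_volume_mixed_model(
            self._table(genotype_shift=0.3, noise=0.05, animal_sd=0.05, seed=2)
        )
        shift = [
            v for k, v in res.fixed_effects.items()
            if "genotype" in k and "region" not in k
        ][0]
        assert abs(abs(shift) - 0.3) < 0.1

    def test_interaction_detected(self):
        res = fit_volume_mixed_model(
            self._table(interaction=0.5, noise=0.02, animal_sd=0.02,
                        n_animals=6, seed=3)
        )
        assert res.interaction_p < 0.01

    def test_requires_two_genotypes(self):
        table = self._table()
        with pytest.raises(ValueError):
            fit_volume_mixed_model(table[table["genotype"] == "WT"])


class TestWard:
    def test_identical_rows_merge_first(self):
        M = np.array([[1.0, 2.0], [5.0, 9.0], [1.0, 2.0], [8.0, 1.0]])
        res = ward_two_way(M)
        first = sorted(int(v) for v in res.row_linkage[0, :2])
        assert first == [0, 2]
        assert res.row_linkage[0, 2] == pytest.approx(0.0)

    def test_heights_nondecreasing(self):
        rng = np.random.default_rng(4)
        res = ward_two_way(rng.random((10, 6)))
        heights = res.row_linkage[:, 2]
        assert np.all(np.diff(heights) >= -1e-12)

    @pytest.mark.parametrize("n", [3, 5, 7])
    def test_matches_bruteforce_ward(self, n):
        rng = np.random.default_rng(n)
        for _ in range(10):
            pts = rng.random((n, 3))
            res = ward_two_way(pts)
            lib = linkage_to_merges(res.row_linkage, n)
            oracle = ward_bruteforce(pts)
            for a, b in zip(lib, oracle):
                assert a["members"] == b["members"]
                assert a["height"] == pytest.approx(b["height"], rel=1e-9)

    def test_row_permutation_same_tree(self):
        rng = np.random.default_rng(6)
        M = rng.random((6, 4))
        perm = rng.permutation(6)
        res_a = ward_two_way(M)
        res_b = ward_two_way(M[perm])
        merges_a = linkage_to_merges(res_a.row_linkage, 6)
        merges_b = linkage_to_merges(res_b.row_linkage, 6)
        inv = np.argsort(perm)
        relabeled = [
            {"members": sorted(int(perm[i]) for i in m["members"]),
             "height": m["height"]}
            for m in merges_b
        ]
        assert [sorted(m["members"]) for m in merges_a] == [
            m["members"] for m in relabeled
        ]

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            ward_two_way(np.array([[1.0, np.nan]]))


class TestEfficiency:
    def test_ratio_and_region_mean(self):
        records = pd.DataFrame(
            [
                {"region": "MS", "animal_id": a, "slice_id": 0,
                 "co_positive": c, "total": 10}
                for a, c in [("a1", 6), ("a2", 8), ("a3", 10)]
            ]
        )
        summary, dropped = labeling_efficiency(records)
        assert dropped == []
        row = summary.iloc[0]
        assert row.mean_ratio == pytest.approx(0.8)
        assert row.n == 3
        assert row.bin == "75-100%"

    def test_slices_average_within_animal_first(self):
        records = pd.DataFrame(
            [
                {"region": "CP", "animal_id": "a1", "slice_id": s,
                 "co_positive": c, "total": 10}
                for s, c in [(0, 2), (1, 4)]
            ]
            + [{"region": "CP", "animal_id": "a2", "slice_id": 0,
                "co_positive": 9, "total": 10}]
        )
        summary, _ = labeling_efficiency(records)
        # animal means are 0.3 and 0.9 -> region mean 0.6, not the slice mean
        assert summary.iloc[0].mean_ratio == pytest.approx(0.6)

    def test_zero_total_excluded_and_logged(self):
        records = pd.DataFrame(
            [
                {"region": "GP", "animal_id": "a1", "slice_id": 0,
                 "co_positive": 0, "total": 0},
                {"region": "GP", "animal_id": "a2", "slice_id": 0,
                 "co_positive": 5, "total": 10},
            ]
        )
        summary, dropped = labeling_efficiency(records)
        assert len(dropped) == 1 and dropped[0]["reason"] == "total=0"
        assert summary.iloc[0].n == 1

    def test_co_positive_exceeding_total_rejected(self):
        records = pd.DataFrame(
            [{"region": "X", "animal_id": "a", "slice_id": 0,
              "co_positive": 11, "total": 10}]
        )
        with pytest.raises(ValueError):
            labeling_efficiency(records)


class TestTukey:
    def test_all_equal(self):
        box = tukey_box_stats([4.0, 4.0, 4.0])
        assert box["q1"] == box["q3"] == box["median"] == 4.0
        assert box["outliers"] == []
        assert box["whisker_low"] == box["whisker_high"] == 4.0

    def test_hand_computed_outlier(self):
        box = tukey_box_stats([1, 2, 3, 4, 100])
        # linear-interpolation quartiles: q1=2, q3=4, iqr=2, fences [-1, 7]
        assert box["q1"] == pytest.approx(2.0)
        assert box["q3"] == pytest.approx(4.0)
        assert box["outliers"] == [100.0]
        assert box["whisker_high"] == 4.0

    def test_median_of_1_to_9(self):
        assert tukey_box_stats(list(range(1, 10)))["median"] == 5.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            tukey_box_stats([])


class TestClassifyEfficiency:
    @pytest.mark.parametrize(
        "ratio,label",
        [
            (0.05, "<10%"),
            (0.0, "<10%"),
            (0.10, "10-50%"),
            (0.499, "10-50%"),
            (0.50, "50-75%"),
            (0.749, "50-75%"),
            (0.75, "75-100%"),
            (1.0, "75-100%"),
        ],
    )
    def test_bin_edges_left_closed(self, ratio, label):
        assert classify_efficiency(ratio) == label

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_efficiency(1.2)
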