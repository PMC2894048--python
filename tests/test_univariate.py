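"""Single-parameter correlation and group-comparison analyses."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gagfib.exceptions import InsufficientDataError
from gagfib.synthetic_data import GeneratorConfig, generate_entries, noise_for_target_r2
from gagfib.univariate import (
    compare_two_groups,
    correlate,
    correlate_xy,
    mean_G_by_bin,
    mean_G_by_level,
)


class TestCorrelate:
    def test_perfect_collinearity(self):
        x = np.linspace(0, 3, 20)
        res = correlate_xy(x, 2.0 * x - 1.0)
        assert res.r == pytest.approx(1.0)
        assert res.p < 1e-10
        assert res.slope == pytest.approx(2.0)
        assert res.x_intercept == pytest.approx(0.5)

    def test_p_matches_exact_t_transform(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=25)
        y = 0.5 * x + rng.normal(size=25)
        res = correlate_xy(x, y)
        t = res.r * np.sqrt((res.n - 2) / (1 - res.r**2))
        assert res.p == pytest.approx(2 * stats.t.sf(abs(t), res.n - 2), rel=1e-9)

    def test_affine_rescaling_of_x_preserves_r_and_p(self, noisy_entries):
        base = correlate(noisy_entries, "solute_molarity")
        frame = None
        from gagfib.data_model import entries_to_frame

        frame = entries_to_frame(noisy_entries).copy()
        frame["solute_molarity"] = frame["solute_molarity"] * 3.7 + 12.0
        scaled = correlate(frame, "solute_molarity")
        assert scaled.r == pytest.approx(base.r, abs=1e-12)
        assert scaled.p == pytest.approx(base.p, rel=1e-9)
        assert scaled.slope == pytest.approx(base.slope / 3.7, rel=1e-9)

    def test_constant_x_is_insufficient(self, noisy_entries):
        from gagfib.data_model import entries_to_frame

        frame = entries_to_frame(noisy_entries).copy()
        frame["solute_molarity"] = 100.0
        with pytest.raises(InsufficientDataError):
            correlate(frame, "solute_molarity")

    def test_filter_predicate_subsets_entries(self, demo_entries):
        from gagfib.data_model import entries_to_frame

        frame = entries_to_frame(demo_entries)
        target = frame["protein"].mode()[0]
        res = correlate(
            demo_entries, "solute_molarity", filter=lambda d: d["protein"] == target
        )
        assert res.n == (frame["protein"] == target).sum()

    @pytest.mark.parametrize(
        "variable", ["solute_molarity", "sulfates_per_disaccharide"]
    )
    def test_permutation_oracle_calibrates_analytic_p(self, noisy_entries, variable):
        # the analytic t-transform p should match the fraction of 1000 seeded
        # permutations of G whose |r| beats the observed one, for a strongly
        # correlated descriptor (molarity) and a weakly correlated one alike
        res = correlate(noisy_entries, variable)
        from gagfib.data_model import entries_to_frame

        frame = entries_to_frame(noisy_entries)
        x = frame[variable].to_numpy(float)
        g = frame["G"].to_numpy(float)
        rng = np.random.default_rng(0)
        exceed = 0
        for _ in range(1000):
            rp, _ = stats.pearsonr(x, rng.permutation(g))
            exceed += abs(rp) >= abs(res.r)
        perm_p = exceed / 1000
        mc_sd = np.sqrt(max(res.p * (1 - res.p), 1e-4) / 1000)
        assert abs(perm_p - res.p) <= max(0.03, 4 * mc_sd)


class TestMeanByLevel:
    def test_one_entry_per_level_means_equal_raw_values(self):
        frame = pd.DataFrame(
            {"sulfates_per_disaccharide": [0.0, 1.0, 2.0, 3.0], "G": [0.1, 0.9, 1.7, 2.2]}
        )
        summaries, corr = mean_G_by_level(frame, "sulfates_per_disaccharide")
        assert [s.mean_G for s in summaries] == [0.1, 0.9, 1.7, 2.2]
        assert all(s.sd_G is None for s in summaries)
        assert corr.r > 0.99

    def test_level_means_correlate_more_tightly_than_raw(self, noisy_entries):
        raw = correlate(noisy_entries, "sulfates_per_disaccharide")
        _, level = mean_G_by_level(noisy_entries, "sulfates_per_disaccharide")
        assert abs(level.r) >= abs(raw.r)

    def test_zero_effect_levels_rarely_significant(self):
        # generator with a = 0: level-mean correlation should be a null test
        from gagfib.multivariate import PredictiveModel

        coef = PredictiveModel(y0=2.0, a=0.0, b=-0.016, c=0.11, c_prime=-0.0020)
        hits = 0
        for seed in range(100):
            cfg = GeneratorConfig(n_entries=39, coefficients=coef, seed=seed)
            cfg.noise_sd = 0.8
            entries = generate_entries(cfg)
            try:
                _, corr = mean_G_by_level(entries, "sulfates_per_disaccharide")
            except InsufficientDataError:
                continue
            hits += corr.p <= 0.05
        assert hits <= 10

    def test_fewer_than_three_levels_rejected(self):
        frame = pd.DataFrame({"sulfates_per_disaccharide": [0.0, 3.0] * 5, "G": range(10)})
        with pytest.raises(InsufficientDataError):
            mean_G_by_level(frame, "sulfates_per_disaccharide")


class TestMeanByBin:
    def test_quartile_edges_cover_range_and_are_returned(self, noisy_entries):
        summaries, corr, edges = mean_G_by_bin(noisy_entries, "solute_molarity")
        from gagfib.data_model import entries_to_frame

        x = entries_to_frame(noisy_entries)["solute_molarity"]
        assert edges[0] <= x.min() and edges[-1] >= x.max()
        assert sum(s.n for s in summaries) == len(x)

    def test_single_bin_is_insufficient(self, noisy_entries):
        with pytest.raises(InsufficientDataError):
            mean_G_by_bin(noisy_entries, "solute_molarity", bin_edges=[0.0, 1e6])

    def test_binned_slope_sign_matches_generating_negative_molarity_effect(self):
        cfg = GeneratorConfig(n_entries=120, seed=3)
        cfg.noise_sd = noise_for_target_r2(cfg, 0.74)
        entries = generate_entries(cfg)
        _, corr, _ = mean_G_by_bin(entries, "solute_molarity")
        assert corr.slope < 0
        assert corr.r < 0


class TestTwoGroups:
    def test_identical_groups_show_no_difference(self):
        frame = pd.DataFrame(
            {"uronic_acid": ["iduronic"] * 6 + ["glucuronic"] * 6, "G": [1.0, 1.5, 2.0] * 4}
        )
        res = compare_two_groups(frame, "uronic_acid", "iduronic", "glucuronic")
        assert res.summary_a.mean_G == pytest.approx(res.summary_b.mean_G)
        assert res.p == pytest.approx(1.0)

    def test_three_pooled_sd_offset_detected_in_at_least_99_of_100(self):
        rng_master = np.random.default_rng(12)
        hits = 0
        for _ in range(100):
            rng = np.random.default_rng(rng_master.integers(2**31))
            a = rng.normal(0.0, 1.0, 10)
            b = rng.normal(3.0, 1.0, 10)
            frame = pd.DataFrame(
                {"uronic_acid": ["glucuronic"] * 10 + ["iduronic"] * 10,
                 "G": np.concatenate([a, b])}
            )
            res = compare_two_groups(frame, "uronic_acid", "glucuronic", "iduronic")
            hits += res.p < 0.01
        assert hits >= 99

    def test_matching_restricts_to_fixed_covariates(self, demo_entries):
        from gagfib.data_model import entries_to_frame

        frame = entries_to_frame(demo_entries)
        res = compare_two_groups(
            frame[frame["uronic_acid"].isin(["iduronic", "glucuronic"])],
            "uronic_acid", "iduronic", "glucuronic",
            matching={"sulfates_per_disaccharide": 2.0},
        )
        sub = frame[frame["sulfates_per_disaccharide"] == 2.0]
        assert res.summary_a.n == (sub["uronic_acid"] == "iduronic").sum()
        assert res.summary_b.n == (sub["uronic_acid"] == "glucuronic").sum()

    def test_tiny_group_returns_summaries_without_test(self):
        frame = pd.DataFrame(
            {"uronic_acid": ["iduronic", "glucuronic", "glucuronic"], "G": [1.0, 2.0, 3.0]}
        )
        res = compare_two_groups(frame, "uronic_acid", "iduronic", "glucuronic")
        assert res.p is None and res.t is None
        assert res.summary_a.n == 1
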