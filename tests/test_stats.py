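"""Statistical layer against closed-form and quadrature oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate
from scipy import stats as sps

from conftest import residual_on_residual
from discqmri.stats import (
    StatsError,
    anova_tukey,
    blocked_linear_model,
    bonferroni_flags,
    categorize_strength,
    gag_content,
    healthy_filter,
    pearson,
    run_model_grid,
    water_content,
)


class TestPearson:
    def test_perfect_linear_relation(self):
        x = np.arange(10.0)
        r, p = pearson(x, 2 * x + 1)
        assert r == pytest.approx(1.0)

    def test_matches_covariance_formula_oracle(self):
        x = np.array([1.0, 2.0, 4.0, 4.5, 7.0, 9.0])
        y = np.array([2.2, 1.0, 5.5, 3.3, 8.0, 6.1])
        r, _ = pearson(x, y)
        oracle = (np.mean(x * y) - x.mean() * y.mean()) / (x.std() * y.std())
        assert r == pytest.approx(oracle, abs=1e-12)

    def test_listwise_deletion_of_missing_pairs(self):
        x = np.array([1.0, 2.0, np.nan, 4.0, 5.0])
        y = np.array([2.0, 4.0, 100.0, np.nan, 10.0])
        r, _ = pearson(x, y)
        r_ref, _ = pearson([1.0, 2.0, 5.0], [2.0, 4.0, 10.0])
        assert r == pytest.approx(r_ref)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(StatsError, match="degenerate"):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(StatsError, match="pairs"):
            pearson([1.0, 2.0], [1.0, 2.0])


class TestHealthyFilter:
    def test_keeps_grades_one_and_two_only(self):
        df = pd.DataFrame({"pfirrmann": np.repeat([1, 2, 3, 4, 5], 10)})
        assert len(healthy_filter(df)) == 20

    def test_all_degenerated_gives_empty(self):
        df = pd.DataFrame({"pfirrmann": [5, 5, 5]})
        assert healthy_filter(df).empty


def studentized_range_sf_oracle(q, k, df):
    """P(Q > q) by direct double quadrature of the studentized-range CDF.

    Q = R / S where R is the range of k standard normals and S^2 ~
    chi2_df/df.  CDF(q) = E_S[ P(range <= q*S) ] with
    P(range <= r) = k * int phi(z) [Phi(z) - Phi(z - r)]^(k-1) dz.
    """
    def p_range_le(r):
        val, _ = integrate.quad(
            lambda z: sps.norm.pdf(z) * (sps.norm.cdf(z) - sps.norm.cdf(z - r)) ** (k - 1),
            -9, 9 + r, limit=300, epsabs=1e-12)
        return k * val

    def outer(s):
        # density of S = sqrt(chi2_df / df)
        import math

        dens = (2 * (df / 2.0) ** (df / 2.0) / math.gamma(df / 2.0)
                * s ** (df - 1) * np.exp(-df * s * s / 2.0))
        return dens * p_range_le(q * s)

    cdf, _ = integrate.quad(outer, 1e-9, 8, limit=300, epsabs=1e-12)
    return 1.0 - cdf


class TestAnovaTukey:
    def test_extreme_separation_gives_one_significant_pair(self):
        rng = np.random.default_rng(0)
        values = np.concatenate([rng.normal(0, 1, 10), rng.normal(100, 1, 10)])
        groups = np.repeat(["a", "b"], 10)
        res = anova_tukey(values, groups)
        assert res.n_pairs == 1 and res.n_significant_pairs == 1

    def test_adjusted_p_matches_quadrature_oracle(self):
        rng = np.random.default_rng(1)
        values = np.concatenate([rng.normal(0, 1, 5), rng.normal(1.0, 1, 4),
                                 rng.normal(2.0, 1, 6)])
        groups = np.repeat(["a", "b", "c"], [5, 4, 6])
        res = anova_tukey(values, groups)
        df_within = len(values) - 3
        for _, row in res.pairs.iterrows():
            oracle = studentized_range_sf_oracle(row["q"], 3, df_within)
            assert row["p_adj"] == pytest.approx(oracle, abs=1e-6)

    def test_matches_statsmodels_tukeyhsd(self):
        """Independent cross-check of the whole Tukey-Kramer procedure."""
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        rng = np.random.default_rng(2)
        values = np.concatenate([rng.normal(m, 2, n) for m, n in
                                 [(0, 7), (1.5, 9), (3.0, 5), (0.5, 11)]])
        groups = np.repeat(["a", "b", "c", "d"], [7, 9, 5, 11])
        ours = anova_tukey(values, groups)
        sm_res = pairwise_tukeyhsd(values, groups)
        np.testing.assert_allclose(ours.pairs["p_adj"].to_numpy(),
                                   sm_res.pvalues, atol=1e-8)

    def test_omnibus_gating_of_pair_counts(self):
        rng = np.random.default_rng(3)
        values = rng.normal(0, 1, 40)
        groups = np.repeat(list("abcd"), 10)
        res = anova_tukey(values, groups)
        if res.omnibus_p > 0.05:
            assert res.n_significant_pairs == 0
        assert len(res.pairs) == 6  # pairwise table still reported

    def test_label_shuffling_rarely_finds_pairs(self):
        """Permutation consistency: under shuffled labels the pair count is
        zero in at least 94% of 200 shuffles at alpha 0.05."""
        rng = np.random.default_rng(4)
        values = np.concatenate([rng.normal(m, 1, 12) for m in (0, 0.5, 1.0, 2.0)])
        groups = np.repeat(list("abcd"), 12)
        zero = 0
        for _ in range(200):
            perm = rng.permutation(groups)
            if anova_tukey(values, perm).n_significant_pairs == 0:
                zero += 1
        assert zero >= 188

    def test_zero_variance_rejected(self):
        with pytest.raises(StatsError, match="variance"):
            anova_tukey([1.0, 1.0, 2.0, 2.0], ["a", "a", "b", "b"])


def _blocked_frame(n_dogs=5, n_levels=8, slope=0.1, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    dogs = [f"d{i}" for i in range(n_dogs)]
    levels = [f"L{i}" for i in range(n_levels)]
    rows = []
    dog_eff = dict(zip(dogs, rng.normal(0, 5, n_dogs)))
    lev_eff = dict(zip(levels, rng.normal(0, 2, n_levels)))
    for d in dogs:
        for lv in levels:
            x = rng.uniform(20, 150)
            y = dog_eff[d] + lev_eff[lv] + slope * x + rng.normal(0, noise)
            rows.append({"dog": d, "level": lv, "x": x, "y": y})
    return pd.DataFrame(rows)


class TestBlockedLinearModel:
    def test_perfect_partial_fit(self):
        df = _blocked_frame(slope=0.1, noise=0.0)
        res = blocked_linear_model(df, "y", "x")
        assert res.r_partial == pytest.approx(1.0, abs=1e-8)
        assert res.m == pytest.approx(0.1, abs=1e-10)
        assert res.p_value < 1e-12

    def test_r_partial_equals_residual_on_residual_oracle(self):
        df = _blocked_frame(n_dogs=5, n_levels=8, slope=0.05, noise=3.0, seed=1)
        res = blocked_linear_model(df, "y", "x")
        oracle = residual_on_residual(df, "y", "x")
        assert res.r_partial == pytest.approx(oracle, abs=1e-10)
        assert np.sign(res.r_partial) == np.sign(res.m)

    def test_single_block_levels_reduce_to_simple_regression(self):
        df = _blocked_frame(n_dogs=1, n_levels=1, slope=0.2, noise=1.0, seed=2)
        df = pd.concat([df] * 12, ignore_index=True)
        rng = np.random.default_rng(3)
        df["x"] = rng.uniform(0, 100, len(df))
        df["y"] = 3.0 + 0.2 * df["x"] + rng.normal(0, 1.0, len(df))
        res = blocked_linear_model(df, "y", "x")
        lr = sps.linregress(df["x"], df["y"])
        assert res.m == pytest.approx(lr.slope, abs=1e-10)
        assert res.p_value == pytest.approx(lr.pvalue, rel=1e-8)

    def test_predictor_rescaling_leaves_r_partial_invariant(self):
        df = _blocked_frame(slope=0.05, noise=2.0, seed=4)
        res1 = blocked_linear_model(df, "y", "x")
        df2 = df.assign(x=df["x"] * 3.0 + 7.0)
        res2 = blocked_linear_model(df2, "y", "x")
        assert abs(res2.r_partial) == pytest.approx(abs(res1.r_partial), abs=1e-10)
        assert res2.m == pytest.approx(res1.m / 3.0, rel=1e-10)

    def test_inverse_slope_and_ci_contain_m(self):
        df = _blocked_frame(slope=0.08, noise=2.0, seed=5)
        res = blocked_linear_model(df, "y", "x")
        assert res.inv_m == pytest.approx(1.0 / res.m)
        assert res.ci95_m[0] <= res.m <= res.ci95_m[1]

    def test_listwise_deletion_reported_in_n_obs(self):
        df = _blocked_frame(seed=6)
        df.loc[df.index[:5], "y"] = np.nan
        res = blocked_linear_model(df, "y", "x")
        assert res.n_obs == len(df) - 5

    def test_aliased_predictor_reported(self):
        df = _blocked_frame(seed=7)
        df["x"] = (df["dog"] == "d1").astype(float)  # aliased with a block
        with pytest.raises(StatsError, match="aliased"):
            blocked_linear_model(df, "y", "x")

    def test_too_few_complete_cases_rejected(self):
        df = _blocked_frame(n_dogs=5, n_levels=8, seed=8).head(10)
        with pytest.raises(StatsError, match="too few"):
            blocked_linear_model(df, "y", "x")


class TestModelGrid:
    def _records(self, seed=0):
        from discqmri.phantom import sample_cohort

        discs = sample_cohort(seed=seed).discs.copy()
        ren = {c: c.removeprefix("true_") for c in discs.columns if c.startswith("true_")}
        return discs.rename(columns=ren)

    def test_np_grid_has_seven_by_four_results(self):
        grid = run_model_grid(self._records(), rois=("NP",))
        fitted = grid[grid["note"] == ""]
        assert len(fitted) == 28  # 7 measures x 4 health responses
        assert set(grid["response"]) == {"pfirrmann", "histology_score",
                                         "water_np", "gag_np"}

    def test_daf_grid_has_only_two_response_rows(self):
        grid = run_model_grid(self._records(), rois=("dAF",))
        assert set(grid["response"]) == {"pfirrmann", "histology_score"}
        assert len(grid) == 14

    def test_sign_structure_of_np_relationships(self):
        """Relaxation-health links in the NP: grade/histology regressions are
        negative, water/GAG positive, as built into the generator."""
        grid = run_model_grid(self._records(), rois=("NP",))
        t2 = grid[(grid.measure == "T2") & (grid.note == "")]
        sign = dict(zip(t2["response"], np.sign(t2["r_partial"])))
        assert sign["pfirrmann"] == -1 and sign["histology_score"] == -1
        assert sign["water_np"] == +1


class TestThresholdsAndBins:
    @pytest.mark.parametrize("p,n,expected", [
        (0.013, 4, False),  # 0.0125 threshold for four health measures
        (0.013, 2, True),   # 0.025 threshold for two
        (0.0, 4, True),
        (0.0125, 4, False),  # strict inequality
    ])
    def test_bonferroni(self, p, n, expected):
        assert bonferroni_flags(p, n) is expected

    @pytest.mark.parametrize("r,label", [
        (0.45, "moderate"), (0.4, "moderate"), (0.0, "very weak"),
        (-0.62, "strong"), (0.2, "weak"), (0.8, "very strong"), (1.0, "very strong"),
        (0.19, "very weak"),
    ])
    def test_strength_bins(self, r, label):
        assert categorize_strength(r) == label


class TestBiochemistry:
    def test_water_content_arithmetic(self):
        assert water_content(55.0, 19.0) == pytest.approx(65.4545, abs=1e-3)
        assert water_content(50.0, 50.0) == 0.0
        assert water_content(50.0, 1e-9) == pytest.approx(100.0, abs=1e-6)

    def test_dry_exceeding_wet_rejected(self):
        with pytest.raises(StatsError, match="exceeds"):
            water_content(19.0, 55.0)

    def test_gag_zero_absorbance_through_origin(self):
        standards = [(c, 10 ** (-0.02 * c)) for c in (0.0, 10.0, 25.0, 50.0)]
        out = gag_content(1.0, standards, dilution_factor=200, dry_mg=20.0,
                          digest_volume_ml=1.0)
        assert out == pytest.approx(0.0, abs=1e-12)

    def test_gag_arithmetic_matches_hand_computation(self):
        # slope 0.02 AU/(ug/mL): absorbance 0.5 -> 25 ug/mL; x200 dilution
        # x 1 mL digest = 5000 ug = 5 mg; / 20 mg dry = 0.25 mg/mg
        standards = [(c, 10 ** (-0.02 * c)) for c in (0.0, 10.0, 25.0, 50.0)]
        out = gag_content(10 ** (-0.5), standards, dilution_factor=200,
                          dry_mg=20.0, digest_volume_ml=1.0)
        assert out == pytest.approx(0.25, rel=1e-9)

    def test_flat_standard_curve_rejected(self):
        standards = [(0.0, 0.9), (25.0, 0.9), (50.0, 0.9)]
        with pytest.raises(StatsError, match="flat_standard_curve"):
            gag_content(0.5, standards, 200, 20.0, 1.0)

    def test_extrapolation_warns(self):
        standards = [(c, 10 ** (-0.02 * c)) for c in (0.0, 10.0, 25.0, 50.0)]
        with pytest.warns(UserWarning, match="extrapolates"):
            gag_content(10 ** (-1.5), standards, 200, 20.0, 1.0)
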