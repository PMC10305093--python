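"""Post-stratification weights, prevalence estimation, sample-size formula."""

import math

import numpy as np
import pandas as pd
import pytest

from stride_prev.weighting import (
    EligibilityError,
    PopulationMargins,
    PrecisionSpec,
    assign_age_band,
    assign_cell,
    estimate_prevalence,
    extrapolate_count,
    fit_weights,
    precision_sample_size,
    prevalence_table,
)


def cells_frame(rows):
    return pd.DataFrame(rows, columns=["age_band", "sex", "literacy"])


class TestCells:
    @pytest.mark.parametrize(
        "age, band",
        [(65, "65-69"), (69, "65-69"), (70, "70-74"), (79, "75-79"), (83, "80+"),
         (101, "80+")],
    )
    def test_five_year_bands_with_open_top(self, age, band):
        assert assign_age_band(age) == band

    def test_under_age_is_an_eligibility_error(self):
        with pytest.raises(EligibilityError):
            assign_cell(64, "female", "literate")

    def test_unknown_levels_rejected(self):
        with pytest.raises(ValueError):
            assign_cell(70, "F", "literate")


class TestFitWeights:
    def test_matching_shares_give_unit_weights(self):
        sample = cells_frame(
            [("65-69", "female", "literate")] * 30
            + [("70-74", "male", "illiterate")] * 70
        )
        margins = PopulationMargins(
            cells=pd.DataFrame(
                [
                    {"age_band": "65-69", "sex": "female", "literacy": "literate",
                     "count": 3000},
                    {"age_band": "70-74", "sex": "male", "literacy": "illiterate",
                     "count": 7000},
                ]
            )
        )
        wt = fit_weights(sample, margins)
        assert np.allclose(wt.weights, 1.0)

    def test_two_cell_share_ratio_hand_checked(self):
        # population 0.5/0.5, sample 0.8/0.2 -> weights 0.625 / 2.5
        sample = cells_frame(
            [("65-69", "female", "literate")] * 80
            + [("80+", "male", "illiterate")] * 20
        )
        margins = PopulationMargins(
            cells=pd.DataFrame(
                [
                    {"age_band": "65-69", "sex": "female", "literacy": "literate",
                     "count": 500},
                    {"age_band": "80+", "sex": "male", "literacy": "illiterate",
                     "count": 500},
                ]
            )
        )
        wt = fit_weights(sample, margins)
        w = wt.weights.sort_values()
        assert np.allclose(w.to_numpy(), [0.625, 2.5])
        # weights sum to the sample size over records
        counts = sample.value_counts()
        assert math.isclose((wt.weights * counts).sum(), 100)

    def test_raking_matches_all_three_margins_to_1e8(self):
        rng = np.random.default_rng(4)
        n = 800
        sample = cells_frame(
            list(
                zip(
                    rng.choice(["65-69", "70-74"], n, p=[0.7, 0.3]),
                    rng.choice(["female", "male"], n, p=[0.6, 0.4]),
                    rng.choice(["literate", "illiterate"], n, p=[0.45, 0.55]),
                )
            )
        )
        margins = PopulationMargins(
            margins={
                "age_band": {"65-69": 550_000, "70-74": 450_000},
                "sex": {"female": 520_000, "male": 480_000},
                "literacy": {"literate": 600_000, "illiterate": 400_000},
            }
        )
        wt = fit_weights(sample, margins)
        assert wt.method == "raking"
        counts = sample.value_counts().astype(float)
        wn = (wt.weights * counts)
        for dim, target in margins.margins.items():
            got = wn.groupby(wn.index.get_level_values(dim)).sum() / wn.sum()
            want = pd.Series(target, dtype=float) / sum(target.values())
            assert (got - want.reindex(got.index)).abs().max() <= 1e-8

    def test_zero_population_cell_collapses_age_bands_with_log(self):
        sample = cells_frame(
            [("65-69", "female", "literate")] * 50
            + [("80+", "female", "literate")] * 50
        )
        margins = PopulationMargins(
            cells=pd.DataFrame(
                [
                    {"age_band": "65-69", "sex": "female", "literacy": "literate",
                     "count": 1000},
                    {"age_band": "80+", "sex": "female", "literacy": "literate",
                     "count": 0},
                ]
            )
        )
        wt = fit_weights(sample, margins)
        assert any("collapsed" in line for line in wt.log)
        assert (wt.weights > 0).all()
        with pytest.raises(ValueError, match="zero population"):
            fit_weights(sample, margins, collapse_empty=False)


def wilson_oracle(k, n, z=1.959963984540054):
    """Independent closed-form Wilson interval."""
    p = k / n
    denom = 1 + z**2 / n
    centre = (p + z**2 / (2 * n)) / denom
    half = z * math.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
    return centre - half, centre + half


class TestPrevalence:
    def test_all_cases_give_point_one(self):
        est = estimate_prevalence([True] * 10)
        assert est.point == 1.0 and est.ci_high == 1.0 and not math.isnan(est.ci_low)

    def test_wilson_interval_matches_independent_closed_form(self):
        est = estimate_prevalence([True] * 3 + [False] * 7)
        lo, hi = wilson_oracle(3, 10)
        assert est.point == 0.30
        assert math.isclose(est.ci_low, lo, abs_tol=1e-10)
        assert math.isclose(est.ci_high, hi, abs_tol=1e-10)

    def test_weighted_mean_algebra_two_cells(self):
        # truth 0.1 / 0.4 in two equal-population cells, sample 80/20:
        # correct weights recover (0.1 + 0.4) / 2 = 0.25
        y = [True] * 8 + [False] * 72 + [True] * 8 + [False] * 12
        w = [0.625] * 80 + [2.5] * 20
        est = estimate_prevalence(y, w)
        assert math.isclose(est.point, 0.25)

    def test_weighted_estimate_invariant_to_weight_scale(self):
        rng = np.random.default_rng(1)
        y = rng.random(200) < 0.3
        w = rng.uniform(0.5, 3.0, 200)
        a = estimate_prevalence(y, w)
        b = estimate_prevalence(y, w * 17.3)
        assert math.isclose(a.point, b.point)
        assert math.isclose(a.ci_low, b.ci_low) and math.isclose(a.ci_high, b.ci_high)
        assert math.isclose(a.n_effective, b.n_effective)

    def test_matching_composition_weighted_equals_unweighted(self):
        y = [True] * 30 + [False] * 70
        est_u = estimate_prevalence(y)
        est_w = estimate_prevalence(y, [1.0] * 100)
        assert math.isclose(est_u.point, est_w.point)

    def test_boundary_prevalence_has_finite_interval(self):
        est = estimate_prevalence([False] * 50, [1.0] * 50)
        assert est.point == 0.0 and 0 <= est.ci_high < 0.2

    def test_empty_input_is_an_error(self):
        with pytest.raises(ValueError):
            estimate_prevalence([])

    def test_subgroup_table_brackets_every_point(self):
        rng = np.random.default_rng(7)
        n = 300
        df = pd.DataFrame(
            {
                "age_band": rng.choice(["65-69", "70-74"], n),
                "sex": rng.choice(["female", "male"], n),
                "literacy": rng.choice(["literate", "illiterate"], n),
                "is_case": rng.random(n) < 0.2,
            }
        )
        w = pd.Series(rng.uniform(0.5, 2.0, n), index=df.index)
        tab = prevalence_table(df, weights=w)
        assert (tab["ci_low"] <= tab["prevalence"]).all()
        assert (tab["prevalence"] <= tab["ci_high"]).all()
        assert (tab["group"] == "total").sum() == 2  # unweighted + weighted


class TestExtrapolation:
    def test_count_scales_linearly_with_population(self):
        est = estimate_prevalence([True] * 10 + [False] * 90)
        out = extrapolate_count(est, 1_000_000)
        assert out["count"] == pytest.approx(100_000)
        assert out["ci_low"] == pytest.approx(est.ci_low * 1_000_000)
        assert out["ci_high"] == pytest.approx(est.ci_high * 1_000_000)
        width_ratio = (out["ci_high"] - out["ci_low"]) / 1_000_000
        assert width_ratio == pytest.approx(est.ci_high - est.ci_low)


class TestPrecisionSampleSize:
    @pytest.mark.parametrize(
        "p, d, n",
        [(0.045, 0.009, 2039), (0.5, 0.05, 385), (0.5, 0.5, 4)],
    )
    def test_formula_examples(self, p, d, n):
        assert precision_sample_size(PrecisionSpec(p, d)) == n

    def test_infeasible_half_width_rejected(self):
        with pytest.raises(ValueError):
            PrecisionSpec(0.045, 0.99)
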