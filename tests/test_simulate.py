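"""Synthetic cohort generator: determinism, validity, missingness, margins."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from stride_prev.algorithm import predict_dataframe
from stride_prev.instruments import MISSING_REFUSED, score_dataframe
from stride_prev.simulate import (
    CohortScenario,
    MissingnessEntry,
    MissingnessSpec,
    TRUTH_COLUMNS,
    apply_missingness,
    band_probabilities,
    generate_cohort,
    indonesia_like,
    make_margins,
    matched_algorithm_spec,
    overall_true_prevalence,
    simulate_dataset,
    southafrica_like,
)
from stride_prev.weighting import fit_weights


@pytest.fixture(scope="module")
def sa_bundle(item_maps):
    return simulate_dataset(southafrica_like(), item_maps, seed=42)


class TestGeneration:
    def test_seeded_runs_are_identical(self, item_maps):
        sc = southafrica_like()
        a = simulate_dataset(sc, item_maps, seed=5)
        b = simulate_dataset(sc, item_maps, seed=5)
        pd.testing.assert_frame_equal(a["records"], b["records"])
        pd.testing.assert_frame_equal(a["truth"], b["truth"])

    def test_latent_truth_never_leaks_into_analysis_columns(self, sa_bundle):
        cols = set(sa_bundle["records"].columns)
        assert not cols.intersection(TRUTH_COLUMNS)
        assert not any(c.startswith("true_") or c == "severity" for c in cols)

    def test_generated_items_validate_against_the_maps(self, item_maps, sa_bundle):
        scores = score_dataframe(sa_bundle["records"], item_maps.values())
        for imap in item_maps.values():
            name = imap.score_name
            ok = scores[f"{name}_evaluable"]
            assert scores.loc[ok, name].between(imap.min_score, imap.max_score).all()

    def test_infeasible_scenario_rejected(self):
        with pytest.raises(ValueError):
            replace(indonesia_like(), prop_female=1.4)
        with pytest.raises(ValueError):
            MissingnessSpec(mode="rate", entries=(MissingnessEntry("eurod", 1.2),))

    def test_demographics_track_scenario_anchors(self, item_maps):
        sc = indonesia_like()
        df, truth, flow = generate_cohort(sc, item_maps, seed=11)
        assert len(df) == sc.n_recruited == 2216
        assert flow["listed"] - sum(flow["ineligible"].values()) == flow["recruited"]
        assert abs(df["age"].mean() - sc.age_mean) < 0.6
        assert abs((df["sex"] == "female").mean() - sc.prop_female) < 0.04
        p_lit_m = (df.loc[df.sex == "male", "literacy"] == "literate").mean()
        p_lit_f = (df.loc[df.sex == "female", "literacy"] == "literate").mean()
        assert 2.0 < p_lit_m / p_lit_f < 3.1  # literacy gap by construction

    def test_zero_prevalence_scenario_classifies_almost_nobody(self, item_maps):
        sc = replace(
            indonesia_like(),
            baseline_prevalence=1e-9,
            missingness=MissingnessSpec(entries=()),
            prior_diagnosis_count=0,
        )
        df, truth, _ = generate_cohort(sc, item_maps, seed=3)
        assert truth["true_case"].sum() == 0
        spec = matched_algorithm_spec(indonesia_like(), item_maps)
        case = predict_dataframe(score_dataframe(df, item_maps.values()), spec)
        assert case["is_case"].mean() < 0.02


class TestMissingness:
    def test_zero_rates_leave_records_unchanged(self, item_maps, sa_bundle):
        df = sa_bundle["records"]
        out, log = apply_missingness(
            df, MissingnessSpec(mode="rate", entries=()),
            item_maps, np.random.default_rng(0),
        )
        pd.testing.assert_frame_equal(out, df)
        assert log.empty

    def test_exact_mode_plants_disjoint_counts(self, item_maps):
        sc = southafrica_like()
        df, *_ = generate_cohort(sc, item_maps, seed=9)
        out, log = apply_missingness(
            df, sc.missingness, item_maps, np.random.default_rng(9)
        )
        assert log["n_struck"].sum() == 85  # 82 algorithm-relevant + 3 lawton
        eurod_cols = item_maps["eurod"].item_ids
        assert (out[eurod_cols].eq(MISSING_REFUSED).all(axis=1)).sum() == 64

    def test_rate_mode_hits_expected_refusals_within_binomial_error(self, item_maps):
        sc = southafrica_like()
        df, *_ = generate_cohort(sc, item_maps, seed=1)
        rate = 64 / 490
        spec = MissingnessSpec(
            mode="rate", entries=(MissingnessEntry("eurod", rate),)
        )
        rng = np.random.default_rng(10)
        hits = [
            apply_missingness(df, spec, item_maps, rng)[1]["n_struck"].iloc[0]
            for _ in range(30)
        ]
        # mean within 3 binomial SEs of 64
        se = np.sqrt(490 * rate * (1 - rate)) / np.sqrt(30)
        assert abs(np.mean(hits) - 64) < 3 * se + 1

    def test_mcar_missingness_is_unrelated_to_demographics(self, item_maps):
        """Chi-squared of strike vs demographics rejects at ~nominal rate."""
        from stride_prev.associations import chisq_independence

        sc = southafrica_like()
        df, *_ = generate_cohort(sc, item_maps, seed=2)
        spec = MissingnessSpec(
            mode="rate", entries=(MissingnessEntry("eurod", 0.13),)
        )
        rng = np.random.default_rng(21)
        rejections = 0
        reps = 100
        for _ in range(reps):
            out, _ = apply_missingness(df, spec, item_maps, rng)
            struck = out[item_maps["eurod"].item_ids[0]] >= MISSING_REFUSED
            for factor in ("sex", "literacy"):
                tab = pd.crosstab(df[factor], struck)
                if tab.shape == (2, 2):
                    _, p, _ = chisq_independence(tab.to_numpy())
                    rejections += p < 0.05
        assert rejections / (2 * reps) < 0.10


class TestMargins:
    def test_undistorted_margins_give_near_unit_weights(self, item_maps):
        sc = indonesia_like()
        df, *_ = generate_cohort(sc, item_maps, seed=6)
        wt = fit_weights(df[["age_band", "sex", "literacy"]], make_margins(sc))
        # sampling noise only; small cells fluctuate more (se ~ 1/sqrt(n_cell))
        counts = df.value_counts(["age_band", "sex", "literacy"])
        big = counts[counts >= 100].index
        assert wt.weights.loc[big].between(0.8, 1.25).all()
        assert wt.weights.between(0.5, 2.5).all()
        assert abs(wt.weights.mean() - 1.0) < 0.15

    def test_oversampled_band_gets_half_weight(self, item_maps):
        sc = indonesia_like()
        df, *_ = generate_cohort(sc, item_maps, seed=6)
        margins = make_margins(sc, distortion={"age_band": {"65-69": 0.5}})
        wt = fit_weights(df[["age_band", "sex", "literacy"]], margins)
        w = wt.weights.reset_index()
        young = w.loc[w.age_band == "65-69", 0].mean()
        older = w.loc[w.age_band != "65-69", 0].mean()
        assert 0.35 < young / older < 0.65

    def test_margins_sum_to_population_total(self):
        sc = southafrica_like()
        m = make_margins(sc)
        assert m.total == pytest.approx(sc.population_65plus)
        m2 = make_margins(sc, margins_only=True)
        assert m2.total == pytest.approx(sc.population_65plus)


def test_analytic_overall_prevalence_matches_simulation(item_maps):
    sc = replace(
        indonesia_like(),
        n_listed=8578,  # 8000 recruited after ineligibility
        missingness=MissingnessSpec(entries=()),
    )
    pi = overall_true_prevalence(sc)
    _, truth, _ = generate_cohort(sc, item_maps, seed=13)
    assert abs(truth["true_case"].mean() - pi) < 0.02
    assert abs(sum(band_probabilities(sc).values()) - 1.0) < 1e-12
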