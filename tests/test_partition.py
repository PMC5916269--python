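import warnings
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from itvpart import partition, synthgen
from itvpart.partition import (
    ModelSpec,
    apply_transform,
    fit_initial_biomass,
    fit_survival_model,
    fit_trait_model,
    lsmeans_pairwise,
    percent_plasticity,
    sequential_anova,
    type3_anova,
)
from itvpart.published import published_percent_e

from .test_synthgen import noise_free_params


class TestTransforms:
    def test_sqrt_and_log_values(self):
        df = pd.DataFrame({"individual_id": ["a", "b"], "height": [16.0, 9.0], "sla": [1.0, np.e]})
        out = apply_transform(df, {"height": "sqrt", "sla": "log"})
        assert list(out["height_transformed"]) == [4.0, 3.0]
        assert out["sla_transformed"].iloc[0] == 0.0
        # originals untouched
        assert list(out["height"]) == [16.0, 9.0]

    def test_log_domain_error_names_record(self):
        df = pd.DataFrame({"individual_id": ["ok", "bad"], "leaf_area": [2.0, 0.0]})
        with pytest.raises(ValueError, match="bad"):
            apply_transform(df, {"leaf_area": "log"})

    def test_sqrt_domain_error(self):
        df = pd.DataFrame({"individual_id": ["x"], "height": [-1.0]})
        with pytest.raises(ValueError, match="sqrt"):
            apply_transform(df, {"height": "sqrt"})


class TestModelFit:
    def test_noise_free_fit_recovers_plastic_contrasts(self):
        df = synthgen.simulate_transplant(noise_free_params(plastic=(2.0, 1.0, 0.0)))
        dft = apply_transform(df, synthgen.TRAIT_TRANSFORMS)
        m = fit_trait_model(dft, ModelSpec(response="height_transformed", covariate=None))
        assert m.rss == pytest.approx(0.0, abs=1e-16)
        # sum-to-zero EL_T coefficients are the level deviations (1, 0, -1)
        coef = m.params[m.term_slices["EL_T"]]
        np.testing.assert_allclose(coef, [1.0, 0.0], atol=1e-10)
        coef_o = m.params[m.term_slices["EL_O"]]
        np.testing.assert_allclose(coef_o, 0.0, atol=1e-10)

    def test_constant_response_gives_zero_effects(self, transformed_records):
        df = transformed_records.copy()
        df["const"] = 5.0
        m = fit_trait_model(df, ModelSpec(response="const"))
        assert m.rss == pytest.approx(0.0, abs=1e-18)
        np.testing.assert_allclose(m.params[1:], 0.0, atol=1e-10)
        assert m.params[0] == pytest.approx(5.0)

    def test_single_transect_drops_R_with_warning(self, transformed_records):
        south = transformed_records[transformed_records["transect"] == "south"]
        with pytest.warns(UserWarning, match="transect"):
            m = fit_trait_model(south, ModelSpec(response="height_transformed"))
        assert "R" not in m.term_slices

    def test_rank_deficiency_names_aliased_terms(self, transformed_records):
        df = transformed_records.copy()
        # make origin a copy of transplant elevation: EL_O aliases EL_T
        df["elevation_origin"] = df["elevation_transplant"]
        with pytest.raises(ValueError, match="aliased"):
            fit_trait_model(df, ModelSpec(response="height_transformed"))


class TestAnova:
    def test_type3_matches_statsmodels_oracle_on_unbalanced_data(self, transformed_records):
        from statsmodels.formula.api import ols
        from statsmodels.stats.anova import anova_lm

        rng = np.random.default_rng(0)
        df = transformed_records.drop(
            rng.choice(transformed_records.index, 80, replace=False)
        ).reset_index(drop=True)
        df["y"] = df["height_transformed"]
        m = fit_trait_model(df, ModelSpec(response="y", include_block=False))
        mine = type3_anova(m).set_index("term")

        data = m.data.copy()
        data["ib"] = data["init_biomass"] - data["init_biomass"].mean()
        res = ols(
            "y ~ C(elevation_origin, Sum) + C(elevation_transplant, Sum)"
            " + C(elevation_origin, Sum):C(elevation_transplant, Sum)"
            " + C(transect, Sum) + ib",
            data=data,
        ).fit()
        ref = anova_lm(res, typ=3)
        pairs = {
            "EL_O": "C(elevation_origin, Sum)",
            "EL_T": "C(elevation_transplant, Sum)",
            "EL_O:EL_T": "C(elevation_origin, Sum):C(elevation_transplant, Sum)",
            "R": "C(transect, Sum)",
            "Init.biom": "ib",
            "Residuals": "Residual",
        }
        for term, ref_term in pairs.items():
            assert mine.loc[term, "ss"] == pytest.approx(
                ref.loc[ref_term, "sum_sq"], rel=1e-8
            )

    def test_type3_equals_type1_on_balanced_design(self, transformed_records):
        # the simulated design is fully balanced; without the (continuous)
        # covariate all terms are mutually orthogonal
        m = fit_trait_model(
            transformed_records, ModelSpec(response="height_transformed", covariate=None)
        )
        t3 = type3_anova(m).set_index("term")["ss"]
        t1 = sequential_anova(m).set_index("term")["ss"]
        for term in t3.index:
            assert t3[term] == pytest.approx(t1[term], abs=1e-8, rel=1e-8)

    def test_sequential_ss_conservation_on_unbalanced_design(self, transformed_records):
        rng = np.random.default_rng(1)
        df = transformed_records.drop(
            rng.choice(transformed_records.index, 120, replace=False)
        ).reset_index(drop=True)
        m = fit_trait_model(df, ModelSpec(response="height_transformed"))
        t1 = sequential_anova(m)
        assert t1["ss"].sum() == pytest.approx(m.total_ss, rel=1e-10)

    def test_single_factor_model_reduces_to_oneway_anova(self, transformed_records):
        df = transformed_records
        m = fit_trait_model(
            df,
            ModelSpec(
                response="height_transformed",
                covariate=None,
                include_interaction=False,
                include_transect=False,
                include_block=False,
            ),
        )
        # drop EL_O to leave a one-way EL_T model for the classical check
        y = df["height_transformed"].to_numpy()
        grand = y.mean()
        between = sum(
            len(g) * (g.mean() - grand) ** 2
            for _, g in df.groupby("elevation_transplant")["height_transformed"]
        )
        t3 = type3_anova(m).set_index("term")
        assert t3.loc["EL_T", "ss"] == pytest.approx(between, rel=1e-10)

    def test_null_term_f_test_calibration(self):
        # EL_O has no effect in the plastic-only generator: its type III F
        # test should reject at the nominal 5% rate
        rejections = 0
        n_reps = 200
        for s in range(n_reps):
            p = synthgen.plastic_only(seed=1000 + s)
            df = synthgen.simulate_transplant(p)
            dft = apply_transform(df, {"height": "sqrt"})
            m = fit_trait_model(dft, ModelSpec(response="height_transformed"))
            tab = type3_anova(m).set_index("term")
            rejections += tab.loc["EL_O", "p"] < 0.05
        rate = rejections / n_reps
        ci = 1.96 * np.sqrt(0.05 * 0.95 / n_reps)
        assert abs(rate - 0.05) < ci + 1e-12


class TestPercentPlasticity:
    def test_simple_ratio(self):
        tab = pd.DataFrame(
            {"term": ["EL_O", "EL_T"], "df": [2, 2], "ss": [1.0, 3.0], "ms": [0.5, 1.5]}
        )
        r = percent_plasticity(tab, "t")
        assert r.percent_e == pytest.approx(75.0)
        assert r.percent_e + r.percent_g == 100.0

    def test_zero_denominator_is_undefined_not_coerced(self):
        tab = pd.DataFrame({"term": ["EL_O", "EL_T"], "df": [2, 2], "ss": [0.0, 0.0]})
        r = percent_plasticity(tab)
        assert np.isnan(r.percent_e) and np.isnan(r.percent_g)

    def test_ratio_invariant_to_response_rescaling(self, transformed_records):
        df = transformed_records.copy()
        df["scaled"] = 10.0 * df["height_transformed"]
        m1 = fit_trait_model(df, ModelSpec(response="height_transformed"))
        m2 = fit_trait_model(df, ModelSpec(response="scaled"))
        p1 = percent_plasticity(type3_anova(m1)).percent_e
        p2 = percent_plasticity(type3_anova(m2)).percent_e
        assert p1 == pytest.approx(p2, abs=1e-9)

    def test_published_mean_squares_reproduce_reported_shares(self):
        # SS = df × MS from the printed trait ANOVA of the field study
        assert published_percent_e("height") == pytest.approx(68.4, abs=0.15)
        assert published_percent_e("sla") == pytest.approx(78.2, abs=0.15)
        assert 68.3 <= published_percent_e("leaf_area") <= 78.2


class TestSurvivalModel:
    def test_logit_effect_recovery(self):
        design = synthgen.DesignSpec(individuals_per_origin_per_block=28)  # n=2016
        offsets = {}
        for tr in design.transects:
            for o in design.elevations:
                offsets[(tr, o, "low")] = 0.5
                offsets[(tr, o, "high")] = -0.5
        p = replace(default_surv_params(seed=7), design=design, survival_logit_offsets=offsets)
        df = synthgen.simulate_transplant(p)
        model, _ = fit_survival_model(df)
        coef = model.params[model.term_slices["EL_T"]]
        se = np.sqrt(np.diag(model.cov_params))[model.term_slices["EL_T"]]
        # sum-to-zero level effects of (0.5, 0, -0.5): first contrast = 0.5
        assert abs(coef[0] - 0.5) < 3 * se[0]
        assert abs(coef[1] - 0.0) < 3 * se[1]

    def test_constant_outcome_rejected(self, default_records):
        df = default_records.copy()
        df["survived"] = True
        with pytest.raises(ValueError, match="constant"):
            fit_survival_model(df)

    def test_all_survivor_cell_reported_as_separation(self, default_records):
        df = default_records.copy()
        mask = (
            (df["transect"] == "south")
            & (df["elevation_origin"] == "low")
            & (df["elevation_transplant"] == "low")
        )
        df.loc[mask, "survived"] = True
        with pytest.warns(UserWarning, match="separation"):
            fit_survival_model(df)

    def test_null_survival_p_values_are_uniform(self):
        # no cell offsets: every term's deviance test is a null test
        pvals = []
        for s in range(80):
            df = synthgen.simulate_transplant(synthgen.default_params(seed=2000 + s))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                _, tab = fit_survival_model(df)
            pvals.append(float(tab.set_index("term").loc["EL_O", "p"]))
        from scipy import stats

        assert stats.kstest(pvals, "uniform").pvalue > 0.01


def default_surv_params(seed):
    return synthgen.default_params(seed=seed)


class TestLsmeans:
    def test_noise_free_lsmeans_recover_plastic_effects(self):
        df = synthgen.simulate_transplant(noise_free_params(plastic=(2.0, 1.0, 0.0)))
        dft = apply_transform(df, synthgen.TRAIT_TRANSFORMS)
        m = fit_trait_model(dft, ModelSpec(response="height_transformed", covariate=None))
        res = lsmeans_pairwise(m)
        means = res.means.groupby("EL_T")["estimate"].mean()
        assert means["low"] - means["mid"] == pytest.approx(1.0, abs=1e-10)
        assert means["mid"] - means["high"] == pytest.approx(1.0, abs=1e-10)
        by_origin = res.means.groupby("EL_O")["estimate"].mean()
        assert by_origin.max() - by_origin.min() == pytest.approx(0.0, abs=1e-10)

    def test_lsmeans_equal_raw_cell_means_in_balanced_design(self, transformed_records):
        m = fit_trait_model(
            transformed_records, ModelSpec(response="height_transformed", covariate=None)
        )
        res = lsmeans_pairwise(m)
        raw = transformed_records.groupby(["elevation_origin", "elevation_transplant"])[
            "height_transformed"
        ].mean()
        for _, row in res.means.iterrows():
            assert row["estimate"] == pytest.approx(
                raw[(row["EL_O"], row["EL_T"])], abs=1e-10
            )

    def test_contrasts_are_antisymmetric(self, transformed_records):
        m = fit_trait_model(transformed_records, ModelSpec(response="height_transformed"))
        res = lsmeans_pairwise(m)
        means = {
            f"{r['EL_O']}:{r['EL_T']}": r["estimate"] for _, r in res.means.iterrows()
        }
        for _, row in res.contrasts.iterrows():
            assert row["estimate"] == pytest.approx(
                means[row["a"]] - means[row["b"]], abs=1e-10
            )

    def test_adjusted_p_not_smaller_than_unadjusted(self, transformed_records):
        m = fit_trait_model(transformed_records, ModelSpec(response="height_transformed"))
        tukey = lsmeans_pairwise(m, adjust="tukey").contrasts
        none = lsmeans_pairwise(m, adjust="none").contrasts
        assert (tukey["p_adj"] >= none["p_adj"] - 1e-12).all()


class TestStepwise:
    def test_single_collinear_candidate_gives_r2_one(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"x": rng.normal(size=40)})
        df["final_biomass"] = 2.0 * df["x"] + 1.0
        out = fit_initial_biomass(df, candidates=("x",))
        assert out["selected"] == ["x"]
        assert out["r_squared"] == pytest.approx(1.0)

    def test_known_generating_subset_is_selected(self):
        rng = np.random.default_rng(3)
        n = 200
        df = pd.DataFrame(rng.normal(size=(n, 5)), columns=[f"c{i}" for i in range(5)])
        df["final_biomass"] = 1.0 + 0.8 * df["c1"] - 0.6 * df["c3"] + rng.normal(0, 0.05, n)
        out = fit_initial_biomass(df, candidates=tuple(f"c{i}" for i in range(5)))
        assert sorted(out["selected"]) == ["c1", "c3"]
        assert len(out["path"]) >= 3  # selection path is logged

    def test_predictions_are_returned_per_row(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame({"a": rng.normal(size=50)})
        df["final_biomass"] = df["a"] + rng.normal(0, 0.1, 50)
        out = fit_initial_biomass(df, candidates=("a",))
        assert len(out["predictions"]) == 50
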