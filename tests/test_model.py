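"""Design construction, mixed/OLS fitting, prediction, contrasts, selection."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from cacaoflow import model, reference, synthetic_data as sd
from conftest import one_row_covariates


def _noiseless_campaign(seed=11):
    cfg = sd.GeneratorConfig(seed=seed, n_days=3, interval_min=5, n_flow_rows=1200,
                             noise_sd=0.0, plant_effect_sd=0.0, day_effect_sd=0.0)
    return sd.generate_campaign(cfg)


class TestBuildDesign:
    def test_full_interaction_has_15_columns(self, small_campaign):
        _, flow = small_campaign
        X, y = model.build_design(flow)
        assert X.shape[1] == 15
        assert list(X.columns) == model.design_columns()
        assert len(y) == len(flow)

    def test_single_af_has_5_columns(self, small_campaign):
        _, flow = small_campaign
        X, _ = model.build_design(flow[flow.af == "H_PAR"])
        assert X.shape[1] == 5

    def test_missing_covariate_rejected_with_index(self, small_campaign):
        _, flow = small_campaign
        broken = flow.copy().reset_index(drop=True)
        broken.loc[7, "vpd_kpa"] = np.nan
        with pytest.raises(ValueError, match=r"rows \[7\]"):
            model.build_design(broken)

    def test_unknown_af_rejected(self, small_campaign):
        _, flow = small_campaign
        broken = flow.copy().reset_index(drop=True)
        broken.loc[3, "af"] = "Z_PAR"
        with pytest.raises(ValueError, match="unknown AF"):
            model.build_design(broken)


class TestPredict:
    def test_intercept_only(self):
        coeffs = model.ModelCoefficients.reconciled()
        assert model.predict(coeffs, one_row_covariates(0, 0, 0, 0, "H_PAR"))[0] == pytest.approx(0.14904)

    def test_linear_in_par(self):
        coeffs = model.ModelCoefficients.reconciled()
        base = one_row_covariates(80.0, 25.0, 400.0, 0.6, "M_PAR")
        doubled = one_row_covariates(80.0, 25.0, 800.0, 0.6, "M_PAR")
        delta = model.predict(coeffs, doubled)[0] - model.predict(coeffs, base)[0]
        assert delta == pytest.approx(coeffs["M_PAR"]["par"] * 400.0, abs=1e-12)

    def test_missing_covariate_errors(self):
        coeffs = model.ModelCoefficients.reconciled()
        df = one_row_covariates(80.0, 25.0, 400.0, 0.6, "M_PAR").drop(columns=["vpd_kpa"])
        with pytest.raises(ValueError, match="vpd_kpa"):
            model.predict(coeffs, df)

    def test_unknown_af_errors(self):
        coeffs = model.ModelCoefficients.reconciled()
        with pytest.raises(ValueError, match="no coefficients"):
            model.predict(coeffs, one_row_covariates(0, 0, 0, 0, "Z_PAR"))


class TestFit:
    def test_noiseless_data_recovers_generating_coefficients(self):
        _, flow = _noiseless_campaign()
        res = model.fit(flow, method="ols")
        truth = model.ModelCoefficients.reconciled()
        for af in reference.AFS:
            for term in model.TERMS:
                assert res.params[f"{af}:{term}"] == pytest.approx(truth[af][term], abs=1e-8)

    def test_ols_and_mixed_agree_without_group_variance(self):
        _, flow = _noiseless_campaign()
        rng = np.random.default_rng(0)
        flow = flow.assign(vs_l_h=flow["vs_true"] + rng.normal(0, 0.01, len(flow)))
        ols = model.fit(flow, method="ols")
        reml = model.fit(flow, method="reml")
        assert np.allclose(ols.params, reml.params.reindex(ols.params.index), atol=1e-6)

    def test_information_criteria_consistent_with_loglik(self, small_campaign):
        _, flow = small_campaign
        res = model.fit(flow, method="ols")
        assert res.aic == pytest.approx(-2 * res.llf + 2 * res.n_params, abs=1e-6)
        assert res.bic == pytest.approx(-2 * res.llf + res.n_params * np.log(res.n), abs=1e-6)

    def test_singular_design_names_columns(self, small_campaign):
        _, flow = small_campaign
        broken = flow.copy()
        broken["vpd_kpa"] = broken["t_a_c"]  # exact collinearity with t_a
        with pytest.raises(ValueError, match="collinear"):
            model.fit(broken, method="ols")

    def test_random_factor_with_single_level_dropped(self, small_campaign, caplog):
        _, flow = small_campaign
        single = flow[flow["plant_id"] == flow["plant_id"].iloc[0]]
        res = model.fit(single[single.af == single.af.iloc[0]], random_spec=("plant",))
        assert res.method == "ols"  # falls back once the only factor is dropped


@pytest.fixture(scope="module")
def fitted():
    _, flow = sd.generate_campaign(sd.GeneratorConfig(seed=19, n_days=3, interval_min=5, n_flow_rows=1500))
    return model.fit(flow, method="ols")


class TestContrasts:

    def test_self_contrast_is_null(self, fitted):
        c = model.contrast_slopes(fitted, "vpd", "H_PAR", "H_PAR")
        assert c["estimate"] == 0.0 and c["p"] == 1.0

    def test_contrast_matches_param_difference(self, fitted):
        c = model.contrast_slopes(fitted, "par", "M_PAR", "L_PAR")
        manual = fitted.params["M_PAR:par"] - fitted.params["L_PAR:par"]
        assert c["estimate"] == pytest.approx(manual)
        assert 0 <= c["p"] <= 1

    def test_reference_coded_table_roundtrip(self, fitted):
        tab = model.reference_coded_table(fitted).set_index(["term", "level"])
        base = tab.loc[("vpd", "H_PAR"), "estimate"]
        diff = tab.loc[("vpd", "M_PAR"), "estimate"]
        assert base + diff == pytest.approx(fitted.params["M_PAR:vpd"], abs=1e-12)

    def test_unknown_term_errors(self, fitted):
        with pytest.raises(ValueError, match="unknown term"):
            model.contrast_slopes(fitted, "humidity", "H_PAR", "M_PAR")


class TestSelectModel:
    def _linear_data(self, seed, n=400):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame({
            "af": "H_PAR",
            "rh_a_pct": rng.uniform(50, 100, n),
            "t_a_c": rng.uniform(20, 32, n),
            "par_umol_m2_s": rng.uniform(0, 2000, n),
        })
        from cacaoflow.micromet import vpd

        df["vpd_kpa"] = vpd(df["t_a_c"].to_numpy(), df["rh_a_pct"].to_numpy())
        df["vs_l_h"] = sd.true_sap_flow(df, af="H_PAR") + rng.normal(0, 0.015, n)
        return df

    def test_linear_truth_wins_bic_across_seeds(self):
        candidates = [{"name": "linear", "quadratic": ()},
                      {"name": "quad_par", "quadratic": ("par",)}]
        wins = 0
        for seed in range(50):
            tab = model.select_model(candidates, self._linear_data(seed)).set_index("name")
            wins += tab.loc["linear", "rank_bic"] == 1
        assert wins >= 45

    def test_duplicate_candidates_tie_to_first(self):
        candidates = [{"name": "a", "quadratic": ()}, {"name": "b", "quadratic": ()}]
        tab = model.select_model(candidates, self._linear_data(1))
        assert tab.loc[0, "aic"] == tab.loc[1, "aic"]
        assert tab.loc[0, "rank_aic"] == 1 and tab.loc[1, "rank_aic"] == 2

    def test_single_candidate(self):
        tab = model.select_model([{"name": "only", "quadratic": ()}], self._linear_data(2))
        assert tab["rank_aic"].tolist() == [1]

    def test_failed_candidate_excluded(self):
        df = self._linear_data(3)
        # two-valued covariate: its square is linearly dependent on it,
        # so only the quadratic candidate is singular
        df["t_a_c"] = np.where(np.arange(len(df)) % 2 == 0, 20.0, 30.0)
        candidates = [{"name": "linear", "quadratic": ()}, {"name": "quad_ta", "quadratic": ("t_a",)}]
        tab = model.select_model(candidates, df).set_index("name")
        assert tab.loc["quad_ta", "failed"]
        assert tab.loc["linear", "rank_bic"] == 1


class TestPartialResiduals:
    def _fit(self, quad_coeff=0.0, seed=4, n=600):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame({
            "af": "L_PAR",
            "rh_a_pct": rng.uniform(60, 100, n),
            "t_a_c": rng.uniform(20, 30, n),
            "par_umol_m2_s": rng.uniform(0, 600, n),
        })
        df["vpd_kpa"] = 3.5 * (1 - df["rh_a_pct"] / 100) + rng.normal(0, 0.05, n)
        signal = sd.true_sap_flow(df, af="L_PAR")
        centered_par = df["par_umol_m2_s"] - df["par_umol_m2_s"].mean()
        df["vs_l_h"] = signal + quad_coeff * centered_par**2 + rng.normal(0, 0.01, n)
        return df, model.fit(df, method="ols")

    def test_linear_data_not_flagged(self):
        df, res = self._fit(quad_coeff=0.0)
        _, flagged, p = model.partial_residuals(res, df, "par", alpha=0.01)
        assert not flagged

    def test_injected_quadratic_flagged(self):
        df, res = self._fit(quad_coeff=5e-7)
        _, flagged, _ = model.partial_residuals(res, df, "par", alpha=0.01)
        assert flagged

    def test_constant_covariate_errors(self):
        df, res = self._fit()
        df["t_a_c"] = 25.0
        with pytest.raises(ValueError, match="constant"):
            model.partial_residuals(res, df, "t_a")

    def test_unknown_variable_errors(self):
        df, res = self._fit()
        with pytest.raises(ValueError, match="not a model covariate"):
            model.partial_residuals(res, df, "wind")


def test_printed_coefficient_table_preserved_verbatim():
    printed = model.ModelCoefficients.as_printed()
    assert printed["M_PAR"]["beta0"] == 0.37090
    assert model.ModelCoefficients.reconciled()["M_PAR"]["beta0"] == pytest.approx(0.51994)
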