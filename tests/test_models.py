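"""Hypothesis model rosters, weighted REML estimation, prediction curves."""

import subprocess

import numpy as np
import pandas as pd
import pytest

from alfrange import fit_model, model_spec, predict_response_curve
from alfrange.models import (
    ALF_TYPES,
    ENV_ATTRIBUTES,
    ModelSpec,
    RankDeficientDesign,
    build_dataset,
)


def wls_oracle(X, y, w):
    """Closed-form weighted OLS: beta = (X'WX)^-1 X'Wy."""
    W = np.diag(w)
    return np.linalg.solve(X.T @ W @ X, X.T @ W @ y)


def simulate_table(seed, n_groups=25, per_group=4, group_sd=0.0, noise_sd=1.0, weights=None):
    rng = np.random.default_rng(seed)
    n = n_groups * per_group
    g = np.repeat(np.arange(n_groups), per_group)
    x1 = rng.normal(size=n)
    x2 = rng.normal(size=n)
    ge = rng.normal(0, group_sd, n_groups)[g]
    w = np.ones(n) if weights is None else weights
    y = 1.5 + 2.0 * x1 - 0.7 * x2 + ge + rng.normal(size=n) * noise_sd / np.sqrt(w)
    return pd.DataFrame(
        {"resp": y, "x1": x1, "x2": x2, "weight": w, "animal_id": g}
    )


class TestRosters:
    def test_h1_full_roster_verbatim(self):
        spec = model_spec("H1")
        assert spec.response == "log_area"
        assert spec.fixed_terms == (
            "avail_paved", "avail_unpaved", "avail_fence",
            "avail_elevation", "avail_roughness", "avail_forage",
            "avail_shrub", "avail_tree", "avail_snow",
            "I_male",
            "I_male:avail_paved", "I_male:avail_unpaved", "I_male:avail_fence",
            "nDays",
        )

    def test_h2_restricted_to_movement_cost_attributes(self):
        spec = model_spec("H2")
        assert spec.response == "loglog_si"
        assert spec.fixed_terms == (
            "avail_paved", "avail_unpaved", "avail_fence",
            "avail_roughness", "avail_snow",
            "I_male",
            "I_male:avail_paved", "I_male:avail_unpaved", "I_male:avail_fence",
            "nDays",
        )
        env_terms = [t for t in spec.fixed_terms if t.startswith("avail_") and
                     t.split("_")[1] in ENV_ATTRIBUTES]
        assert env_terms == ["avail_roughness", "avail_snow"]

    @pytest.mark.parametrize("focal", ALF_TYPES)
    def test_h3_roster_and_self_exclusion(self, focal):
        spec = model_spec("H3", focal)
        assert spec.response == f"logSR_{focal}"
        assert spec.fixed_terms == tuple(
            [f"avail_{focal}"]
            + [f"logSR_{t}" for t in ALF_TYPES if t != focal]
            + [f"logSR_{a}" for a in ENV_ATTRIBUTES]
            + ["I_male", f"I_male:avail_{focal}"]
        )
        assert spec.response not in spec.fixed_terms
        assert "nDays" not in spec.fixed_terms

    @pytest.mark.parametrize("focal", ENV_ATTRIBUTES)
    def test_h4_roster_and_self_exclusion(self, focal):
        spec = model_spec("H4", focal)
        assert spec.response == f"logSR_{focal}"
        assert spec.fixed_terms == tuple(
            [f"avail_{focal}", "logSR_paved", "logSR_unpaved", "logSR_fence"]
            + [f"logSR_{a}" for a in ENV_ATTRIBUTES if a != focal]
            + ["I_male", "I_male:avail_paved", "I_male:avail_unpaved", "I_male:avail_fence"]
        )
        assert spec.response not in spec.fixed_terms

    def test_invalid_focal_rejected(self):
        with pytest.raises(ValueError):
            model_spec("H3", "forage")
        with pytest.raises(ValueError):
            model_spec("H4", "fence")


class TestFitModel:
    def test_zero_group_variance_matches_ols(self):
        """With no between-animal variance and equal weights the fixed
        effects collapse to ordinary least squares."""
        tab = simulate_table(1, group_sd=0.0)
        fit = fit_model(tab, ModelSpec("H1", "resp", ("x1", "x2")))
        X = np.column_stack([np.ones(len(tab)), tab.x1, tab.x2])
        expected = wls_oracle(X, tab.resp.to_numpy(), np.ones(len(tab)))
        np.testing.assert_allclose(fit.beta, expected, rtol=1e-6)
        assert not fit.used_random_effect

    def test_unequal_weights_match_wls_oracle(self):
        rng = np.random.default_rng(5)
        w = rng.uniform(0.2, 4.0, 100)
        tab = simulate_table(2, group_sd=0.0, weights=w)
        fit = fit_model(tab, ModelSpec("H1", "resp", ("x1", "x2")))
        X = np.column_stack([np.ones(len(tab)), tab.x1, tab.x2])
        expected = wls_oracle(X, tab.resp.to_numpy(), w)
        np.testing.assert_allclose(fit.beta, expected, rtol=1e-6)

    def test_vanishing_noise_recovers_slope(self):
        tab = simulate_table(3, group_sd=0.0, noise_sd=1e-8)
        fit = fit_model(tab, ModelSpec("H1", "resp", ("x1", "x2")))
        assert fit.coef("x1") == pytest.approx(2.0, abs=1e-6)
        assert fit.coef("x2") == pytest.approx(-0.7, abs=1e-6)

    def test_group_variance_recovered(self):
        tab = simulate_table(4, n_groups=60, per_group=5, group_sd=2.0)
        fit = fit_model(tab, ModelSpec("H1", "resp", ("x1", "x2")))
        assert fit.used_random_effect
        assert 2.0 < fit.tau2 < 8.0  # true 4.0
        assert 0.5 < fit.sigma2 < 2.0  # true 1.0

    def test_matches_lme4_reference(self, tmp_path):
        """Independent cross-check of the weighted random-intercept REML
        fit against lme4::lmer on the same data."""
        rng = np.random.default_rng(7)
        n, G = 120, 30
        g = np.repeat(np.arange(G), 4)
        x = rng.normal(size=n)
        w = rng.uniform(0.3, 3.0, n)
        y = 1.0 + 2.0 * x + rng.normal(0, 1.5, G)[g] + rng.normal(size=n) * np.sqrt(0.8 / w)
        csv = tmp_path / "d.csv"
        pd.DataFrame({"y": y, "x": x, "g": g, "w": w}).to_csv(csv, index=False)
        r_out = tmp_path / "r.csv"
        script = (
            f"suppressMessages(library(lme4));"
            f"d <- read.csv('{csv}');"
            f"m <- lmer(y ~ x + (1|g), data=d, weights=w, REML=TRUE);"
            f"co <- summary(m)$coefficients;"
            f"vc <- as.data.frame(VarCorr(m));"
            f"write.csv(data.frame(beta0=co[1,1], beta1=co[2,1], se1=co[2,2],"
            f" tau2=vc$vcov[1], sigma2=vc$vcov[2]), '{r_out}', row.names=FALSE)"
        )
        try:
            subprocess.run(["Rscript", "-e", script], check=True, capture_output=True, timeout=120)
        except (FileNotFoundError, subprocess.CalledProcessError, subprocess.TimeoutExpired):
            pytest.skip("Rscript/lme4 unavailable")
        ref = pd.read_csv(r_out).iloc[0]
        tab = pd.DataFrame({"resp": y, "x": x, "weight": w, "animal_id": g})
        fit = fit_model(tab, ModelSpec("H1", "resp", ("x",)))
        assert fit.coef("x") == pytest.approx(ref.beta1, rel=1e-5)
        assert fit.coef_se("x") == pytest.approx(ref.se1, rel=1e-4)
        assert fit.tau2 == pytest.approx(ref.tau2, rel=1e-3)
        assert fit.sigma2 == pytest.approx(ref.sigma2, rel=1e-3)

    def test_single_observation_groups_fall_back_to_wls(self):
        tab = simulate_table(6, n_groups=40, per_group=1, group_sd=1.0)
        fit = fit_model(tab, ModelSpec("H1", "resp", ("x1",)))
        assert not fit.used_random_effect
        assert fit.n_groups == 40

    def test_rank_deficient_design_reports_aliased(self):
        tab = simulate_table(8)
        tab["x3"] = 2.0 * tab["x1"]  # exact collinearity
        with pytest.raises(RankDeficientDesign) as err:
            fit_model(tab, ModelSpec("H1", "resp", ("x1", "x2", "x3")))
        assert set(err.value.aliased) & {"x1", "x3"}

    def test_too_few_rows_rejected(self):
        tab = simulate_table(9).head(3)
        with pytest.raises(ValueError, match="too few rows"):
            fit_model(tab, ModelSpec("H1", "resp", ("x1", "x2")))

    def test_missing_rows_dropped_and_counted(self):
        tab = simulate_table(10)
        tab.loc[:4, "x1"] = np.nan
        fit = fit_model(tab, ModelSpec("H1", "resp", ("x1", "x2")))
        assert fit.n_dropped == 5
        assert fit.n_obs == len(tab) - 5


class TestBuildDataset:
    def _inputs(self):
        manifest = pd.DataFrame(
            {
                "fold_id": ["f1", "f2", "f3"],
                "animal_id": ["a1", "a1", "a2"],
                "species": ["deer", "deer", "pronghorn"],
                "sex": ["F", "M", "F"],
                "season": ["winter"] * 3,
                "year": [2021] * 3,
                "n_points": [30, 40, 50],
                "n_days": [3, 4, 5],
                "weight": [1.0, 1.1, 0.9],
            }
        )
        metrics = pd.DataFrame(
            {"fold_id": ["f1", "f2", "f3"], "log_area": [12.0, 12.5, 13.0],
             "loglog_si": [-0.5, -0.4, -0.3]}
        )
        sel = pd.DataFrame(
            [
                {"fold_id": f, "attribute": a, "log_sr": 0.1, "available": 0.5}
                for f in ["f1", "f2", "f3"]
                for a in ["forage", "fence"]
            ]
        )
        return manifest, metrics, sel

    def test_species_split_disjoint(self):
        manifest, metrics, sel = self._inputs()
        deer = build_dataset(manifest, metrics, sel, "deer", "winter")
        prong = build_dataset(manifest, metrics, sel, "pronghorn", "winter")
        assert set(deer.fold_id) == {"f1", "f2"}
        assert set(prong.fold_id) == {"f3"}

    def test_sex_indicator_and_ndays(self):
        manifest, metrics, sel = self._inputs()
        df = build_dataset(manifest, metrics, sel, "deer", "winter")
        assert df["I_male"].tolist() == [0.0, 1.0]
        assert df["nDays"].tolist() == [3.0, 4.0]
        assert "logSR_forage" in df.columns and "avail_fence" in df.columns

    def test_empty_selection_rejected(self):
        manifest, metrics, sel = self._inputs()
        with pytest.raises(ValueError, match="no folds"):
            build_dataset(manifest, metrics, sel, "elk", "winter")


class TestPredictionCurves:
    def _fit(self):
        tab = simulate_table(11, n_groups=30, per_group=4, group_sd=1.0)
        return fit_model(tab, ModelSpec("H1", "resp", ("x1", "x2"))), tab

    def test_mean_point_equals_weighted_mean_prediction(self):
        fit, tab = self._fit()
        curve = predict_response_curve(fit, "x1", n_grid=7)
        w = tab["weight"].to_numpy()
        x1_bar = np.average(tab.x1, weights=w)
        x2_bar = np.average(tab.x2, weights=w)
        expected = fit.coef("Intercept") + fit.coef("x1") * x1_bar + fit.coef("x2") * x2_bar
        interp = np.interp(x1_bar, curve.x, curve.y_hat)
        assert interp == pytest.approx(expected, abs=1e-6)

    def test_ci_width_grows_toward_edges(self):
        fit, _ = self._fit()
        curve = predict_response_curve(fit, "x1", n_grid=101)
        width = curve.hi95 - curve.lo95
        mid = len(curve) // 2
        assert width.iloc[0] > width.iloc[mid]
        assert width.iloc[-1] > width.iloc[mid]
        assert np.allclose(width, 2 * 1.96 * curve.se)

    def test_curve_slope_equals_coefficient(self):
        fit, _ = self._fit()
        curve = predict_response_curve(fit, "x1", n_grid=50)
        slopes = np.diff(curve.y_hat) / np.diff(curve.x)
        np.testing.assert_allclose(slopes, fit.coef("x1"), rtol=1e-9)

    def test_male_interaction_adds_to_slope(self):
        rng = np.random.default_rng(12)
        n = 120
        tab = pd.DataFrame(
            {
                "x1": rng.normal(size=n),
                "I_male": np.tile([0.0, 1.0], n // 2),
                "weight": 1.0,
                "animal_id": np.repeat(np.arange(30), 4),
            }
        )
        tab["resp"] = 1 + 2 * tab.x1 + 0.5 * tab.I_male * tab.x1 + rng.normal(size=n) * 0.1
        fit = fit_model(tab, ModelSpec("H1", "resp", ("x1", "I_male", "I_male:x1")))
        cf = predict_response_curve(fit, "x1", n_grid=20, male=False)
        cm = predict_response_curve(fit, "x1", n_grid=20, male=True)
        sf = np.diff(cf.y_hat)[0] / np.diff(cf.x)[0]
        sm = np.diff(cm.y_hat)[0] / np.diff(cm.x)[0]
        assert sf == pytest.approx(fit.coef("x1"), rel=1e-6)
        assert sm == pytest.approx(fit.coef("x1") + fit.coef("I_male:x1"), rel=1e-6)

    def test_absent_focal_rejected(self):
        fit, _ = self._fit()
        with pytest.raises(ValueError, match="not among"):
            predict_response_curve(fit, "x9")
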