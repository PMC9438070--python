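"""Penalized GAM engine: shrinkage, calibration, prediction, model specs."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from nutriage.gam import GAM, Categorical, RandomIntercept, Smooth
from nutriage.models import (
    FitSummary,
    build_model_spec,
    compare_models_aic,
    fit_gam,
    predict_at,
)


def _panel_data(rng, ns=150, nv=4, beta=0.0, optimum=0.0, noise=0.5, subject_sd=0.5):
    """Repeated-measures table with an optional quadratic carbohydrate
    effect planted at ``optimum`` (standardized units)."""
    n = ns * nv
    sid = np.repeat(np.arange(ns), nv)
    X = rng.normal(0, 1, (n, 3))
    u = np.repeat(rng.normal(0, subject_sd, ns), nv)
    y = beta * (X[:, 1] - optimum) ** 2 + u + rng.normal(0, noise, n)
    return pd.DataFrame(
        {"prot": X[:, 0], "carb": X[:, 1], "lip": X[:, 2], "y": y, "sid": sid}
    )


class TestFitting:
    def test_linear_truth_matches_ols_and_shrinks_edf(self, rng):
        n = 400
        x = rng.uniform(-2, 2, n)
        y = 1.0 + 0.7 * x + rng.normal(0, 0.4, n)
        df = pd.DataFrame({"x": x, "y": y})
        res = GAM(df, "y", [Smooth("x")]).fit()
        coef = np.polyfit(x, y, 1)
        ols_pred = np.polyval(coef, x)
        assert res.edf("s(x)") < 2.5  # shrinks toward the linear null space
        assert np.max(np.abs(res.fittedvalues - ols_pred)) < 0.05

    def test_quadratic_optimum_recovered_in_3d_smooth(self):
        rng = np.random.default_rng(21)
        df = _panel_data(rng, ns=250, beta=0.4, optimum=0.5)
        res = GAM(
            df, "y", [Smooth(("prot", "carb", "lip")), RandomIntercept("sid")]
        ).fit()
        grid = pd.DataFrame(
            {"prot": 0.0, "carb": np.linspace(-2, 2, 201), "lip": 0.0}
        )
        pred = res.predict(grid, include_random=False)
        argmin = grid["carb"].iloc[int(np.argmin(pred))]
        assert abs(argmin - 0.5) < 0.5

    def test_null_smooth_p_values_approximately_uniform(self):
        """Pure-noise outcome across seeded replicates: rejection rate at
        alpha=0.05 stays within binomial tolerance of 0.05."""
        n_rep, n = 200, 120
        ps = []
        for rep in range(n_rep):
            r = np.random.default_rng(1000 + rep)
            df = pd.DataFrame({"x": r.uniform(-2, 2, n), "y": r.normal(0, 1, n)})
            res = GAM(df, "y", [Smooth("x")]).fit()
            ps.append(res.smooth_terms()["p"].iloc[0])
        frac = np.mean(np.asarray(ps) < 0.05)
        tol = 3 * np.sqrt(0.05 * 0.95 / n_rep)  # ~3 sigma binomial band
        assert abs(frac - 0.05) < tol

    def test_fit_invariant_to_row_order(self, rng):
        df = _panel_data(rng, ns=40, beta=0.3)
        res1 = GAM(df, "y", [Smooth(("prot", "carb", "lip")), RandomIntercept("sid")]).fit()
        shuffled = df.sample(frac=1.0, random_state=1).reset_index(drop=True)
        res2 = GAM(shuffled, "y", [Smooth(("prot", "carb", "lip")), RandomIntercept("sid")]).fit()
        grid = pd.DataFrame({"prot": [0.0, 1.0], "carb": [0.0, -1.0], "lip": [0.0, 0.5]})
        np.testing.assert_allclose(
            res1.predict(grid, include_random=False),
            res2.predict(grid, include_random=False),
            atol=1e-6,
        )

    def test_fit_invariant_to_affine_rescaling_of_inputs(self, rng):
        df = _panel_data(rng, ns=40, beta=0.3)
        res1 = GAM(df, "y", [Smooth(("prot", "carb", "lip"))]).fit()
        scaled = df.copy()
        scaled["carb"] = scaled["carb"] * 1000.0 + 5.0
        res2 = GAM(scaled, "y", [Smooth(("prot", "carb", "lip"))]).fit()
        grid1 = pd.DataFrame({"prot": [0.3], "carb": [-0.7], "lip": [0.1]})
        grid2 = grid1.assign(carb=grid1["carb"] * 1000.0 + 5.0)
        assert res1.predict(grid1)[0] == pytest.approx(res2.predict(grid2)[0], abs=1e-6)

    def test_deviance_explained_weakly_increases_with_true_term(self, rng):
        df = _panel_data(rng, ns=100, beta=0.0)
        df["y"] = df["y"] + 0.8 * df["prot"]
        base = GAM(df, "y", [RandomIntercept("sid")]).fit()
        richer = GAM(df, "y", [Smooth("prot"), RandomIntercept("sid")]).fit()
        assert richer.deviance_explained >= base.deviance_explained

    def test_matches_mgcv_oracle_on_fixture(self, tmp_path, rng):
        """Independent cross-check: same small dataset fitted by mgcv via
        Rscript gives closely matching predictions and smooth edf."""
        n = 250
        x = rng.uniform(-2, 2, n)
        z = rng.uniform(-2, 2, n)
        y = np.sin(x) + 0.3 * z**2 + rng.normal(0, 0.3, n)
        df = pd.DataFrame({"x": x, "z": z, "y": y})
        csv = tmp_path / "fixture.csv"
        df.to_csv(csv, index=False)
        rcode = textwrap.dedent(
            f"""
            suppressMessages(library(mgcv))
            d <- read.csv("{csv}")
            m <- gam(y ~ s(x, z, k=20), data=d, method="REML")
            cat(sum(m$edf[-1]), "\\n")
            write.csv(data.frame(fit=fitted(m)), "{tmp_path}/mgcv_fit.csv", row.names=FALSE)
            """
        )
        proc = subprocess.run(
            ["Rscript", "-e", rcode], capture_output=True, text=True, timeout=120
        )
        assert proc.returncode == 0, proc.stderr
        mgcv_edf = float(proc.stdout.strip().split()[-1])
        mgcv_fit = pd.read_csv(tmp_path / "mgcv_fit.csv")["fit"].to_numpy()
        res = GAM(df, "y", [Smooth(("x", "z"), k=20)]).fit()
        assert res.edf("s(x,z)") == pytest.approx(mgcv_edf, abs=1.5)
        r = np.corrcoef(res.fittedvalues, mgcv_fit)[0, 1]
        assert r > 0.99


@pytest.fixture(scope="module")
def fit():
    rng = np.random.default_rng(5)
    df = _panel_data(rng, ns=80, beta=0.4)
    model = GAM(df, "y", [Smooth(("prot", "carb", "lip")), RandomIntercept("sid")])
    return model.fit()


class TestPrediction:

    def test_training_row_prediction_equals_fitted_value(self, fit):
        rows = fit.model.data.head(10)
        pred = fit.predict(rows)  # includes the subject effect
        np.testing.assert_allclose(pred, fit.fittedvalues[:10], atol=1e-10)

    def test_standard_errors_strictly_positive(self, fit):
        grid = fit.model.data.head(50)
        _, se = fit.predict(grid, se=True)
        assert (se > 0).all()

    def test_se_lower_in_dense_centre_than_at_edges(self, fit):
        centre = pd.DataFrame(
            {"prot": np.linspace(-0.3, 0.3, 30), "carb": 0.0, "lip": 0.0}
        )
        edge = pd.DataFrame(
            {"prot": np.linspace(-2.4, -2.0, 15).tolist() + np.linspace(2.0, 2.4, 15).tolist(),
             "carb": 2.0, "lip": -2.0}
        )
        _, se_c = fit.predict(centre, se=True, include_random=False)
        _, se_e = fit.predict(edge, se=True, include_random=False)
        assert np.median(se_c) < np.median(se_e)

    def test_unknown_column_fails_loudly(self, fit):
        with pytest.raises(ValueError, match="lacks column"):
            fit.predict(pd.DataFrame({"prot": [0.0]}))


class TestModelSpecs:
    def test_model_1_composition(self):
        spec = build_model_spec(1, "z_dm_global")
        assert spec.smooth_triples == [("protein_kj", "carbohydrate_kj", "lipid_kj")]
        assert spec.covariates_numeric == () and spec.covariates_categorical == ()

    def test_model_4_adds_exactly_comorbidities_to_model_3(self):
        s3 = build_model_spec(3, "z_dm_global")
        s4 = build_model_spec(4, "z_dm_global")
        assert set(s4.covariates_numeric) - set(s3.covariates_numeric) == {
            "comorbidity_count"
        }
        assert s3.smooth_triples == s4.smooth_triples
        assert s3.covariates_categorical == s4.covariates_categorical

    def test_models_7_and_8_carry_two_smooth_triples(self):
        for mid in (7, 8):
            assert len(build_model_spec(mid, "z_dm_global").smooth_triples) == 2

    def test_screen_model_has_no_confounders(self):
        spec = build_model_spec("screen", "z_dm_global", micro_triple=("a", "b", "c"))
        assert spec.smooth_triples == [("a", "b", "c")]
        assert spec.covariates_numeric == ()

    def test_unknown_model_id_rejected(self):
        with pytest.raises(ValueError, match="model id"):
            build_model_spec(9, "z_dm_global")


class TestAicComparison:
    def _dummy_fit(self, aic, n=100, outcome="z", mid=1):
        fit = FitSummary.__new__(FitSummary)
        fit.spec = build_model_spec("screen", outcome, micro_triple=("a", "b", "c"))
        fit.spec.model_id = mid

        class _R:
            pass

        fit.results = _R()
        fit.results.aic = aic
        fit.results.deviance_explained = 1.0
        fit.results.nobs = n
        fit.results.converged = True
        return fit

    def test_identical_fits_tie_with_no_favourite(self):
        fits = [self._dummy_fit(100.0, mid=1), self._dummy_fit(100.0, mid=2)]
        table = compare_models_aic(fits)
        assert not table["favoured"].any()

    def test_margin_of_two_points_required(self):
        # AICs 5172 / 5179 / 5177: the first wins by > 2 over both others
        fits = [
            self._dummy_fit(5172.0, mid=4),
            self._dummy_fit(5179.0, mid=6),
            self._dummy_fit(5177.0, mid=8),
        ]
        table = compare_models_aic(fits)
        assert table.loc[0, "model"] == 4 and bool(table.loc[0, "favoured"])
        assert table["favoured"].sum() == 1

    def test_within_margin_reported_equivalent(self):
        fits = [self._dummy_fit(100.0, mid=1), self._dummy_fit(101.5, mid=2)]
        assert not compare_models_aic(fits)["favoured"].any()

    def test_differing_sample_sizes_rejected(self):
        fits = [self._dummy_fit(100.0, n=100), self._dummy_fit(90.0, n=90)]
        with pytest.raises(ValueError, match="sample sizes"):
            compare_models_aic(fits)

    def test_nested_models_with_planted_effect_prefer_larger(self, rng):
        df = _panel_data(rng, ns=120, beta=0.0)
        df["y"] = df["y"] + 1.0 * df["prot"]
        small = GAM(df, "y", [RandomIntercept("sid")]).fit()
        large = GAM(df, "y", [Smooth("prot"), RandomIntercept("sid")]).fit()
        assert large.aic < small.aic - 2


class TestFitGamWrapper:
    def test_minimum_sample_size_enforced(self, rng):
        df = _panel_data(rng, ns=5)
        df = df.rename(columns={"sid": "subject_id"})
        spec = build_model_spec("screen", "y", micro_triple=("prot", "carb", "lip"))
        with pytest.raises(ValueError, match="minimum"):
            fit_gam(spec, df, min_n=100)

    def test_predict_at_uses_population_profile(self, rng):
        df = _panel_data(rng, ns=100, beta=0.4)
        df = df.rename(columns={"sid": "subject_id"})
        spec = build_model_spec("screen", "y", micro_triple=("prot", "carb", "lip"))
        fit = fit_gam(spec, df)
        pred, se = predict_at(fit, {"prot": 0.0, "carb": 0.0, "lip": 0.0})
        assert np.isfinite(pred) and se > 0
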