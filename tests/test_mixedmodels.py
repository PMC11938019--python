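import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy.signal import lfilter

import dendro_isophys as di
from dendro_isophys import mixedmodels as mm


def simulate_lme(rng, n_groups=12, n_times=60, beta=(1.0, 0.5, -0.3),
                 sigma_b=0.7, sigma=1.0, rho=0.5):
    rows = []
    innov = sigma * np.sqrt(1.0 - rho**2)
    for g in range(n_groups):
        x1 = rng.normal(size=n_times)
        x2 = rng.normal(size=n_times)
        e = lfilter([1.0], [1.0, -rho], rng.normal(0, innov, n_times))
        y = beta[0] + beta[1] * x1 + beta[2] * x2 + rng.normal(0, sigma_b) + e
        rows.append(pd.DataFrame({"tree_id": g, "time": np.arange(n_times),
                                  "x1": x1, "x2": x2, "y": y}))
    return pd.concat(rows, ignore_index=True)


class TestBuildDesign:
    def test_interaction_and_zscoring(self, rng):
        d = pd.DataFrame({"tree_id": 1, "time": np.arange(50),
                          "y": rng.normal(size=50),
                          "ca": rng.normal(300, 20, 50),
                          "ndep": rng.normal(10, 3, 50)})
        spec = mm.ModelSpec("y", ("ca", "ndep"), ("ca:ndep",))
        X, y, g, t, stds = mm.build_design(d, spec)
        assert list(X.columns) == ["Intercept", "ca", "ndep", "ca:ndep"]
        for c in ("ca", "ndep"):
            assert abs(X[c].mean()) < 1e-10
            assert abs(X[c].std(ddof=1) - 1) < 1e-10
        assert np.allclose(X["ca:ndep"], X["ca"] * X["ndep"])

    def test_marginality_enforced(self):
        with pytest.raises(ValueError, match="marginality"):
            mm.ModelSpec("y", ("ndep",), ("ca:ndep",))

    def test_missing_values_rejected(self):
        d = pd.DataFrame({"tree_id": [1, 1], "time": [0, 1],
                          "y": [1.0, np.nan], "ca": [1.0, 2.0]})
        with pytest.raises(ValueError, match="missing values"):
            mm.build_design(d, mm.ModelSpec("y", ("ca",)))


class TestFitLmeAr1:
    def test_degenerate_reduction_to_ols(self, rng):
        d = simulate_lme(rng, sigma_b=0.0, rho=0.0)
        X = pd.DataFrame({"Intercept": 1.0, "x1": d.x1, "x2": d.x2})
        fit = mm.fit_lme_ar1(X, d.y, d.tree_id, d.time, fix_rho=0.0, fix_lambda=0.0)
        coef, *_ = np.linalg.lstsq(X.to_numpy(), d.y.to_numpy(), rcond=None)
        assert np.abs(fit.beta.to_numpy() - coef).max() < 1e-6

    def test_loglik_nesting(self, rng):
        d = simulate_lme(rng)
        X = pd.DataFrame({"Intercept": 1.0, "x1": d.x1, "x2": d.x2})
        full = mm.fit_lme_ar1(X, d.y, d.tree_id, d.time)
        null = mm.fit_lme_ar1(X, d.y, d.tree_id, d.time, fix_rho=0.0, fix_lambda=0.0)
        assert full.loglik >= null.loglik - 1e-8

    def test_parameter_recovery(self, rng):
        d = simulate_lme(rng, n_groups=30, n_times=100)
        X = pd.DataFrame({"Intercept": 1.0, "x1": d.x1, "x2": d.x2})
        fit = mm.fit_lme_ar1(X, d.y, d.tree_id, d.time)
        assert fit.beta["x1"] == pytest.approx(0.5, abs=3 * fit.se["x1"])
        assert fit.rho == pytest.approx(0.5, abs=0.1)
        assert fit.sigma == pytest.approx(1.0, abs=0.1)

    def test_single_group_gls_oracle(self, rng):
        # one group, no random intercept: directly coded AR(1) GLS
        n, rho, sigma = 50, 0.6, 1.0
        x = rng.normal(size=n)
        e = lfilter([1.0], [1.0, -rho], rng.normal(0, sigma, n))
        y = 1.0 + 0.8 * x + e
        X = pd.DataFrame({"Intercept": 1.0, "x": x})
        fit = mm.fit_lme_ar1(X, y, np.zeros(n), np.arange(n), fix_lambda=0.0)
        lags = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
        R = fit.rho ** lags
        Ri = np.linalg.inv(R)
        Xm = X.to_numpy()
        beta_gls = np.linalg.solve(Xm.T @ Ri @ Xm, Xm.T @ Ri @ y)
        assert np.abs(fit.beta.to_numpy() - beta_gls).max() < 1e-6

    def test_nlme_cross_check(self, tmp_path, rng):
        # independent oracle: R nlme::lme with corAR1, ML, on a small dataset
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript not available for the nlme cross-check")
        d = simulate_lme(rng, n_groups=6, n_times=25)
        csv = tmp_path / "d.csv"
        d.to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(f"""
            suppressMessages(library(nlme))
            d <- read.csv("{csv}")
            m <- lme(y ~ x1 + x2, random = ~1 | tree_id,
                     correlation = corAR1(form = ~ time | tree_id),
                     data = d, method = "ML")
            cat(fixef(m), sqrt(diag(vcov(m))),
                coef(m$modelStruct$corStruct, unconstrained = FALSE),
                m$sigma, as.numeric(logLik(m)), sep = "\\n")
        """)
        out = subprocess.run(["Rscript", str(script)], capture_output=True,
                             text=True, timeout=300)
        assert out.returncode == 0, out.stderr
        vals = [float(v) for v in out.stdout.split()]
        r_beta, r_se, r_rho, r_sigma, r_ll = vals[:3], vals[3:6], vals[6], vals[7], vals[8]
        X = pd.DataFrame({"Intercept": 1.0, "x1": d.x1, "x2": d.x2})
        fit = mm.fit_lme_ar1(X, d.y, d.tree_id, d.time)
        assert np.abs(fit.beta.to_numpy() - r_beta).max() < 1e-3
        assert np.abs(fit.se.to_numpy() - r_se).max() < 2e-3
        assert fit.rho == pytest.approx(r_rho, abs=1e-3)
        assert fit.sigma == pytest.approx(r_sigma, rel=1e-3)
        assert fit.loglik == pytest.approx(r_ll, abs=1e-4)


class TestAICc:
    def test_hand_value(self):
        assert mm.aicc(-5.0, k=3, n=10) == pytest.approx(20.0)

    def test_limits_to_aic(self):
        assert mm.aicc(-5.0, k=3, n=10**7) == pytest.approx(16.0, abs=1e-4)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            mm.aicc(-5.0, k=3, n=4)

    def test_penalty_monotone_in_k(self):
        assert mm.aicc(-5.0, k=4, n=20) > mm.aicc(-5.0, k=3, n=20)


class TestAllSubsets:
    def test_small_enumeration(self):
        spec = mm.ModelSpec("y", ("ca", "ndep"), ("ca:ndep",))
        subs = mm.all_subsets(spec)
        assert len(subs) == 5
        terms = {s.terms for s in subs}
        assert ("ca", "ndep", "ca:ndep") in terms
        assert () in terms

    def test_marginality_never_violated(self):
        spec = mm.ModelSpec("y", ("cambial_age", "ca", "ndep", "ph"),
                            ("ca:ndep", "ca:cambial_age"))
        for s in mm.all_subsets(spec):
            for ia in s.interactions:
                assert "ca" in s.mains and ia.split(":")[1] in s.mains

    def test_full_paper_spec_count_matches_enumeration_oracle(self):
        import itertools
        mains = ("cambial_age", "ca", "ndep", "ph", "spi_jun_aug", "t_apr_aug")
        inters = ("ca:cambial_age", "ca:ndep", "ca:ph", "ca:spi_jun_aug",
                  "ca:t_apr_aug")
        count = 0
        for r in range(7):
            for msub in itertools.combinations(mains, r):
                ok = [i for i in inters if "ca" in msub and i.split(":")[1] in msub]
                count += 2 ** len(ok)
        spec = mm.ModelSpec("y", mains, inters)
        assert len(mm.all_subsets(spec)) == count

    def test_cap_guard(self):
        spec = mm.ModelSpec("y", ("ca", "ndep"), ("ca:ndep",))
        with pytest.raises(ValueError, match="cap"):
            mm.all_subsets(spec, max_models=2)


class TestModelAverage:
    def _fake_fit(self, terms, beta, se, loglik, n=100):
        idx = ["Intercept", *terms]
        return mm.LMEFit(beta=pd.Series(beta, index=idx),
                         se=pd.Series(se, index=idx),
                         cov_beta=np.diag(np.square(se)), sigma_b=0.5, sigma=1.0,
                         rho=0.0, loglik=loglik, n=n, k=len(idx) + 3,
                         converged=True,
                         spec=mm.ModelSpec("y", tuple(terms)),
                         X_columns=tuple(idx),
                         fitted_fixed=np.zeros(n))

    def test_single_model_identity(self):
        f = self._fake_fit(["x"], [1.0, 2.0], [0.1, 0.2], -50.0)
        avg = mm.model_average([f])
        assert avg.table.loc["x", "estimate"] == pytest.approx(2.0)
        assert avg.table.loc["x", "se"] == pytest.approx(0.2)

    def test_opposite_estimates_average_to_zero_with_inflated_se(self):
        f1 = self._fake_fit(["x"], [0.0, 1.0], [0.1, 0.2], -50.0)
        f2 = self._fake_fit(["x"], [0.0, -1.0], [0.1, 0.2], -50.0)
        avg = mm.model_average([f1, f2])
        assert avg.table.loc["x", "estimate"] == pytest.approx(0.0)
        assert avg.table.loc["x", "se"] == pytest.approx(np.sqrt(0.2**2 + 1.0))

    def test_weights_sum_to_one(self):
        fits = [self._fake_fit(["x"], [0, 1], [0.1, 0.2], ll)
                for ll in (-50.0, -50.4, -60.0)]
        avg = mm.model_average(fits)
        assert avg.models.loc[avg.models.retained, "weight"].sum() == pytest.approx(1.0)

    def test_term_in_single_retained_model(self):
        f1 = self._fake_fit(["x"], [0, 1.0], [0.1, 0.2], -50.0)
        f2 = self._fake_fit(["x", "z"], [0, 1.1, 0.7], [0.1, 0.2, 0.3], -49.0)
        avg = mm.model_average([f1, f2])
        assert avg.table.loc["z", "estimate"] == pytest.approx(0.7)
        assert avg.table.loc["z", "n_models"] == 1


class TestR2AndVIF:
    def test_r2_trivial_cases(self):
        f = TestModelAverage()._fake_fit(["x"], [0.0, 0.0], [0.1, 0.1], -10.0)
        f.fitted_fixed = np.zeros(100)
        marg, cond = mm.r2_nakagawa(f)
        assert marg == 0.0
        assert cond == pytest.approx(0.5**2 / (0.5**2 + 1.0))
        f.sigma_b = 0.0
        marg, cond = mm.r2_nakagawa(f)
        assert marg == cond

    def test_r2_simulation_oracle(self, rng):
        # known variance components at large n: plug-in truth within 0.05
        d = simulate_lme(rng, n_groups=30, n_times=100, sigma_b=0.7,
                         sigma=1.0, rho=0.0)
        X = pd.DataFrame({"Intercept": 1.0, "x1": d.x1, "x2": d.x2})
        fit = mm.fit_lme_ar1(X, d.y, d.tree_id, d.time)
        var_f = 0.5**2 + 0.3**2
        truth_marg = var_f / (var_f + 0.7**2 + 1.0)
        truth_cond = (var_f + 0.7**2) / (var_f + 0.7**2 + 1.0)
        marg, cond = mm.r2_nakagawa(fit)
        assert marg == pytest.approx(truth_marg, abs=0.05)
        assert cond == pytest.approx(truth_cond, abs=0.05)

    def test_vif_hand_values(self):
        n = 400
        u = np.tile([1.0, -1.0], n // 2)
        v = np.tile([1.0, 1.0, -1.0, -1.0], n // 4)
        x2 = 0.9 * u + np.sqrt(1 - 0.81) * v       # empirical corr exactly 0.9
        X = pd.DataFrame({"a": u, "b": x2})
        out = mm.vif(X)
        assert out.loc["a", "vif"] == pytest.approx(1 / (1 - 0.81), rel=1e-9)
        assert bool(out.loc["a", "high_collinearity"])

    def test_vif_orthogonal_and_duplicate(self):
        n = 100
        rng = np.random.default_rng(0)
        a = np.tile([1.0, -1.0], n // 2)
        b = np.tile([1.0, 1.0, -1.0, -1.0], n // 4)
        out = mm.vif(pd.DataFrame({"a": a, "b": b}))
        assert out["vif"].tolist() == pytest.approx([1.0, 1.0])
        out2 = mm.vif(pd.DataFrame({"a": a, "b": a.copy(), "c": rng.normal(size=n)}))
        assert np.isinf(out2.loc["a", "vif"])


class TestPCA:
    def test_perfectly_correlated_pair(self, rng):
        x = rng.normal(size=200)
        res = mm.pca_summary(pd.DataFrame({"a": x, "b": 2 * x + 1}))
        assert res.explained.iloc[0] == pytest.approx(1.0)

    def test_orthonormal_loadings_and_fractions(self, rng):
        df = pd.DataFrame(rng.normal(size=(200, 4)), columns=list("abcd"))
        res = mm.pca_summary(df)
        L = res.loadings.to_numpy()
        assert np.allclose(L.T @ L, np.eye(4), atol=1e-10)
        assert res.explained.sum() == pytest.approx(1.0)
        # deterministic sign: leading variable loads positively
        for j in range(4):
            assert L[np.argmax(np.abs(L[:, j])), j] > 0


class TestBasisConversion:
    def test_round_trip_and_cross_basis(self, rng):
        from dendro_isophys.environment import Standardizer
        coefs = {"Intercept": 5.0, "ca": 2.0, "ndep": -1.0, "cellulose": 3.0,
                 "ca:ndep": 0.7}
        stds_a = {"ca": Standardizer(300.0, 30.0), "ndep": Standardizer(8.0, 5.0)}
        stds_b = {"ca": Standardizer(310.0, 25.0), "ndep": Standardizer(9.0, 6.0)}
        raw = mm.zcoefs_to_raw(coefs, stds_a)
        back = mm.raw_to_zcoefs(raw, stds_a)
        for k, v in coefs.items():
            assert back[k] == pytest.approx(v, rel=1e-12)
        # cross-basis conversion preserves predictions on raw inputs
        zb = mm.raw_to_zcoefs(raw, stds_b)
        x_ca, x_nd, cel = 350.0, 12.0, 1.0
        def predict(c, stds):
            za = (x_ca - stds["ca"].mean) / stds["ca"].sd
            zn = (x_nd - stds["ndep"].mean) / stds["ndep"].sd
            return (c["Intercept"] + c["ca"] * za + c["ndep"] * zn
                    + c["cellulose"] * cel + c["ca:ndep"] * za * zn)
        assert predict(zb, stds_b) == pytest.approx(predict(coefs, stds_a), rel=1e-12)
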