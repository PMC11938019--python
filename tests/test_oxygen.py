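import numpy as np
import pandas as pd
import pytest

import dendro_isophys as di
from dendro_isophys import oxygen as ox


class TestScalarFormulas:
    def test_delta18o_tr_hand_values(self):
        assert di.delta18o_tr(30.0, 0.0) == pytest.approx(30.0)
        assert di.delta18o_tr(30.0, -10.0) == pytest.approx(40.0 / 0.99, rel=1e-12)
        assert di.delta18o_tr(-10.0, -10.0) == pytest.approx(0.0)

    def test_pex_hand_values(self):
        assert di.pex_from_vpd(0.0) == pytest.approx(0.13)
        assert di.pex_from_vpd(1.0) == pytest.approx(0.49)
        assert di.pex_from_vpd(0.6) == pytest.approx(0.346)

    def test_pex_clipped_and_logged(self):
        assert di.pex_from_vpd(5.0) == 0.95

    def test_delta18o_lw_hand_values(self):
        p = ox.OxygenParams(px=1.0)
        tr = 40.0 / 0.99
        assert di.delta18o_lw(tr, 27.0, 0.49, p) == pytest.approx(
            (tr - 27.0) / 0.51, rel=1e-12)
        assert di.delta18o_lw(30.0, 27.0, 0.0, p) == pytest.approx(3.0)
        assert di.delta18o_lw(27.0, 27.0, 0.49, p) == pytest.approx(0.0)

    def test_delta18o_lw_monotonicity(self):
        up = di.delta18o_lw(np.array([20.0, 21.0]), 27.0, 0.3)
        assert up[1] > up[0]
        assert di.delta18o_lw(30.0, 28.0, 0.3) < di.delta18o_lw(30.0, 27.0, 0.3)

    def test_invalid_exchange_fraction(self):
        with pytest.raises(ValueError):
            di.delta18o_lw(30.0, 27.0, 1.0)


class TestEpsilonWC:
    def test_constant_mode(self):
        assert di.epsilon_wc(5.0) == 27.0
        assert di.epsilon_wc(35.0) == 27.0

    def test_quadratic_matches_polynomial(self):
        p = ox.OxygenParams(ewc_model="quadratic")
        c2, c1, c0 = ox.EWC_QUAD
        for t in (0.0, 12.5, 20.0, 30.0):
            assert di.epsilon_wc(t, p) == pytest.approx(c2 * t**2 + c1 * t + c0)
        # anchored near 27 permil at ~20 degC
        assert di.epsilon_wc(20.0, p) == pytest.approx(27.0, abs=0.5)

    def test_quadratic_decreasing_5_to_30(self):
        p = ox.OxygenParams(ewc_model="quadratic")
        t = np.linspace(5, 30, 100)
        assert np.all(np.diff(di.epsilon_wc(t, p)) < 0)


class TestD18OpModel:
    def test_noiseless_recovery(self, env_default):
        t = env_default["t_annual"].to_numpy()[:70]
        s = env_default["spi_annual"].to_numpy()[:70]
        y = -12.0 + 0.35 * t - 0.2 * s
        m = di.fit_d18op_model(y, t, s)
        assert m.intercept == pytest.approx(-12.0, abs=1e-8)
        assert m.t_coef == pytest.approx(0.35, abs=1e-8)
        assert m.spi_coef == pytest.approx(-0.2, abs=1e-8)

    def test_noisy_recovery_within_2se(self, rng):
        n = 300
        t = rng.normal(6, 1, n)
        s = rng.normal(0, 1, n)
        y = -12.0 + 0.35 * t - 0.2 * s + rng.normal(0, 0.3, n)
        m = di.fit_d18op_model(y, t, s)
        se_t = 0.3 / np.sqrt(n) / np.std(t)
        assert abs(m.t_coef - 0.35) < 3 * se_t
        assert 0 < m.r <= 1

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValueError, match="rank"):
            di.fit_d18op_model(np.arange(20.0), np.ones(20), np.arange(20.0))

    def test_hindcast_flags_and_values(self, env_default):
        m = ox.D18OpModel(-12.0, 0.35, -0.2, 0.8, 70)
        out = di.hindcast_d18op(m, env_default, (1950, 2020))
        out = out.set_index("year")
        assert out.loc[1960, "source"] == "observed"
        assert out.loc[1600, "source"] == "hindcast"
        env = env_default.set_index("year")
        expected = -12.0 + 0.35 * env.loc[1600, "t_annual"] - 0.2 * env.loc[1600, "spi_annual"]
        assert out.loc[1600, "d18o_p"] == pytest.approx(expected)
        assert out.loc[1960, "d18o_p"] == env.loc[1960, "d18o_p"]


class TestLeafwaterSeries:
    def _iso(self, year=1990, d18o=30.0):
        return pd.DataFrame({"tree_id": ["T1"], "species": ["spruce"],
                             "year_start": [year], "year_end": [year],
                             "material": ["cellulose"], "d18o": [d18o]})

    def test_chain_equals_scalar_composition(self, env_default):
        iso = self._iso()
        m = di.fit_d18op_model(env_default["d18o_p"][:71],
                               env_default["t_annual"][:71],
                               env_default["spi_annual"][:71])
        d18op = di.hindcast_d18op(m, env_default, (1950, 2020))
        out = di.leafwater_series(iso, env_default, d18op)
        dp = d18op.set_index("year").loc[1990, "d18o_p"]
        tr = di.delta18o_tr(30.0, dp)
        pex = di.pex_from_vpd(float(env_default["vpd"].mean()))
        assert out.loc[0, "big_delta_18o_lw"] == pytest.approx(
            di.delta18o_lw(tr, 27.0, pex), rel=1e-12)

    def test_wood_rows_rejected(self, env_default, tiny_iso):
        d18op = pd.DataFrame({"year": env_default["year"], "d18o_p": -10.0,
                              "source": "observed"})
        with pytest.raises(ValueError, match="cellulose only"):
            di.leafwater_series(tiny_iso, env_default, d18op)

    def test_prescribed_trajectory_recovered_exactly(self, env_default):
        # invert the chain from a known leaf-water series, then recover it
        years = np.arange(1950, 2000)
        target = 23.0 + 0.01 * (years - 1950)
        env = env_default.set_index("year")
        pex = di.pex_from_vpd(float(env_default["vpd"].mean()))
        dp = env["d18o_p"].loc[years].to_numpy()
        tr = target * (1 - pex) + 27.0
        cell = tr * (1 + dp / 1000.0) + dp
        iso = pd.DataFrame({"tree_id": "T1", "species": "spruce",
                            "year_start": years, "year_end": years,
                            "material": "cellulose", "d18o": cell})
        d18op = pd.DataFrame({"year": env_default["year"],
                              "d18o_p": env_default["d18o_p"], "source": "observed"})
        out = di.leafwater_series(iso, env_default, d18op)
        assert np.abs(out["big_delta_18o_lw"].to_numpy() - target).max() < 1e-9

    def test_cellulose_lw_correlation_with_constant_source(self, env_default):
        # constant source water makes the map affine, correlation exactly 1
        years = np.arange(1950, 2000)
        cell = 30.0 + np.sin(np.arange(50))
        iso = pd.DataFrame({"tree_id": "T1", "species": "spruce",
                            "year_start": years, "year_end": years,
                            "material": "cellulose", "d18o": cell})
        d18op = pd.DataFrame({"year": env_default["year"], "d18o_p": -10.0,
                              "source": "observed"})
        out = di.leafwater_series(iso, env_default, d18op)
        r = np.corrcoef(cell, out["big_delta_18o_lw"])[0, 1]
        assert r == pytest.approx(1.0, abs=1e-12)
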