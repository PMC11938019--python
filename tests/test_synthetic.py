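import numpy as np
import pandas as pd
import pytest

import dendro_isophys as di
from dendro_isophys import synthetic as syn


class TestRoster:
    def test_reproducible_and_sized(self):
        a = di.generate_trees(10, seed=1)
        b = di.generate_trees(10, seed=1)
        pd.testing.assert_frame_equal(a, b)
        assert (a.groupby("species").size() == 10).all()

    def test_zero_width_recruitment(self):
        r = di.generate_trees(5, recruitment=(1600, 1600), seed=0)
        assert (r["recruit_year"] == 1600).all()

    def test_different_seeds_differ(self):
        a = di.generate_trees(10, seed=1)
        b = di.generate_trees(10, seed=2)
        assert not a["recruit_year"].equals(b["recruit_year"])


class TestGenerateResponses:
    def test_flat_when_no_effects(self, env_default):
        truth = syn._null_truth()
        for k, rt in truth.responses.items():
            truth.responses[k] = syn.ResponseTruth(rt.intercept, {}, 0.0, 0.0, 0.0)
        roster = di.generate_trees({"beech": 3}, species=("beech",), seed=0)
        lat = di.generate_responses(roster, env_default, truth, seed=0)
        assert lat["iwue"].nunique() == 1

    def test_single_driver_correlation(self, env_default):
        truth = syn._paper_like_truth()
        truth.responses[("beech", "iwue")] = syn.ResponseTruth(
            40.0, {"ndep": 5.0}, 0.0, 1e-6, 0.0)
        roster = di.generate_trees({"beech": 3}, species=("beech",), seed=0)
        lat = di.generate_responses(roster, env_default, truth, seed=0)
        env_idx = env_default.set_index("year")
        nd = env_idx["ndep"].loc[lat["year"]].to_numpy()
        assert np.corrcoef(lat["iwue"], nd)[0, 1] > 0.99

    def test_ar1_noise_autocorrelation(self, env_default):
        truth = syn._null_truth()
        key = ("beech", "iwue")
        truth.responses[key] = syn.ResponseTruth(50.0, {}, 0.0, 1.0, 0.7)
        roster = di.generate_trees({"beech": 2}, species=("beech",),
                                   recruitment=(1440, 1460), seed=0)
        lat = di.generate_responses(roster, env_default, truth, seed=0)
        one = lat[lat.tree_id == lat.tree_id.iloc[0]]["iwue"].to_numpy() - 50.0
        acf1 = np.corrcoef(one[1:], one[:-1])[0, 1]
        assert acf1 == pytest.approx(0.7, abs=0.05)


class TestObservables:
    def test_annual_cellulose_iwue_recovered_exactly(self, paper_scenario):
        sc = paper_scenario
        truth = sc.truth
        roster = sc.roster[sc.roster.material == "cellulose"]
        lat = di.generate_responses(sc.roster, sc.env, truth, seed=sc.seed)
        iso, _ = di.latents_to_observables(lat, sc.env, truth, seed=sc.seed,
                                           measurement_noise=False)
        cell = iso[iso.material == "cellulose"]
        physio = di.iwue_series(cell, sc.env, method="photoresp")
        lat_cell = lat[lat.tree_id.isin(roster.tree_id)]
        merged = physio.merge(lat_cell, left_on=["tree_id", "year_start"],
                              right_on=["tree_id", "year"], suffixes=("_rec", "_true"))
        assert np.abs(merged["iwue_rec"] - merged["iwue_true"]).max() < 1e-9

    def test_pooled_segment_bias_below_half_percent(self, paper_scenario):
        sc = paper_scenario
        lat = di.generate_responses(sc.roster, sc.env, sc.truth, seed=sc.seed)
        iso, _ = di.latents_to_observables(lat, sc.env, sc.truth, seed=sc.seed,
                                           measurement_noise=False)
        wood = iso[(iso.material == "wood") & (iso.species == "beech")]
        physio = di.iwue_series(wood, sc.env, method="photoresp")
        lat_idx = lat.set_index(["tree_id", "year"])["iwue"]
        rel = []
        for _, row in physio.iterrows():
            truth_mean = np.mean([lat_idx.loc[(row.tree_id, y)]
                                  for y in range(int(row.year_start),
                                                 int(row.year_end) + 1)])
            rel.append(abs(row.iwue - truth_mean) / truth_mean)
        assert max(rel) < 0.005

    def test_bai_round_trip_exact(self, paper_scenario):
        sc = paper_scenario
        lat = di.generate_responses(sc.roster, sc.env, sc.truth, seed=sc.seed)
        _, rings = di.latents_to_observables(lat, sc.env, sc.truth, seed=sc.seed)
        tid = rings.tree_id.iloc[0]
        out = di.bai(rings[rings.tree_id == tid])
        truth_bai = np.exp(lat[lat.tree_id == tid].sort_values("year")["bai_ln"])
        assert np.abs(out["bai"].to_numpy() - truth_bai.to_numpy()).max() < 1e-9

    def test_infeasible_latent_rejected(self, env_default):
        truth = syn._null_truth()
        truth.responses[("beech", "iwue")] = syn.ResponseTruth(500.0, {}, 0, 0, 0)
        roster = di.generate_trees({"beech": 2}, species=("beech",), seed=0)
        lat = di.generate_responses(roster, env_default, truth, seed=0)
        with pytest.raises(ValueError, match="infeasible"):
            di.latents_to_observables(lat, env_default, truth, seed=0)


class TestScenarios:
    def test_reproducible(self):
        a = di.make_scenario("paper_like", seed=4)
        b = di.make_scenario("paper_like", seed=4)
        pd.testing.assert_frame_equal(a.isotopes, b.isotopes)
        pd.testing.assert_frame_equal(a.rings, b.rings)

    def test_no_truth_leakage(self, paper_scenario):
        # latent quantities must not appear in the observables (δ13C/δ15N/δ18O
        # and ring widths are the measurements)
        leaky = {"iwue", "bai_ln", "big_delta_18o_lw", "latent", "recruit_year"}
        assert not leaky & set(paper_scenario.isotopes.columns)
        assert not leaky & set(paper_scenario.rings.columns)

    def test_unknown_name_rejected(self):
        with pytest.raises(ValueError, match="unknown scenario"):
            di.make_scenario("bogus", seed=0)

    def test_two_break_power(self):
        # strong prescribed slope changes: two breakpoints found, near truth
        hits = 0
        for seed in range(5):
            sc = di.make_scenario("two_break", seed=seed)
            res = di.analyze(sc.env, sc.isotopes, sc.rings,
                             options=di.AnalysisOptions(),
                             stages=("physiology", "growth", "breakpoints"))
            f = res["breakpoints"][("spruce", "iwue_cellulose")]
            truth_psi = sc.truth.implied_breakpoints[("spruce", "iwue_cellulose")]["psi"]
            if f.n_breakpoints == 2 and np.allclose(f.psi, truth_psi, atol=10):
                hits += 1
        assert hits >= 4

    def test_null_scenario_flat_chronology(self):
        sc = di.make_scenario("null", seed=3)
        res = di.analyze(sc.env, sc.isotopes, sc.rings,
                         options=di.AnalysisOptions(),
                         stages=("physiology", "growth", "breakpoints"))
        c = res["chronologies"][("spruce", "iwue_cellulose")]
        cw = c[(c.year >= 1818) & (c.year <= 2020)]
        slope = np.polyfit(cw["year"], cw["mean"], 1)[0]
        assert abs(slope) < 0.02  # no systematic drift without effects
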