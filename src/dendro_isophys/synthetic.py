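"""Synthetic multi-species tree-ring datasets with known ground truth.

The generator emulates the structure of a Central-European old-growth
isotope study: 8-12 of the oldest trees per species (European beech, Norway
spruce, silver fir) recruited between 1430 and 1700, ring widths measured
annually, bulk-wood δ13C/δ15N pooled into tree-anchored 5-year segments,
and annual α-cellulose δ13C/δ18O for a subset of spruce trees.  Responses
are built from the same linear-predictor structure the attribution models
assume — Z-scored drivers with CO2 interactions, per-tree random
intercepts, AR(1) process noise — and pushed through the *inverse* of the
physiology chain so that running the forward pipeline on the observables
recovers the prescribed quantities.

Ground truth (coefficients in the generator's Z basis together with the
standardizers defining that basis, variance components, the prescribed
leaf-water enrichment trajectory and the candidate model space) is returned
in a :class:`TruthRecord`; the observable tables carry no truth columns.

Scenarios
---------
``paper_like``
    All three species, driver-driven trends in iWUE/δ15N/BAI_ln matching
    the magnitudes the attribution literature reports, and a leaf-water
    enrichment chronology prescribed as a broken line (rise of 0.007
    permil/yr to a breakpoint at 1877, then −0.003 permil/yr).
``null``
    Same layout with all driver effects zero — flat responses, noise only —
    for false-positive-rate studies.
``two_break``
    Spruce cellulose only, iWUE prescribed as a two-breakpoint broken line
    (accelerating in 1936, decelerating in 1983) for power studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import carbon as cb
from . import oxygen as ox
from .environment import EnvParams, Standardizer, synth_environment

SPECIES = ("beech", "spruce", "fir")
ANALYSIS_WINDOW = (1501, 2020)
POOL_YEARS = 5

#: measurement SDs (permil), per isotope and material
MEAS_SD = {("d13c", "cellulose"): 0.06, ("d13c", "wood"): 0.07,
           ("d18o", "cellulose"): 0.17, ("d15n", "wood"): 0.11}

#: candidate model space searched by the recovery studies, per response
CANDIDATE_MAINS = ("cambial_age", "ca", "ndep", "ph")
CANDIDATE_INTERACTIONS = {
    "iwue": ("ca:ndep",),
    "d15n": ("ca:ndep",),
    "bai_ln": ("ca:cambial_age", "ca:ndep"),
}


@dataclass
class ResponseTruth:
    """One species' true linear predictor for one response (Z-basis)."""

    intercept: float
    coefs: dict                      # term -> beta in the generator's Z units
    sigma_b: float
    sigma: float
    rho: float


@dataclass
class TruthRecord:
    """Everything the recovery tests need and the observables must not leak."""

    responses: dict                  # (species, response) -> ResponseTruth
    standardizers: dict              # (species, response) -> {main: Standardizer}
    d18o_lw_knots: tuple             # prescribed leaf-water trajectory, (year, permil)
    d18o_lw_noise: tuple             # (sigma_b, sigma, rho)
    candidate_mains: tuple
    candidate_interactions: dict
    pooling: str = "tree_anchored"
    implied_breakpoints: dict = field(default_factory=dict)


@dataclass
class Scenario:
    name: str
    seed: int
    env: pd.DataFrame
    roster: pd.DataFrame
    isotopes: pd.DataFrame
    rings: pd.DataFrame
    truth: TruthRecord


def _rng(seed: int, stream: int) -> np.random.Generator:
    """Counter-based fan-out so module draws are independent per stream."""
    return np.random.default_rng([int(seed) % (2**31), int(stream)])


def generate_trees(n_per_species, species=SPECIES,
                   recruitment: tuple[int, int] = (1430, 1700),
                   seed: int = 0) -> pd.DataFrame:
    """Tree roster with staggered recruitment years.

    ``n_per_species`` is an int or a ``{species: n}`` mapping; recruitment
    years are drawn uniformly on the window (width 0 pins all trees to the
    same age).
    """
    if isinstance(n_per_species, int):
        n_per_species = {sp: n_per_species for sp in species}
    rng = _rng(seed, 10)
    rows = []
    for sp in species:
        n = int(n_per_species[sp])
        if n < 2:
            raise ValueError("need >= 2 trees per species")
        years = rng.integers(recruitment[0], recruitment[1] + 1, size=n)
        for i, ry in enumerate(sorted(years)):
            rows.append({"tree_id": f"{sp[:3].upper()}{i + 1:02d}", "species": sp,
                         "recruit_year": int(ry), "material": "wood"})
    return pd.DataFrame(rows)


def _piecewise(years, knots):
    ky = np.array([k[0] for k in knots], dtype=float)
    kv = np.array([k[1] for k in knots], dtype=float)
    return np.interp(np.asarray(years, dtype=float), ky, kv)


def _ar1(rng, n, rho, sigma):
    """AR(1) noise with *stationary* SD ``sigma`` (the nlme convention)."""
    if rho == 0.0:
        return rng.normal(0.0, sigma, size=n)
    e = rng.normal(0.0, sigma * np.sqrt(1.0 - rho**2), size=n)
    out = np.empty(n)
    out[0] = e[0] / np.sqrt(1.0 - rho**2)
    for i in range(1, n):
        out[i] = rho * out[i - 1] + e[i]
    return out


def _paper_like_truth() -> TruthRecord:
    r = {
        ("beech", "iwue"): ResponseTruth(37.0, {"cambial_age": 4.0, "ca": 2.5,
                                                "ndep": 5.0, "ca:ndep": -2.0}, 3.0, 3.5, 0.5),
        ("spruce", "iwue"): ResponseTruth(50.0, {"cellulose": 9.5, "cambial_age": 4.0,
                                                 "ca": 9.0, "ndep": 5.0, "ca:ndep": 2.0},
                                          3.5, 4.5, 0.5),
        ("fir", "iwue"): ResponseTruth(47.0, {"cambial_age": 6.5, "ca": 5.0,
                                              "ndep": 6.0}, 3.0, 4.5, 0.5),
        ("beech", "d15n"): ResponseTruth(-2.0, {"cambial_age": -0.5, "ca": -0.4,
                                                "ndep": -0.4, "ca:ndep": 0.35},
                                         1.0, 1.2, 0.4),
        ("spruce", "d15n"): ResponseTruth(-4.5, {"cambial_age": -1.2, "ndep": 0.6},
                                          1.0, 1.2, 0.4),
        ("fir", "d15n"): ResponseTruth(-4.2, {"cambial_age": -0.7, "ca": 0.0,
                                              "ndep": 0.2, "ca:ndep": -0.6},
                                       1.0, 1.2, 0.4),
        ("beech", "bai_ln"): ResponseTruth(6.4, {"cambial_age": 1.3, "ca": 0.4,
                                                 "ca:cambial_age": -0.5}, 0.4, 1.0, 0.5),
        ("spruce", "bai_ln"): ResponseTruth(6.7, {"cambial_age": 1.5, "ca": 0.3,
                                                  "ndep": 0.3, "ca:cambial_age": -0.5},
                                            0.4, 1.0, 0.5),
        ("fir", "bai_ln"): ResponseTruth(6.8, {"cambial_age": 1.5, "ca": 0.4,
                                               "ndep": -0.3, "ca:cambial_age": -0.5},
                                         0.4, 1.0, 0.5),
    }
    return TruthRecord(
        responses=r, standardizers={},
        d18o_lw_knots=((1501.0, 21.40), (1877.0, 24.03), (2020.0, 23.60)),
        d18o_lw_noise=(0.3, 0.15, 0.3),
        candidate_mains=CANDIDATE_MAINS,
        candidate_interactions=dict(CANDIDATE_INTERACTIONS),
    )


def _null_truth() -> TruthRecord:
    t = _paper_like_truth()
    for key, rt in t.responses.items():
        keep = {"cellulose": rt.coefs["cellulose"]} if "cellulose" in rt.coefs else {}
        t.responses[key] = ResponseTruth(rt.intercept, keep, rt.sigma_b, rt.sigma, rt.rho)
    t.d18o_lw_knots = ((1501.0, 23.0), (2020.0, 23.0))
    return t


def generate_responses(roster: pd.DataFrame, env: pd.DataFrame,
                       truth: TruthRecord, seed: int = 0) -> pd.DataFrame:
    """Annual latent iwue/d15n/bai_ln per tree.

    The linear predictor uses Z-scored drivers; the Z basis of each
    (species, response) is computed over that species' pooled tree-year rows
    (wood trees only for d15n) and stored in ``truth.standardizers``.
    Per-tree random intercepts and AR(1) noise are drawn per response with
    that response's variance components.
    """
    env_idx = env.set_index("year")
    lo, hi = int(env["year"].iloc[0]), int(env["year"].iloc[-1])
    rows = []
    for _, tr in roster.iterrows():
        start = max(int(tr.recruit_year), lo)
        years = np.arange(start, hi + 1)
        rows.append(pd.DataFrame({
            "tree_id": tr.tree_id, "species": tr.species, "material": tr.material,
            "year": years,
            "cambial_age": years - int(tr.recruit_year) + 1,
        }))
    base = pd.concat(rows, ignore_index=True)
    for c in ("ca", "ndep", "ph", "t_apr_aug", "spi_jun_aug"):
        base[c] = env_idx[c].loc[base["year"]].to_numpy()
    base["cellulose"] = (base["material"] == "cellulose").astype(float)

    out = base[["tree_id", "species", "material", "year", "cambial_age"]].copy()
    rng_b = _rng(seed, 20)
    rng_e = _rng(seed, 21)
    for resp_i, resp in enumerate(("iwue", "d15n", "bai_ln")):
        vals = np.full(len(base), np.nan)
        for sp in roster["species"].unique():
            key = (sp, resp)
            if key not in truth.responses:
                continue
            rt = truth.responses[key]
            mask = (base["species"] == sp).to_numpy()
            if resp == "d15n":
                mask &= (base["material"] == "wood").to_numpy()
            if not mask.any():
                continue
            # δ15N and BAI_ln are modelled at wood-segment resolution, so
            # their Z basis is the wood trees' rows
            basis_mask = mask.copy()
            if resp == "bai_ln":
                wood = mask & (base["material"] == "wood").to_numpy()
                if wood.any():
                    basis_mask = wood
            sub = base[mask]
            basis = base[basis_mask]
            zcols, stds = {}, {}
            for m in set(list(rt.coefs) + list(truth.candidate_mains)):
                m0 = m.split(":", 1)[1] if ":" in m else m
                for name in ({"ca", m0} if ":" in m else {m0}):
                    if name in zcols or name == "cellulose":
                        continue
                    v0 = basis[name].to_numpy(dtype=float)
                    st = Standardizer(float(np.mean(v0)), float(np.std(v0, ddof=1)))
                    stds[name] = st
                    zcols[name] = st.transform(sub[name].to_numpy(dtype=float))
            zcols["cellulose"] = sub["cellulose"].to_numpy()
            truth.standardizers[key] = stds
            lin = np.full(len(sub), rt.intercept)
            for term, beta in rt.coefs.items():
                if ":" in term:
                    a, b = term.split(":", 1)
                    lin = lin + beta * zcols[a] * zcols[b]
                else:
                    lin = lin + beta * zcols[term]
            vals_sub = lin.copy()
            for tid in sub["tree_id"].unique():
                tmask = (sub["tree_id"] == tid).to_numpy()
                b_tree = rng_b.normal(0.0, rt.sigma_b)
                noise = _ar1(rng_e, int(tmask.sum()), rt.rho, rt.sigma)
                vals_sub[tmask] += b_tree + noise
            vals[mask] = vals_sub
        out[resp] = vals
    return out


def _prescribed_d18o_lw(years, truth: TruthRecord):
    return _piecewise(years, truth.d18o_lw_knots)


def latents_to_observables(latents: pd.DataFrame, env: pd.DataFrame,
                           truth: TruthRecord,
                           carbon_params: cb.CarbonParams = cb.DEFAULT_CARBON,
                           oxygen_params: ox.OxygenParams = ox.DEFAULT_OXYGEN,
                           seed: int = 0, measurement_noise: bool = True,
                           ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Map latent responses to isotope and ring-width observables.

    δ13C comes from the exact inverse of the photorespiration-corrected
    physiology chain; wood-tree δ13C/δ15N are pooled into tree-anchored
    5-year segments (segment value = unweighted mean of the annual values,
    counted back from the most recent year; an incomplete oldest remainder
    is dropped); cellulose δ18O is built by inverting the leaf-water chain
    from the prescribed Δ18O_lw trajectory plus per-tree noise.  Ring widths
    are back-computed from BAI = exp(bai_ln) via the cumulative radius.
    Measurement noise (printed replicate SDs) is added after pooling unless
    disabled.
    """
    env_idx = env.set_index("year")
    rng = _rng(seed, 30)
    p_ex = float(ox.pex_from_vpd(float(env["vpd"].mean()), oxygen_params))
    sigb_o, sig_o, rho_o = truth.d18o_lw_noise
    iso_rows, ring_frames = [], []
    for (tid, sp, mat), sub in latents.groupby(["tree_id", "species", "material"],
                                               sort=True):
        sub = sub.sort_values("year")
        years = sub["year"].to_numpy(dtype=int)
        ca = env_idx["ca"].loc[years].to_numpy()
        atm = env_idx["d13c_atm"].loc[years].to_numpy()
        tleaf = env_idx["t_apr_aug"].loc[years].to_numpy()
        w = sub["iwue"].to_numpy()
        bad = (w <= 0) | (w >= ca / carbon_params.diffusion_ratio)
        if bad.any():
            j = int(np.flatnonzero(bad)[0])
            raise ValueError(f"infeasible latent iWUE for tree {tid} year {years[j]}: "
                             f"{w[j]:.2f} outside (0, {ca[j] / 1.6:.2f})")
        d13c_annual = cb.invert_iwue_to_d13c(w, ca, atm, t_leaf=tleaf,
                                             params=carbon_params, method="photoresp")
        if mat == "cellulose":
            d13c = d13c_annual.copy()
            if measurement_noise:
                d13c += rng.normal(0, MEAS_SD[("d13c", "cellulose")], len(d13c))
            dlw = (_prescribed_d18o_lw(years, truth)
                   + rng.normal(0, sigb_o)
                   + _ar1(rng, len(years), rho_o, sig_o))
            ewc = ox.epsilon_wc(np.clip(tleaf, 0, 40), oxygen_params)
            dtr = dlw * (1.0 - oxygen_params.px * p_ex) + ewc
            d18o_p = env_idx["d18o_p"].loc[years].to_numpy()
            d18o = dtr * (1.0 + d18o_p / 1000.0) + d18o_p
            if measurement_noise:
                d18o += rng.normal(0, MEAS_SD[("d18o", "cellulose")], len(d18o))
            for i in range(len(years)):
                iso_rows.append({"tree_id": tid, "species": sp,
                                 "year_start": years[i], "year_end": years[i],
                                 "material": "cellulose", "d13c": d13c[i],
                                 "d15n": np.nan, "d18o": d18o[i]})
        else:
            d15n_annual = sub["d15n"].to_numpy()
            n_full = len(years) // POOL_YEARS
            first = len(years) - n_full * POOL_YEARS   # drop incomplete oldest remainder
            for s in range(n_full):
                sl = slice(first + s * POOL_YEARS, first + (s + 1) * POOL_YEARS)
                d13c = float(np.mean(d13c_annual[sl]))
                d15n = float(np.mean(d15n_annual[sl]))
                if measurement_noise:
                    d13c += rng.normal(0, MEAS_SD[("d13c", "wood")])
                    d15n += rng.normal(0, MEAS_SD[("d15n", "wood")])
                iso_rows.append({"tree_id": tid, "species": sp,
                                 "year_start": int(years[sl][0]),
                                 "year_end": int(years[sl][-1]),
                                 "material": "wood", "d13c": d13c,
                                 "d15n": d15n, "d18o": np.nan})
        bai_vals = np.exp(sub["bai_ln"].to_numpy())
        r = np.sqrt(np.cumsum(bai_vals) / np.pi)
        widths = np.diff(np.concatenate([[0.0], r]))
        ring_frames.append(pd.DataFrame({
            "tree_id": tid, "species": sp, "year": years, "width_mm": widths,
            "cambial_age": sub["cambial_age"].to_numpy(),
        }))
    isotopes = pd.DataFrame(iso_rows).sort_values(
        ["species", "tree_id", "year_start"]).reset_index(drop=True)
    rings = pd.concat(ring_frames, ignore_index=True)
    return isotopes, rings


def _two_break_truth() -> TruthRecord:
    t = _null_truth()
    t.d18o_lw_knots = ((1501.0, 23.0), (2020.0, 23.0))
    return t


#: prescribed two-breakpoint iWUE chronology for the power scenario
TWO_BREAK_KNOTS = ((1501.0, 23.45), (1936.0, 80.0), (1983.0, 115.25), (2020.0, 120.06))


def make_scenario(name: str, seed: int = 0,
                  n_per_species: dict | None = None) -> Scenario:
    """Build a complete dataset + truth for one named scenario."""
    if name not in ("paper_like", "null", "two_break"):
        raise ValueError(f"unknown scenario {name!r}")
    env = synth_environment(EnvParams(), seed=_rng(seed, 1).integers(2**31))
    if name == "two_break":
        roster = generate_trees(n_per_species or {"spruce": 8}, species=("spruce",),
                                seed=seed)
        roster["material"] = "cellulose"
        truth = _two_break_truth()
        latents = generate_responses(roster, env, truth, seed=seed)
        # overwrite flat iwue with the prescribed broken-line trajectory
        rt = truth.responses[("spruce", "iwue")]
        rng = _rng(seed, 40)
        vals = _piecewise(latents["year"].to_numpy(), TWO_BREAK_KNOTS)
        for tid in roster["tree_id"]:
            m = (latents["tree_id"] == tid).to_numpy()
            vals[m] += rng.normal(0, rt.sigma_b) + _ar1(rng, int(m.sum()),
                                                        rt.rho, rt.sigma)
        latents["iwue"] = vals
        truth.implied_breakpoints[("spruce", "iwue_cellulose")] = {
            "psi": [TWO_BREAK_KNOTS[1][0], TWO_BREAK_KNOTS[2][0]],
            "slopes": [(TWO_BREAK_KNOTS[i + 1][1] - TWO_BREAK_KNOTS[i][1])
                       / (TWO_BREAK_KNOTS[i + 1][0] - TWO_BREAK_KNOTS[i][0])
                       for i in range(3)],
        }
    else:
        sizes = n_per_species or {"beech": 12, "spruce": 11, "fir": 12}
        roster = generate_trees(sizes, seed=seed)
        # annual cellulose series for part of the spruce sample, as in the
        # study design (5 cellulose trees, remainder bulk wood)
        spruce_ids = roster.loc[roster["species"] == "spruce", "tree_id"]
        roster.loc[roster["tree_id"].isin(spruce_ids.iloc[:5]), "material"] = "cellulose"
        truth = _paper_like_truth() if name == "paper_like" else _null_truth()
        latents = generate_responses(roster, env, truth, seed=seed)
    isotopes, rings = latents_to_observables(latents, env, truth, seed=seed)
    if name == "paper_like":
        truth.implied_breakpoints[("spruce", "d18o_lw")] = {
            "psi": [truth.d18o_lw_knots[1][0]],
            "slopes": [(truth.d18o_lw_knots[i + 1][1] - truth.d18o_lw_knots[i][1])
                       / (truth.d18o_lw_knots[i + 1][0] - truth.d18o_lw_knots[i][0])
                       for i in range(2)],
        }
        truth.implied_breakpoints[("spruce", "iwue_cellulose")] = \
            _implied_iwue_cellulose_breakpoints(roster, env, truth)
    return Scenario(name=name, seed=seed, env=env, roster=roster,
                    isotopes=isotopes, rings=rings, truth=truth)


def _implied_iwue_cellulose_breakpoints(roster, env, truth,
                                        window=(1818, 2020)) -> dict:
    """Breakpoints the noise-free expected iWUE_cellulose chronology implies.

    The driver-built latent trend is not exactly piecewise linear, so the
    ground truth for breakpoint recovery is defined as the segmented fit of
    the expected (noise-free) chronology itself — the pseudo-true parameter
    of the estimator under these study conditions.
    """
    from .breakpoints import build_chronology, select_n_breakpoints

    noiseless = TruthRecord(
        responses={k: ResponseTruth(rt.intercept, rt.coefs, 0.0, 0.0, 0.0)
                   for k, rt in truth.responses.items()},
        standardizers={}, d18o_lw_knots=truth.d18o_lw_knots,
        d18o_lw_noise=(0.0, 0.0, 0.0),
        candidate_mains=truth.candidate_mains,
        candidate_interactions=truth.candidate_interactions)
    cell = roster[roster["material"] == "cellulose"]
    lat = generate_responses(cell, env, noiseless, seed=0)
    d = lat.rename(columns={"iwue": "value"})[["tree_id", "species", "year", "value"]]
    chron = build_chronology(d, "value", min_fraction=1.0)
    cw = chron[(chron["year"] >= window[0]) & (chron["year"] <= window[1])]
    fit = select_n_breakpoints(cw["year"].to_numpy(dtype=float),
                               cw["mean"].to_numpy(), max_k=2, alpha=0.05)
    return {"psi": [float(p) for p in fit.psi],
            "slopes": [float(s) for s in fit.slopes]}


def truth_coefs_in_basis(truth: TruthRecord, key: tuple, standardizers: dict) -> dict:
    """True coefficients re-expressed in another Z basis.

    The generator Z-scores covariates over its annual tree-year rows while a
    fit Z-scores over its own observation rows (e.g. pooled segments); both
    are exact re-parameterizations of the same raw-unit linear model, so the
    truth is converted generator-Z -> raw -> target-Z for comparison.
    """
    from .mixedmodels import raw_to_zcoefs, zcoefs_to_raw

    rt = truth.responses[key]
    coefs = {"Intercept": rt.intercept, **rt.coefs}
    raw = zcoefs_to_raw(coefs, truth.standardizers[key])
    return raw_to_zcoefs(raw, standardizers)
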