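"""End-to-end orchestration: physiology -> leaf water -> growth -> chronologies
-> breakpoints -> mixed models -> PCA, with a run manifest.

The stages mirror the analysis order of a tree-ring isotope attribution
study.  :func:`analyze` is the in-memory engine used by tests and scripts;
:func:`run_pipeline` wraps it with file I/O, config validation, per-stage
checksums and timings.  Every default in :class:`AnalysisOptions` is the
study default (photorespiration-corrected iWUE at 1030 m with leaf
temperature = Apr-Aug mean, constant ε_wc = 27 permil, breakpoints on
1818-2020 chronologies with at most two breaks, ΔAICc < 2 averaging), so a
bare run reproduces those choices on whatever data is supplied.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import breakpoints as bp
from . import carbon as cb
from . import growth as gr
from . import mixedmodels as mm
from . import oxygen as ox
from .environment import load_environment

logger = logging.getLogger("dendro_isophys")

#: the full attribution model space: all drivers plus their CO2 interactions
FULL_MAINS = ("cambial_age", "ca", "ndep", "ph", "spi_jun_aug", "t_apr_aug")
FULL_INTERACTIONS = ("ca:cambial_age", "ca:ndep", "ca:ph",
                     "ca:spi_jun_aug", "ca:t_apr_aug")
RESPONSES = ("iwue", "d15n", "bai_ln")
POOL_YEARS = 5


@dataclass
class AnalysisOptions:
    iwue_method: str = "photoresp"
    carbon_params: cb.CarbonParams = field(default_factory=cb.CarbonParams)
    oxygen_params: ox.OxygenParams = field(default_factory=ox.OxygenParams)
    d18op_obs_window: tuple = (1950, 2020)
    breakpoint_window: tuple = (1818, 2020)
    max_breakpoints: int = 2
    alpha: float = 0.05
    min_fraction: float = 0.5        # chronology replication rule, pooled wood
    min_fraction_cellulose: float = 1.0
    delta_aicc: float = 2.0
    mains: tuple = FULL_MAINS
    interactions: dict | tuple = FULL_INTERACTIONS
    max_models: int = 4096
    seed: int = 0

    def interactions_for(self, response: str) -> tuple:
        if isinstance(self.interactions, dict):
            return tuple(self.interactions.get(response, ()))
        return tuple(self.interactions)


# ---------------------------------------------------------------------------
# covariate assembly
# ---------------------------------------------------------------------------

def _attach_covariates(rows: pd.DataFrame, env: pd.DataFrame,
                       rings: pd.DataFrame) -> pd.DataFrame:
    """Segment-mean drivers, cambial age and a native-step time index.

    ``rows`` has tree_id/species/year_start/year_end/material; drivers and
    cambial age are averaged over each row's span, and ``time`` counts
    native sampling steps within each tree (1 per year for annual rows, 1
    per segment for pooled rows), so AR(1) lags are in observation units.
    """
    out = rows.copy()
    env_idx = env.set_index("year")
    ages = rings.set_index(["tree_id", "year"])["cambial_age"]
    for col in ("ca", "ndep", "ph", "spi_jun_aug", "t_apr_aug"):
        arr = env_idx[col]
        out[col] = [float(arr.loc[ys:ye].mean())
                    for ys, ye in zip(out["year_start"], out["year_end"])]
    cam = []
    for tid, ys, ye in zip(out["tree_id"], out["year_start"], out["year_end"]):
        cam.append(float(ages.loc[tid].loc[ys:ye].mean()))
    out["cambial_age"] = cam
    out["cellulose"] = (out["material"] == "cellulose").astype(float)
    out = out.reset_index(drop=True)
    times = np.zeros(len(out))
    for _, grp in out.groupby("tree_id"):
        g = grp.sort_values("year_start")
        ys = g["year_start"].to_numpy()
        pooled = (g["year_end"].to_numpy() > ys).any()
        step = POOL_YEARS if pooled else 1
        times[g.index.to_numpy()] = np.round((ys - ys[0]) / step)
    out["time"] = times
    return out


def _response_tables(physio: pd.DataFrame, iso: pd.DataFrame,
                     growth_tables: dict, env: pd.DataFrame,
                     rings: pd.DataFrame) -> dict:
    """Per-(species, response) observation tables for the mixed models.

    iWUE uses wood segments plus annual cellulose rows; δ15N and BAI_ln use
    the wood trees at segment resolution (BAI_ln as the segment mean of
    annual ln BAI), matching the observation units of the isotope tables.
    """
    tables = {}
    base_cols = ["tree_id", "species", "year_start", "year_end", "material"]
    for sp in physio["species"].unique():
        psub = physio[physio["species"] == sp]
        tables[(sp, "iwue")] = _attach_covariates(
            psub[base_cols + ["iwue"]].reset_index(drop=True), env, rings)
        dsub = iso[(iso["species"] == sp) & iso["d15n"].notna()]
        if len(dsub):
            tables[(sp, "d15n")] = _attach_covariates(
                dsub[base_cols + ["d15n"]].reset_index(drop=True), env, rings)
        wood_seg = iso[(iso["species"] == sp) & (iso["material"] == "wood")]
        if len(wood_seg):
            rows = wood_seg[base_cols].copy()
            vals = []
            for tid, ys, ye in zip(rows["tree_id"], rows["year_start"],
                                   rows["year_end"]):
                g = growth_tables[tid]
                vals.append(float(g.set_index("year")["bai_ln"].loc[ys:ye].mean()))
            rows["bai_ln"] = vals
            tables[(sp, "bai_ln")] = _attach_covariates(
                rows.reset_index(drop=True), env, rings)
    return tables


# ---------------------------------------------------------------------------
# in-memory analysis
# ---------------------------------------------------------------------------

def analyze(env: pd.DataFrame, isotopes: pd.DataFrame, rings: pd.DataFrame,
            options: AnalysisOptions | None = None,
            stages: tuple = ("physiology", "leafwater", "growth",
                             "breakpoints", "lme", "pca")) -> dict:
    """Run the analysis stages on in-memory tables; returns a results dict."""
    opt = options or AnalysisOptions()
    res: dict = {"options": opt, "warnings": []}

    physio = cb.iwue_series(isotopes, env, opt.carbon_params, opt.iwue_method)
    res["physio"] = physio

    cell = isotopes[(isotopes["material"] == "cellulose")
                    & isotopes["d18o"].notna()].reset_index(drop=True)
    if "leafwater" in stages and len(cell):
        obs = env[(env["year"] >= opt.d18op_obs_window[0])
                  & (env["year"] <= opt.d18op_obs_window[1])]
        model = ox.fit_d18op_model(obs["d18o_p"], obs["t_annual"], obs["spi_annual"])
        d18op = ox.hindcast_d18op(model, env, opt.d18op_obs_window)
        res["d18op_model"] = model
        res["leafwater"] = ox.leafwater_series(cell, env, d18op, opt.oxygen_params)

    growth_tables = {}
    if "growth" in stages or "lme" in stages or "breakpoints" in stages:
        for tid, grp in rings.groupby("tree_id"):
            growth_tables[tid] = gr.bai(grp)
        res["growth"] = growth_tables

    if "breakpoints" in stages:
        res["chronologies"], res["breakpoints"] = {}, {}
        chron_inputs = {}
        wood = physio[physio["material"] == "wood"]
        for sp in wood["species"].unique():
            chron_inputs[(sp, "iwue_wood")] = (
                bp.expand_segments(wood[wood["species"] == sp], "iwue")
                .rename(columns={"iwue": "value"}), opt.min_fraction)
        cellp = physio[physio["material"] == "cellulose"]
        for sp in cellp["species"].unique():
            d = cellp[cellp["species"] == sp][["tree_id", "species", "iwue"]].copy()
            d["year"] = cellp[cellp["species"] == sp]["year_start"].to_numpy()
            chron_inputs[(sp, "iwue_cellulose")] = (
                d.rename(columns={"iwue": "value"}), opt.min_fraction_cellulose)
        d15 = isotopes[isotopes["d15n"].notna()]
        for sp in d15["species"].unique():
            chron_inputs[(sp, "d15n")] = (
                bp.expand_segments(d15[d15["species"] == sp], "d15n")
                .rename(columns={"d15n": "value"}), opt.min_fraction)
        if "leafwater" in res:
            lw = res["leafwater"]
            for sp in lw["species"].unique():
                d = lw[lw["species"] == sp][["tree_id", "species", "year",
                                             "big_delta_18o_lw"]].copy()
                chron_inputs[(sp, "d18o_lw")] = (
                    d.rename(columns={"big_delta_18o_lw": "value"}),
                    opt.min_fraction_cellulose)
        ring_species = rings[["tree_id", "species"]].drop_duplicates() \
            if "species" in rings.columns else None
        if ring_species is not None:
            for sp in ring_species["species"].unique():
                ids = ring_species[ring_species["species"] == sp]["tree_id"]
                frames = []
                for tid in ids:
                    g = growth_tables[tid].dropna(subset=["bai_ln"])
                    frames.append(pd.DataFrame({"tree_id": tid, "species": sp,
                                                "year": g["year"],
                                                "value": g["bai_ln"]}))
                chron_inputs[(sp, "bai_ln")] = (pd.concat(frames, ignore_index=True),
                                                opt.min_fraction)
        lo, hi = opt.breakpoint_window
        for key, (d, frac) in chron_inputs.items():
            try:
                chron = bp.build_chronology(d, "value", min_fraction=frac)
            except ValueError as exc:
                res["warnings"].append(f"chronology {key}: {exc}")
                continue
            res["chronologies"][key] = chron
            cw = chron[(chron["year"] >= lo) & (chron["year"] <= hi)]
            if len(cw) < 30:
                res["warnings"].append(f"breakpoints {key}: only {len(cw)} years in window")
                continue
            res["breakpoints"][key] = bp.select_n_breakpoints(
                cw["year"].to_numpy(dtype=float), cw["mean"].to_numpy(),
                max_k=opt.max_breakpoints, alpha=opt.alpha, seed=opt.seed)

    if "lme" in stages:
        res["lme"], res["vif"] = {}, {}
        tables = _response_tables(physio, isotopes, growth_tables, env, rings)
        res["lme_tables"] = tables
        for (sp, resp), data in tables.items():
            mains = tuple(opt.mains)
            if resp == "iwue" and data["cellulose"].nunique() > 1:
                mains = ("cellulose",) + mains
            spec = mm.ModelSpec(resp, mains, opt.interactions_for(resp))
            try:
                fits = mm.fit_model_set(data, spec, max_models=opt.max_models)
                res["lme"][(sp, resp)] = mm.model_average(fits, opt.delta_aicc)
                Xf, _, _, _, stds = mm.build_design(data, spec)
                cont = [m for m in mains if m != "cellulose"]
                res["vif"][(sp, resp)] = mm.vif(Xf[cont])
                res["lme"][(sp, resp)].standardizers = stds
            except (ValueError, RuntimeError) as exc:
                res["warnings"].append(f"lme {sp}/{resp}: {exc}")

    if "pca" in stages and "chronologies" in res:
        res["pca"] = {}
        for sp in isotopes["species"].unique():
            cols = {}
            for var in ("iwue_wood", "d15n", "bai_ln"):
                key = (sp, var)
                if key in res["chronologies"]:
                    c = res["chronologies"][key]
                    cols[var] = pd.Series(c["mean"].to_numpy(), index=c["year"])
            if not cols:
                continue
            tab = pd.DataFrame(cols)
            envw = env.set_index("year")[["ca", "ndep", "ph",
                                          "spi_jun_aug", "t_apr_aug"]]
            tab = tab.join(envw, how="inner").dropna()
            if len(tab) >= 10:
                res["pca"][sp] = mm.pca_summary(tab)
    return res


# ---------------------------------------------------------------------------
# file-based runs with manifest
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    env_path: str
    isotopes_path: str
    rings_path: str
    out_dir: str
    window: tuple = (1501, 2020)
    options: AnalysisOptions = field(default_factory=AnalysisOptions)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        opt_raw = raw.pop("options", {}) or {}
        opt = AnalysisOptions()
        for k, v in opt_raw.items():
            if not hasattr(opt, k):
                raise ValueError(f"unknown option {k!r}")
            if isinstance(v, list):
                v = tuple(v)
            setattr(opt, k, v)
        cfg = cls(env_path=raw["env_path"], isotopes_path=raw["isotopes_path"],
                  rings_path=raw["rings_path"], out_dir=raw["out_dir"],
                  window=tuple(raw.get("window", (1501, 2020))), options=opt)
        for p in (cfg.env_path, cfg.isotopes_path, cfg.rings_path):
            if not Path(p).exists():
                raise FileNotFoundError(f"configured input missing: {p}")
        return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages from files and write tables, JSON and a manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t_all = time.time()
    env = load_environment(config.env_path, window=config.window)
    isotopes = pd.read_csv(config.isotopes_path)
    rings_path = Path(config.rings_path)
    if rings_path.suffix.lower() == ".rwl":
        rings = gr.read_rwl(rings_path)
        species_map = isotopes.drop_duplicates("tree_id").set_index("tree_id")["species"]
        rings["species"] = rings["tree_id"].map(species_map)
    else:
        rings = pd.read_csv(rings_path)
        if "cambial_age" not in rings.columns:
            rings["cambial_age"] = rings.groupby("tree_id")["year"].rank().astype(int)

    res = analyze(env, isotopes, rings, options=config.options)

    stage_files: dict[str, list] = {}
    _write_csv(res["physio"], out / "physiology.csv")
    stage_files["physiology"] = ["physiology.csv"]
    if "leafwater" in res:
        _write_csv(res["leafwater"], out / "leafwater.csv")
        m = res["d18op_model"]
        (out / "leafwater_meta.json").write_text(json.dumps({
            "d18op_model": {"intercept": m.intercept, "t_coef": m.t_coef,
                            "spi_coef": m.spi_coef, "r": m.r, "n": m.n},
            "oxygen_params": asdict(config.options.oxygen_params)}, indent=2))
        stage_files["leafwater"] = ["leafwater.csv", "leafwater_meta.json"]
    bp_rows = []
    for (sp, var), fit in res.get("breakpoints", {}).items():
        rep = bp.slope_report(fit)
        rep.insert(0, "species", sp)
        rep.insert(1, "variable", var)
        bp_rows.append(rep)
    if bp_rows:
        _write_csv(pd.concat(bp_rows, ignore_index=True), out / "breakpoints.csv")
        stage_files["breakpoints"] = ["breakpoints.csv"]
    lme_rows = []
    for (sp, resp), avg in res.get("lme", {}).items():
        t = avg.table.reset_index()
        t.insert(0, "species", sp)
        t.insert(1, "response", resp)
        t["marginal_r2"] = avg.marginal_r2
        t["conditional_r2"] = avg.conditional_r2
        t["n_obs"] = avg.n
        lme_rows.append(t)
    if lme_rows:
        _write_csv(pd.concat(lme_rows, ignore_index=True), out / "lme_averaged.csv")
        stage_files["lme"] = ["lme_averaged.csv"]

    cfg_digest = hashlib.sha256(json.dumps({
        "window": list(config.window),
        "options": {k: v for k, v in asdict(config.options).items()},
    }, sort_keys=True, default=str).encode()).hexdigest()
    manifest = {
        "config_hash": cfg_digest,
        "inputs": {p: _sha256(Path(p)) for p in
                   (config.env_path, config.isotopes_path, config.rings_path)},
        "outputs": {f: _sha256(out / f) for files in stage_files.values()
                    for f in files},
        "elapsed_s": round(time.time() - t_all, 3),
        "warnings": res["warnings"],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    res["manifest"] = manifest
    return res


def report(res: dict) -> str:
    """Human-readable run summary: breakpoints and averaged-model tables."""
    lines = []
    for (sp, var), fit in res.get("breakpoints", {}).items():
        lines.append(f"== {sp} {var}: {fit.n_breakpoints} breakpoint(s)")
        for j in range(fit.n_breakpoints):
            lines.append(f"   psi = {fit.psi[j]:.0f} +/- {fit.psi_se[j]:.0f} yr")
        for m, (s, se) in enumerate(zip(fit.slopes, fit.slopes_se)):
            lines.append(f"   segment {m + 1}: slope {s:+.4f} +/- {se:.4f} per year")
    for (sp, resp), avg in res.get("lme", {}).items():
        lines.append(f"== {sp} {resp}: averaged model "
                     f"(marg R2 {avg.marginal_r2:.2f}, cond R2 {avg.conditional_r2:.2f},"
                     f" n {avg.n})")
        for term, row in avg.table.iterrows():
            lines.append(f"   {term:<18} {row['estimate']:+8.3f} +/- {row['se']:.3f}"
                         f"  z={row['z']:.2f}  p={row['p']:.3g}")
    if not lines:
        lines.append("(no results)")
    return "\n".join(lines)
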