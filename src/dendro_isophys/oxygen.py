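"""Oxygen-isotope chain: precipitation δ18O hindcast and leaf-water enrichment.

Cellulose δ18O is referenced to source (precipitation) water to give the
tree-ring enrichment

    Δ18O_tr = (δ18O_cellulose − δ18O_p) / (1 + δ18O_p / 1000),

and the leaf-water enrichment above source water is recovered by undoing the
biochemical water-cellulose fractionation ε_wc and the partial exchange of
oxygen atoms with unenriched stem water during cellulose synthesis:

    Δ18O_lw = (Δ18O_tr − ε_wc) / (1 − p_x · p_ex),

where p_x (~1) is the proportion of stem water at the synthesis site and
p_ex the exchanged fraction, modelled as linear in site vapour pressure
deficit, p_ex = 0.36·VPD + 0.13.  ε_wc defaults to the constant 27 permil;
a temperature-dependent quadratic mode (ε_wc = 0.0084·T² − 0.51·T + 33.63,
~26.8 permil at 20 degC) is selectable.

Because instrumented precipitation-isotope series are short, δ18O_p is
hindcast to the start of the chronology from a linear regression of the
observed series on annual mean temperature and annual SPI; observed years
keep their observations and every year carries a provenance flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger("dendro_isophys")

#: coefficients of the temperature-quadratic water-cellulose fractionation
EWC_QUAD = (0.0084, -0.51, 33.63)


@dataclass(frozen=True)
class OxygenParams:
    px: float = 1.0              # proportion of stem water at synthesis site
    pex_slope: float = 0.36      # kPa^-1
    pex_intercept: float = 0.13
    ewc_model: str = "constant"  # "constant" | "quadratic"
    ewc_constant: float = 27.0   # permil

    def __post_init__(self):
        if not (0.0 <= self.px <= 1.0):
            raise ValueError("px outside [0, 1]")
        if self.ewc_model not in ("constant", "quadratic"):
            raise ValueError(f"unknown ewc_model {self.ewc_model!r}")


DEFAULT_OXYGEN = OxygenParams()


@dataclass(frozen=True)
class D18OpModel:
    """OLS hindcast model δ18O_p ~ annual mean T + annual SPI."""

    intercept: float
    t_coef: float
    spi_coef: float
    r: float          # multiple correlation
    n: int

    def predict(self, t_annual, spi_annual):
        return (self.intercept
                + self.t_coef * np.asarray(t_annual, dtype=float)
                + self.spi_coef * np.asarray(spi_annual, dtype=float))


def fit_d18op_model(d18o_p_obs, t_annual, spi_annual) -> D18OpModel:
    """Fit the δ18O_p hindcast regression on aligned annual series."""
    y = np.asarray(d18o_p_obs, dtype=float)
    t = np.asarray(t_annual, dtype=float)
    s = np.asarray(spi_annual, dtype=float)
    if not (len(y) == len(t) == len(s)):
        raise ValueError("series must be aligned")
    if len(y) < 10:
        raise ValueError("need at least 10 annual observations")
    X = np.column_stack([np.ones(len(y)), t, s])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design (constant predictor?)")
    res = sm.OLS(y, X).fit()
    return D18OpModel(intercept=float(res.params[0]), t_coef=float(res.params[1]),
                      spi_coef=float(res.params[2]),
                      r=float(np.sqrt(max(res.rsquared, 0.0))), n=len(y))


def hindcast_d18op(model: D18OpModel, env: pd.DataFrame,
                   obs_window: tuple[int, int]) -> pd.DataFrame:
    """Full-window δ18O_p series: observed inside ``obs_window``, model elsewhere.

    Returns a frame with columns year, d18o_p, source ("observed"/"hindcast").
    """
    lo, hi = int(obs_window[0]), int(obs_window[1])
    years = env["year"].to_numpy()
    pred = model.predict(env["t_annual"].to_numpy(), env["spi_annual"].to_numpy())
    observed = (years >= lo) & (years <= hi)
    d18o = np.where(observed, env["d18o_p"].to_numpy(), pred)
    return pd.DataFrame({
        "year": years,
        "d18o_p": d18o,
        "source": np.where(observed, "observed", "hindcast"),
    })


def delta18o_tr(d18o_cellulose, d18o_p):
    """Tree-ring cellulose enrichment above source water (permil)."""
    d18o_p = np.asarray(d18o_p, dtype=float)
    if np.any(np.abs(d18o_p) >= 1000):
        raise ValueError("|δ18O_p| must be < 1000 permil")
    return (np.asarray(d18o_cellulose, dtype=float) - d18o_p) / (1.0 + d18o_p / 1000.0)


def pex_from_vpd(vpd, params: OxygenParams = DEFAULT_OXYGEN):
    """Exchanged-oxygen fraction from vapour pressure deficit (kPa)."""
    v = np.asarray(vpd, dtype=float)
    if np.any(v < 0):
        raise ValueError("vpd must be >= 0")
    p = params.pex_intercept + params.pex_slope * v
    clipped = np.clip(p, 0.0, 0.95)
    if np.any(clipped != p):
        logger.warning("pex_from_vpd: p_ex clipped into [0, 0.95]")
    return clipped


def epsilon_wc(t, params: OxygenParams = DEFAULT_OXYGEN):
    """Water-cellulose biochemical fractionation ε_wc (permil) at temperature t."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0) or np.any(t > 40):
        raise ValueError("temperature outside [0, 40] degC")
    if params.ewc_model == "constant":
        return np.broadcast_to(np.float64(params.ewc_constant), t.shape).copy() \
            if t.shape else float(params.ewc_constant)
    c2, c1, c0 = EWC_QUAD
    return c2 * t**2 + c1 * t + c0


def delta18o_lw(big_delta_tr, ewc, p_ex, params: OxygenParams = DEFAULT_OXYGEN):
    """Leaf-water enrichment above source water (permil)."""
    denom = 1.0 - params.px * np.asarray(p_ex, dtype=float)
    if np.any(denom <= 0):
        raise ValueError("px * p_ex must be < 1")
    return (np.asarray(big_delta_tr, dtype=float) - np.asarray(ewc, dtype=float)) / denom


def leafwater_series(iso: pd.DataFrame, env: pd.DataFrame, d18op: pd.DataFrame,
                     params: OxygenParams = DEFAULT_OXYGEN,
                     per_year_pex: bool = False) -> pd.DataFrame:
    """Chain the oxygen operations over an annual cellulose isotope table.

    ``iso`` must contain cellulose rows only (columns tree_id, species,
    year_start, year_end, material, d18o) at annual resolution; ``d18op`` is
    the hindcast frame from :func:`hindcast_d18op`.  By default p_ex is a
    single site constant computed from the mean VPD; ``per_year_pex`` uses
    each year's VPD instead.  All intermediates are retained.
    """
    if len(iso) and (iso["material"] != "cellulose").any():
        raise ValueError("Δ18O computed on cellulose only; wood rows present")
    if len(iso) and (iso["year_end"] != iso["year_start"]).any():
        raise ValueError("cellulose isotope rows must be annual")
    if len(iso) == 0:
        return pd.DataFrame(columns=["tree_id", "species", "year", "d18o_p",
                                     "big_delta_18o_tr", "ewc", "p_ex",
                                     "big_delta_18o_lw"])
    years = iso["year_start"].to_numpy(dtype=int)
    d18op_idx = d18op.set_index("year")["d18o_p"]
    missing = set(years) - set(d18op_idx.index)
    if missing:
        raise ValueError(f"years without δ18O_p: {sorted(missing)[:10]}")
    d18o_p = d18op_idx.loc[years].to_numpy()
    env_idx = env.set_index("year")
    if per_year_pex:
        p_ex = pex_from_vpd(env_idx["vpd"].loc[years].to_numpy(), params)
    else:
        p_ex = float(pex_from_vpd(float(env["vpd"].mean()), params))
    t_leaf = env_idx["t_apr_aug"].loc[years].to_numpy()
    ewc = epsilon_wc(np.clip(t_leaf, 0.0, 40.0), params)
    big_tr = delta18o_tr(iso["d18o"].to_numpy(), d18o_p)
    out = pd.DataFrame({
        "tree_id": iso["tree_id"].to_numpy(),
        "species": iso["species"].to_numpy(),
        "year": years,
        "d18o_cellulose": iso["d18o"].to_numpy(),
        "d18o_p": d18o_p,
        "big_delta_18o_tr": big_tr,
        "ewc": np.broadcast_to(np.asarray(ewc, dtype=float), big_tr.shape),
        "p_ex": np.broadcast_to(np.asarray(p_ex, dtype=float), big_tr.shape),
        "big_delta_18o_lw": delta18o_lw(big_tr, ewc, p_ex, params),
    })
    return out
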