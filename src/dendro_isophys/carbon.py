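"""Carbon-isotope physiology: δ13C -> Δ13C -> ci -> intrinsic water-use efficiency.

The chain follows the classic C3 discrimination model.  Measured tree-ring
δ13C (wood or cellulose) is first corrected for post-photosynthetic
fractionation (constant offset, default 2 permil), converted to
discrimination against the contemporaneous atmosphere,

    Δ13C = (δ13C_atm − δ13C_plant) / (1 + δ13C_plant / 1000),

then inverted for the intercellular CO2 mole fraction using either the
simple linear model

    Δ13C = a + (b − a) · ci/ca                  (simple)

or the photorespiration-corrected form

    Δ13C = a + (b − a) · ci/ca − f · Γ*/ca      (photoresp)

with a = 4.4 permil (diffusion through stomata), b = 28 permil (Rubisco
carboxylation) and f = 12 permil (photorespiratory fractionation).  The CO2
compensation point Γ* uses an Arrhenius temperature response anchored at
42.75 ppm (25 degC, sea level) and is corrected to site barometric pressure
through the 1976 standard atmosphere: as pressure falls with elevation the
compensation *mole fraction* rises, Γ*(z) = Γ*(0) · P0/P(z).

Intrinsic water-use efficiency follows as iWUE = (ca − ci)/1.6, the 1.6
being the H2O:CO2 ratio of stomatal diffusivities.  The whole chain is
algebraically invertible, which the synthetic generator uses to emit δ13C
series with a prescribed iWUE trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

R_GAS = 8.314          # J mol-1 K-1
EA_GAMMA = 37830.0     # J mol-1, activation energy of the Γ* response
P0_KPA = 101.325


@dataclass(frozen=True)
class CarbonParams:
    """Constants of the discrimination model (permil unless noted)."""

    a: float = 4.4               # stomatal diffusion fractionation
    b: float = 28.0              # Rubisco carboxylation fractionation
    d_offset: float = 2.0        # post-photosynthetic offset on measured δ13C
    f: float = 12.0              # photorespiratory fractionation
    gamma_star_25: float = 42.75 # Γ* at 25 degC and sea level, ppm
    elevation: float = 1030.0    # site elevation, m
    diffusion_ratio: float = 1.6 # H2O:CO2 stomatal conductance ratio

    def __post_init__(self):
        if not (self.b > self.a > 0):
            raise ValueError("require b > a > 0")
        if not (0 <= self.d_offset <= 3):
            raise ValueError("d_offset outside [0, 3] permil")
        if self.elevation < 0:
            raise ValueError("elevation must be >= 0")


DEFAULT_CARBON = CarbonParams()


def discrimination(d13c_sample, d13c_atm, params: CarbonParams = DEFAULT_CARBON):
    """Δ13C (permil) from sample and atmospheric δ13C.

    The sample value is first shifted by ``params.d_offset`` toward the
    atmosphere to remove post-photosynthetic fractionation.
    """
    d13c_p = np.asarray(d13c_sample, dtype=float) - params.d_offset
    denom = 1.0 + d13c_p / 1000.0
    if np.any(denom <= 0):
        raise ValueError("impossible δ13C input: 1 + δ13C_plant/1000 <= 0")
    return (np.asarray(d13c_atm, dtype=float) - d13c_p) / denom


def barometric_pressure(elevation_m) -> float:
    """Pressure (kPa) at elevation via the 1976 standard atmosphere."""
    z = np.asarray(elevation_m, dtype=float)
    return P0_KPA * (1.0 - 2.25577e-5 * z) ** 5.25588


def gamma_star(t_leaf, elevation: float | None = None,
               params: CarbonParams = DEFAULT_CARBON):
    """CO2 compensation point Γ* (ppm mole fraction) at leaf T and elevation.

    Arrhenius response anchored at ``gamma_star_25`` for 25 degC, scaled by
    P0/P(elevation) so that the mole-fraction compensation point rises with
    altitude (constant compensation partial pressure).
    """
    t = np.asarray(t_leaf, dtype=float)
    if np.any(t < -10) or np.any(t > 40):
        raise ValueError("t_leaf outside [-10, 40] degC")
    elev = params.elevation if elevation is None else elevation
    tk = t + 273.15
    arrh = np.exp(EA_GAMMA * (tk - 298.15) / (298.15 * R_GAS * tk))
    return params.gamma_star_25 * arrh * (P0_KPA / barometric_pressure(elev))


def ci_simple(big_delta, ca, params: CarbonParams = DEFAULT_CARBON):
    """Intercellular CO2 (ppm) from the simple linear discrimination model."""
    return np.asarray(ca, dtype=float) * (np.asarray(big_delta, dtype=float)
                                          - params.a) / (params.b - params.a)


def ci_photoresp(big_delta, ca, gstar, params: CarbonParams = DEFAULT_CARBON):
    """Intercellular CO2 (ppm) including the photorespiratory term f·Γ*."""
    big_delta = np.asarray(big_delta, dtype=float)
    ca = np.asarray(ca, dtype=float)
    return ((big_delta - params.a) * ca
            + params.f * np.asarray(gstar, dtype=float)) / (params.b - params.a)


def iwue(ca, ci, params: CarbonParams = DEFAULT_CARBON):
    """Intrinsic water-use efficiency (μmol CO2 per mol H2O)."""
    return (np.asarray(ca, dtype=float) - np.asarray(ci, dtype=float)) / params.diffusion_ratio


def _segment_env_means(iso: pd.DataFrame, env: pd.DataFrame, cols):
    """Per-row means of env columns over [year_start, year_end] inclusive."""
    env_idx = env.set_index("year")
    lo, hi = int(env["year"].iloc[0]), int(env["year"].iloc[-1])
    bad = iso[(iso["year_start"] < lo) | (iso["year_end"] > hi)]
    if len(bad):
        rows = bad[["tree_id", "year_start", "year_end"]].to_dict("records")
        raise ValueError(f"isotope rows outside environment window {lo}-{hi}: {rows}")
    arrs = {c: env_idx[c].to_numpy() for c in cols}
    y0 = iso["year_start"].to_numpy(dtype=int) - lo
    y1 = iso["year_end"].to_numpy(dtype=int) - lo
    out = {}
    for c, a in arrs.items():
        csum = np.concatenate([[0.0], np.cumsum(a)])
        out[c] = (csum[y1 + 1] - csum[y0]) / (y1 - y0 + 1)
    return out


def iwue_series(iso: pd.DataFrame, env: pd.DataFrame,
                params: CarbonParams = DEFAULT_CARBON,
                method: str = "photoresp") -> pd.DataFrame:
    """Per-tree iWUE series from an isotope table and the driver table.

    ``iso`` needs columns tree_id, species, year_start, year_end, material,
    d13c.  Pooled segments (year_end > year_start) use the arithmetic mean of
    the annual drivers (ca, δ13C_atm, leaf T) over the segment's years; leaf
    temperature is the Apr-Aug mean of that year/segment.  Returns one row
    per input row with Δ13C, ci, ci/ca and iWUE; ``year`` is the segment
    midpoint.
    """
    if method not in ("simple", "photoresp"):
        raise ValueError(f"unknown method {method!r}")
    if len(iso) == 0:
        return pd.DataFrame(columns=["tree_id", "species", "year", "year_start",
                                     "year_end", "material", "big_delta_13c",
                                     "ci", "ci_ca", "iwue"])
    drv = _segment_env_means(iso, env, ["ca", "d13c_atm", "t_apr_aug"])
    big_delta = discrimination(iso["d13c"].to_numpy(), drv["d13c_atm"], params)
    if method == "simple":
        ci = ci_simple(big_delta, drv["ca"], params)
    else:
        gs = gamma_star(drv["t_apr_aug"], params.elevation, params)
        ci = ci_photoresp(big_delta, drv["ca"], gs, params)
    out = pd.DataFrame({
        "tree_id": iso["tree_id"].to_numpy(),
        "species": iso["species"].to_numpy(),
        "year": (iso["year_start"].to_numpy() + iso["year_end"].to_numpy()) / 2.0,
        "year_start": iso["year_start"].to_numpy(),
        "year_end": iso["year_end"].to_numpy(),
        "material": iso["material"].to_numpy(),
        "big_delta_13c": big_delta,
        "ci": ci,
        "ci_ca": ci / drv["ca"],
        "iwue": iwue(drv["ca"], ci, params),
    })
    return out


def invert_iwue_to_d13c(iwue_target, ca, d13c_atm, t_leaf=None,
                        params: CarbonParams = DEFAULT_CARBON,
                        method: str = "photoresp"):
    """Exact algebraic inverse of the physiology chain.

    Given a target iWUE and the contemporaneous drivers, returns the measured
    δ13C (offset added back) that the forward chain maps onto that iWUE.
    Targets must satisfy 0 < iWUE < ca/1.6 (ci in (0, ca)); the boundary
    itself is rejected.
    """
    w = np.asarray(iwue_target, dtype=float)
    ca = np.asarray(ca, dtype=float)
    if np.any(w <= 0) or np.any(w >= ca / params.diffusion_ratio):
        raise ValueError("iwue_target outside feasible open interval (0, ca/1.6)")
    ci = ca - params.diffusion_ratio * w
    if method == "simple":
        big_delta = params.a + (params.b - params.a) * ci / ca
    elif method == "photoresp":
        if t_leaf is None:
            raise ValueError("photoresp inversion needs t_leaf")
        gs = gamma_star(t_leaf, params.elevation, params)
        big_delta = params.a + ((params.b - params.a) * ci - params.f * gs) / ca
    else:
        raise ValueError(f"unknown method {method!r}")
    d13c_atm = np.asarray(d13c_atm, dtype=float)
    d13c_p = (d13c_atm - big_delta) / (1.0 + big_delta / 1000.0)
    return d13c_p + params.d_offset
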