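"""Annual environmental driver table: loading, validation, Z-scoring, synthesis.

Every downstream stage (physiology, leaf water, mixed models) consumes one
annual table of environmental drivers covering the analysis window.  The
canonical in-memory form is a plain :class:`pandas.DataFrame` with a ``year``
column and the driver columns listed in :data:`DRIVER_COLUMNS`; this module
validates that contract once so the rest of the pipeline can rely on it.

The synthetic driver generator emulates the industrial-era shapes that a
Central-European montane site experienced: a CO2 ramp accelerating in the
late 20th century with the accompanying Suess-effect decline in atmospheric
δ13C, an acid-deposition hump (N deposition peaking ~1989, precipitation pH
bottoming out ~1988 from a pre-industrial 5.8), and post-1974 warming.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("dendro_isophys")

#: required columns of the annual driver table (besides ``year``)
DRIVER_COLUMNS = (
    "ca",          # ambient CO2 mole fraction, ppm
    "d13c_atm",    # δ13C of atmospheric CO2, permil VPDB
    "ndep",        # total N deposition, kg ha-1 yr-1
    "ph",          # precipitation pH
    "t_apr_aug",   # Apr-Aug mean temperature, degC
    "t_annual",    # annual mean temperature, degC
    "spi_jun_aug", # standardized precipitation index Jun-Aug
    "spi_annual",  # annual SPI
    "d18o_p",      # precipitation δ18O, permil VSMOW (may need hindcasting)
    "vpd",         # site mean vapour pressure deficit, kPa
)

#: columns that may be absent from the input and filled from config constants
FILLABLE_COLUMNS = ("vpd", "d18o_p")

DEFAULT_VPD = 0.6  # kPa; plausible montane growing-season mean


class EnvironmentError_(ValueError):
    """Raised when the driver table violates its contract."""


@dataclass(frozen=True)
class Standardizer:
    """Mean/SD pair used for Z-scoring one variable, with exact inverse."""

    mean: float
    sd: float

    def transform(self, x):
        return (np.asarray(x, dtype=float) - self.mean) / self.sd

    def inverse(self, z):
        return np.asarray(z, dtype=float) * self.sd + self.mean


def zscore(values) -> tuple[np.ndarray, Standardizer]:
    """Z-score a numeric series; returns the scaled series and its Standardizer.

    Uses the sample SD (ddof=1), matching the convention of R's ``scale()``.
    Raises ``ValueError`` for series shorter than 2 or with zero variance.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("zscore requires at least 2 values")
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    if sd == 0.0 or not np.isfinite(sd):
        raise ValueError("zscore requires nonzero, finite variance")
    st = Standardizer(mean, sd)
    return st.transform(x), st


def validate_environment(env: pd.DataFrame) -> pd.DataFrame:
    """Check the driver-table contract; returns the table sorted by year."""
    if "year" not in env.columns:
        raise EnvironmentError_("driver table must have a 'year' column")
    missing = [c for c in DRIVER_COLUMNS if c not in env.columns]
    if missing:
        raise EnvironmentError_(f"driver table missing required column(s): {missing}")
    env = env.sort_values("year").reset_index(drop=True)
    years = env["year"].to_numpy()
    if len(np.unique(years)) != len(years):
        dup = int(pd.Series(years).loc[pd.Series(years).duplicated()].iloc[0])
        raise EnvironmentError_(f"duplicated year in driver table: {dup}")
    if len(years) > 1 and not np.all(np.diff(years) == 1):
        gap = int(years[np.flatnonzero(np.diff(years) != 1)[0]])
        raise EnvironmentError_(f"non-contiguous years in driver table (gap after {gap})")
    if (env["ca"] <= 0).any():
        raise EnvironmentError_("ca must be positive")
    if ((env["ph"] <= 0) | (env["ph"] >= 14)).any():
        raise EnvironmentError_("ph must lie in (0, 14)")
    return env


def load_environment(table, window: tuple[int, int] | None = None,
                     fills: dict[str, float] | None = None) -> pd.DataFrame:
    """Load and validate the annual driver table, restricted to ``window``.

    Parameters
    ----------
    table : str | pathlib.Path | pandas.DataFrame
        Delimited text file (comma or tab, sniffed) with a header and a
        ``year`` column, or an already-loaded frame.
    window : (first_year, last_year), inclusive; default is the table's span.
    fills : constants for columns listed in :data:`FILLABLE_COLUMNS` that are
        absent from the input (e.g. ``{"vpd": 0.6}``).  Fills are logged;
        nothing is imputed silently.
    """
    if isinstance(table, pd.DataFrame):
        env = table.copy()
    else:
        env = pd.read_csv(table, sep=None, engine="python")
    if "year" not in env.columns:
        raise EnvironmentError_("driver table must have a 'year' column")
    for col, value in (fills or {}).items():
        if col not in FILLABLE_COLUMNS:
            raise EnvironmentError_(f"column {col!r} is not fillable by constant")
        if col not in env.columns:
            env[col] = float(value)
            logger.info("environment: filled missing column %r with constant %s", col, value)
    env = validate_environment(env)
    if window is not None:
        lo, hi = int(window[0]), int(window[1])
        span = (int(env["year"].iloc[0]), int(env["year"].iloc[-1]))
        if lo < span[0] or hi > span[1]:
            raise EnvironmentError_(f"window {window} outside table span {span}")
        env = env[(env["year"] >= lo) & (env["year"] <= hi)].reset_index(drop=True)
    return env


# ---------------------------------------------------------------------------
# synthetic drivers
# ---------------------------------------------------------------------------

@dataclass
class EnvParams:
    """Piecewise-linear knots and noise SDs for the synthetic driver table.

    Knots are ``(year, value)`` lists; values between knots are linearly
    interpolated, flat extrapolation outside.  Defaults follow the observed
    industrial-era record for a Central-European montane site: CO2 ~280 ppm
    pre-1850 rising to ~415 ppm by 2020 (accelerating after 1966), N
    deposition peaking around 1989, precipitation pH at a pre-industrial 5.8
    dropping to ~4.2 around 1988, and warming of ~0.44 degC/decade after 1974.
    Atmospheric δ13C is tied to the CO2 ramp (Suess effect),
    δ13C_atm = -6.35 - suess_slope * (ca - 280).
    """

    window: tuple[int, int] = (1501, 2020)
    ca_knots: tuple = ((1501, 280.0), (1850, 285.0), (1950, 311.0),
                       (1966, 321.0), (2020, 414.0))
    ndep_knots: tuple = ((1501, 1.5), (1850, 2.5), (1930, 8.0),
                         (1989, 25.0), (2020, 13.0))
    ph_knots: tuple = ((1501, 5.8), (1850, 5.8), (1930, 5.3),
                       (1988, 4.2), (2020, 5.0))
    t_apr_aug_base: float = 11.5   # degC before warming onset
    t_annual_base: float = 5.0
    warming_start: int = 1974
    warming_rate: float = 0.044    # degC per year after warming_start
    suess_slope: float = 0.016     # permil decline per ppm CO2 above 280
    vpd: float = DEFAULT_VPD
    # true δ18O_p model: d18o_p = b0 + bt * t_annual + bs * spi_annual + noise
    d18op_intercept: float = -11.5
    d18op_t_coef: float = 0.30     # permil per degC
    d18op_spi_coef: float = -0.15  # permil per SPI unit
    noise_sd: dict = field(default_factory=lambda: {
        "ca": 0.0, "ndep": 0.4, "ph": 0.05,
        "t_apr_aug": 0.5, "t_annual": 0.5, "d18o_p": 0.04,
    })
    spi_rho: float = 0.2           # mild persistence of the drought index


def _piecewise(years: np.ndarray, knots) -> np.ndarray:
    ky = np.array([k[0] for k in knots], dtype=float)
    kv = np.array([k[1] for k in knots], dtype=float)
    return np.interp(years.astype(float), ky, kv)


def _ar1_noise(rng: np.random.Generator, n: int, rho: float, sd: float) -> np.ndarray:
    e = rng.normal(0.0, sd, size=n)
    if rho == 0.0 or n == 0:
        return e
    out = np.empty(n)
    out[0] = e[0] / np.sqrt(1.0 - rho**2)
    for i in range(1, n):
        out[i] = rho * out[i - 1] + e[i]
    return out


def synth_environment(params: EnvParams | None = None, seed: int = 0) -> pd.DataFrame:
    """Generate a reproducible synthetic annual driver table.

    The deterministic backbone is piecewise-linear in the knots; Gaussian
    noise (SDs in ``params.noise_sd``) is added on top, and the SPI series
    are AR(1) with unit innovation variance scaled to SD 1.  With all noise
    SDs zero the output is exactly the piecewise-linear backbone.
    """
    p = params or EnvParams()
    lo, hi = p.window
    years = np.arange(lo, hi + 1)
    for name, knots in (("ca", p.ca_knots), ("ndep", p.ndep_knots), ("ph", p.ph_knots)):
        for ky, _ in knots:
            if ky < lo or ky > hi:
                raise ValueError(f"{name} knot year {ky} outside window {p.window}")
    rng = np.random.default_rng(seed)
    n = len(years)
    sd = p.noise_sd

    ca = _piecewise(years, p.ca_knots) + rng.normal(0, sd.get("ca", 0.0), n)
    ndep = np.maximum(_piecewise(years, p.ndep_knots)
                      + rng.normal(0, sd.get("ndep", 0.0), n), 0.05)
    ph = np.clip(_piecewise(years, p.ph_knots)
                 + rng.normal(0, sd.get("ph", 0.0), n), 3.0, 9.0)
    warm = np.where(years > p.warming_start,
                    (years - p.warming_start) * p.warming_rate, 0.0)
    t_apr_aug = p.t_apr_aug_base + warm + rng.normal(0, sd.get("t_apr_aug", 0.0), n)
    t_annual = p.t_annual_base + warm + rng.normal(0, sd.get("t_annual", 0.0), n)
    spi_jun_aug = _ar1_noise(rng, n, p.spi_rho, np.sqrt(1 - p.spi_rho**2))
    spi_annual = _ar1_noise(rng, n, p.spi_rho, np.sqrt(1 - p.spi_rho**2))
    d13c_atm = -6.35 - p.suess_slope * (ca - 280.0)
    d18o_p = (p.d18op_intercept + p.d18op_t_coef * t_annual
              + p.d18op_spi_coef * spi_annual
              + rng.normal(0, sd.get("d18o_p", 0.0), n))
    env = pd.DataFrame({
        "year": years, "ca": ca, "d13c_atm": d13c_atm, "ndep": ndep, "ph": ph,
        "t_apr_aug": t_apr_aug, "t_annual": t_annual,
        "spi_jun_aug": spi_jun_aug, "spi_annual": spi_annual,
        "d18o_p": d18o_p, "vpd": np.full(n, p.vpd),
    })
    return validate_environment(env)
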