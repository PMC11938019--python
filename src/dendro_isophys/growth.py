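"""Ring widths to basal area increment and boundary-line growth releases.

Ring widths arrive in the Tucson/RWL decadal interchange format.  From the
cumulative radius r_t = pith_offset + Σ widths the basal area increment is
BAI_t = π (r_t² − r_{t−1}²), the annual cross-sectional area added by the
stem; its natural log (BAI_ln) is the growth response used in the
mixed-effects models.

Canopy-disturbance releases are detected with the boundary-line method:
percent growth change PGC_t = 100·(M2 − M1)/M1 compares mean ring width of
the following `window` years (M2) with the preceding `window` years (M1);
the boundary line — the maximum growth response attainable at a given prior
growth rate — is estimated as the mean of the top decile of PGC within
equal-count bins of prior growth, smoothed by a negative-exponential fit.
Years where PGC strictly exceeds a fraction (default 50%) of the boundary
value at their prior growth are release years; consecutive release years
merge into one event with its peak recorded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

logger = logging.getLogger("dendro_isophys")

_STOP_001 = 999      # stop marker for 0.01 mm files
_STOP_0001 = -9999   # stop marker for 0.001 mm files


class RWLError(ValueError):
    """Malformed Tucson/RWL content."""


def read_rwl(path) -> pd.DataFrame:
    """Read a Tucson/RWL decadal ring-width file.

    Returns a frame with columns ``tree_id, year, width_mm, cambial_age``;
    cambial age counts from 1 at each series' innermost measured ring.  The
    unit flag is taken from the stop marker (999 -> 0.01 mm, -9999 ->
    0.001 mm); a series without stop marker defaults to 0.01 mm.
    """
    series: dict[str, dict[int, int]] = {}
    stopped: dict[str, int] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            sid = line[:8].strip()
            rest = line[8:].split()
            if not sid or len(rest) < 2:
                raise RWLError(f"malformed decade line {lineno}: {line!r}")
            try:
                decade_year = int(rest[0])
                values = [int(v) for v in rest[1:]]
            except ValueError as exc:
                raise RWLError(f"malformed decade line {lineno}: {exc}") from None
            if sid in stopped:
                raise RWLError(f"line {lineno}: series {sid!r} continues after stop marker "
                               "(duplicate series id?)")
            store = series.setdefault(sid, {})
            for offset, v in enumerate(values):
                if v in (_STOP_001, _STOP_0001):
                    stopped[sid] = v
                    break
                year = decade_year + offset
                if year in store:
                    raise RWLError(f"line {lineno}: duplicate year {year} in series {sid!r}")
                store[year] = v
    frames = []
    for sid, store in series.items():
        scale = 0.001 if stopped.get(sid) == _STOP_0001 else 0.01
        years = np.array(sorted(store), dtype=int)
        if len(years) > 1 and not np.all(np.diff(years) == 1):
            raise RWLError(f"series {sid!r}: non-contiguous years")
        widths = np.array([store[y] for y in years], dtype=float) * scale
        frames.append(pd.DataFrame({
            "tree_id": sid, "year": years, "width_mm": widths,
            "cambial_age": np.arange(1, len(years) + 1),
        }))
    if not frames:
        raise RWLError("no series found")
    return pd.concat(frames, ignore_index=True)


def write_rwl(rings: pd.DataFrame, path, units: float = 0.01) -> None:
    """Write ``tree_id, year, width_mm`` rows as Tucson/RWL decadal lines."""
    stop = _STOP_001 if units == 0.01 else _STOP_0001
    with open(path, "w") as fh:
        for sid, grp in rings.groupby("tree_id", sort=True):
            grp = grp.sort_values("year")
            years = grp["year"].to_numpy(dtype=int)
            vals = np.round(grp["width_mm"].to_numpy() / units).astype(int)
            pairs = list(zip(years, vals)) + [(years[-1] + 1, stop)]
            i = 0
            while i < len(pairs):
                y0 = pairs[i][0]
                n_in_decade = 10 - (y0 % 10)
                chunk = pairs[i:i + n_in_decade]
                cells = "".join(f"{v:6d}" for _, v in chunk)
                fh.write(f"{str(sid)[:8]:<8}{y0:4d}{cells}\n")
                i += len(chunk)


def bai(series: pd.DataFrame, pith_offset: float = 0.0) -> pd.DataFrame:
    """Basal area increment (mm² yr⁻¹) and its natural log for one tree.

    ``series`` holds one tree's ``year, width_mm`` rows; widths accumulate
    onto ``pith_offset`` (estimated missing radius, mm).  Rows with BAI = 0
    carry NaN in ``bai_ln`` (count logged).
    """
    s = series.sort_values("year")
    w = s["width_mm"].to_numpy(dtype=float)
    if np.any(w < 0):
        raise ValueError("negative ring width")
    r = pith_offset + np.cumsum(w)
    r_prev = np.concatenate([[pith_offset], r[:-1]])
    bai_vals = np.pi * (r**2 - r_prev**2)
    with np.errstate(divide="ignore"):
        bai_ln = np.where(bai_vals > 0, np.log(np.where(bai_vals > 0, bai_vals, 1.0)), np.nan)
    n_zero = int(np.sum(bai_vals == 0))
    if n_zero:
        logger.info("bai: %d zero-BAI rows excluded from bai_ln", n_zero)
    return pd.DataFrame({
        "year": s["year"].to_numpy(), "width_mm": w,
        "bai": bai_vals, "bai_ln": bai_ln,
    })


def percent_growth_change(series: pd.DataFrame, window: int = 10) -> pd.DataFrame:
    """Percent growth change per year for one tree's ring-width series.

    PGC_t = 100·(M2 − M1)/M1 with M1 the mean width of the ``window`` years
    ending at t and M2 the mean of the ``window`` years after t.  Returns
    ``year, prior_growth, pgc`` for years where both windows are complete;
    years with M1 = 0 are skipped with a log line.
    """
    s = series.sort_values("year")
    w = s["width_mm"].to_numpy(dtype=float)
    years = s["year"].to_numpy()
    if len(w) < 2 * window:
        raise ValueError(f"series length {len(w)} < 2*window = {2 * window}")
    csum = np.concatenate([[0.0], np.cumsum(w)])
    # t index ranges so that [t-window+1, t] and [t+1, t+window] both exist
    t = np.arange(window - 1, len(w) - window)
    m1 = (csum[t + 1] - csum[t + 1 - window]) / window
    m2 = (csum[t + 1 + window] - csum[t + 1]) / window
    ok = m1 > 0
    if np.any(~ok):
        logger.info("percent_growth_change: %d years skipped (zero prior growth)",
                    int(np.sum(~ok)))
    return pd.DataFrame({
        "year": years[t][ok],
        "prior_growth": m1[ok],
        "pgc": 100.0 * (m2[ok] - m1[ok]) / m1[ok],
    })


@dataclass
class BoundaryLine:
    """Fitted boundary line: callable % boundary as a function of prior growth."""

    bin_centers: np.ndarray
    bin_boundary: np.ndarray
    coef: tuple | None          # (a, b, c) of a·exp(−b·x) + c, None if flat
    flat_value: float | None = None
    warned_extrapolation: bool = field(default=False, repr=False)

    def __call__(self, prior_growth):
        x = np.asarray(prior_growth, dtype=float)
        lo, hi = self.bin_centers[0], self.bin_centers[-1]
        out_of_range = (x < lo) | (x > hi)
        if np.any(out_of_range) and not self.warned_extrapolation:
            logger.info("boundary_line: evaluation outside fitted range clamped")
            self.warned_extrapolation = True
        xc = np.clip(x, lo, hi)
        if self.flat_value is not None:
            vals = np.full_like(xc, self.flat_value)
        else:
            a, b, c = self.coef
            vals = a * np.exp(-b * xc) + c
        return vals if vals.shape else float(vals)


def boundary_line(pgc, prior_growth, n_bins: int = 10,
                  top_fraction: float = 0.1, min_points: int = 50) -> BoundaryLine:
    """Fit the boundary line from pooled (prior growth, PGC) pairs.

    Prior growth is split into ``n_bins`` equal-count bins; each bin
    contributes the mean of its top ``top_fraction`` of PGC values, and a
    negative-exponential curve a·exp(−b·x) + c is fit through the bin points.
    """
    g = np.asarray(prior_growth, dtype=float)
    p = np.asarray(pgc, dtype=float)
    if len(g) != len(p):
        raise ValueError("pgc and prior_growth must be aligned")
    if len(g) < min_points:
        raise ValueError(f"only {len(g)} pairs; pool >= {min_points} pairs across trees")
    order = np.argsort(g, kind="stable")
    g, p = g[order], p[order]
    edges = np.array_split(np.arange(len(g)), n_bins)
    centers, bvals = [], []
    for idx in edges:
        if len(idx) == 0:
            continue
        top_n = max(1, int(np.ceil(top_fraction * len(idx))))
        top = np.sort(p[idx])[-top_n:]
        centers.append(float(np.mean(g[idx])))
        bvals.append(float(np.mean(top)))
    centers = np.asarray(centers)
    bvals = np.asarray(bvals)
    if np.allclose(bvals, bvals[0]):
        return BoundaryLine(centers, bvals, coef=None, flat_value=float(bvals[0]))

    def _negexp(x, a, b, c):
        return a * np.exp(-b * x) + c

    a0 = max(bvals[0] - bvals[-1], 1e-3)
    span = max(centers[-1] - centers[0], 1e-6)
    try:
        coef, _ = curve_fit(_negexp, centers, bvals,
                            p0=[a0, 1.0 / span, max(bvals[-1], 0.0)],
                            bounds=([0.0, 0.0, -np.inf], [np.inf, np.inf, np.inf]),
                            maxfev=10000)
        coef = tuple(float(v) for v in coef)
    except RuntimeError:
        logger.warning("boundary_line: exponential fit failed; using flat mean of bin points")
        return BoundaryLine(centers, bvals, coef=None, flat_value=float(np.mean(bvals)))
    return BoundaryLine(centers, bvals, coef=coef)


def detect_releases(pgc_df: pd.DataFrame, boundary: BoundaryLine,
                    threshold: float = 0.5) -> pd.DataFrame:
    """Flag boundary-line releases and merge consecutive years into events.

    A year is a release year when PGC strictly exceeds ``threshold`` times
    the boundary value at its prior growth.  Returns one row per event with
    start/end years, the peak year and peak PGC.
    """
    if len(pgc_df) == 0:
        return pd.DataFrame(columns=["year_start", "year_end", "peak_year", "peak_pgc"])
    d = pgc_df.sort_values("year")
    years = d["year"].to_numpy()
    p = d["pgc"].to_numpy(dtype=float)
    limit = threshold * np.asarray(boundary(d["prior_growth"].to_numpy()), dtype=float)
    flagged = p > limit
    events = []
    i = 0
    while i < len(years):
        if flagged[i]:
            j = i
            while (j + 1 < len(years) and flagged[j + 1]
                   and years[j + 1] == years[j] + 1):
                j += 1
            seg = slice(i, j + 1)
            peak = int(np.argmax(p[seg]))
            events.append({"year_start": int(years[i]), "year_end": int(years[j]),
                           "peak_year": int(years[seg][peak]),
                           "peak_pgc": float(p[seg][peak])})
            i = j + 1
        else:
            i += 1
    return pd.DataFrame(events, columns=["year_start", "year_end", "peak_year", "peak_pgc"])
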