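"""Species chronologies and piecewise-linear trend-change (breakpoint) fits.

A chronology is the per-year mean of a tree-level variable across trees,
kept only for years where at least a configurable fraction (default 50%) of
the sampled trees contribute.  Trend changes in a chronology are estimated
by segmented (broken-line) regression: the mean is continuous piecewise
linear with 0-2 unknown breakpoints.

The estimator is the iterative linearization of Muggeo: given current
breakpoint guesses ψ, fit OLS on

    y ~ 1 + x + Σ_j (x − ψ_j)_+ + Σ_j γ_j · (−1{x > ψ_j})

and update ψ_j <- ψ_j + γ̂_j / β̂_j (β̂_j the slope-change coefficient)
until the largest |Δψ| falls below tolerance; at convergence γ̂ ≈ 0 and the
working model is the broken line itself.  SE(ψ̂_j) = SE(γ̂_j)/|β̂_j| by the
delta method.  The number of breakpoints is chosen by forward sequential
testing (0->1, then 1->2) with a Davies-type supremum test: the largest
|t|-statistic of an added hinge term over a grid of candidate break
positions, with the p-value from the Davies upper bound for the supremum of
a Gaussian process over an interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


# ---------------------------------------------------------------------------
# chronologies
# ---------------------------------------------------------------------------

def expand_segments(df: pd.DataFrame, value_col: str) -> pd.DataFrame:
    """Annualize pooled segments: one row per covered calendar year.

    Each (tree, segment) row with ``year_start..year_end`` contributes its
    value to every year it covers, so segment chronologies can be averaged
    on a common annual axis.
    """
    reps = (df["year_end"].to_numpy(dtype=int)
            - df["year_start"].to_numpy(dtype=int) + 1)
    out = df.loc[df.index.repeat(reps), ["tree_id", "species", value_col]].copy()
    year = np.concatenate([np.arange(s, e + 1) for s, e in
                           zip(df["year_start"], df["year_end"])]) if len(df) else []
    out["year"] = np.asarray(year, dtype=int)
    return out.reset_index(drop=True)


def build_chronology(per_tree: pd.DataFrame, value_col: str,
                     min_fraction: float = 0.5) -> pd.DataFrame:
    """Per-year mean ± SE across trees, with the minimum-replication rule.

    ``per_tree`` needs columns ``tree_id, year, <value_col>``.  Years where
    fewer than ``min_fraction`` of all trees in the table contribute are
    dropped.  SE is the standard error of the mean across trees.
    """
    d = per_tree.dropna(subset=[value_col])
    if d["tree_id"].nunique() < 2:
        raise ValueError("chronology needs >= 2 trees")
    n_total = d["tree_id"].nunique()
    g = d.groupby("year")[value_col]
    out = pd.DataFrame({
        "year": np.fromiter(g.groups.keys(), dtype=int),
        "mean": g.mean().to_numpy(),
        "se": (g.std(ddof=1) / np.sqrt(g.count())).to_numpy(),
        "n_trees": g.count().to_numpy(),
    }).sort_values("year").reset_index(drop=True)
    keep = out["n_trees"] >= min_fraction * n_total
    return out[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# segmented regression
# ---------------------------------------------------------------------------

@dataclass
class SegmentedFit:
    """Converged broken-line fit with delta-method breakpoint SEs."""

    n_breakpoints: int
    psi: np.ndarray            # breakpoint x-positions, increasing
    psi_se: np.ndarray
    slopes: np.ndarray         # per-segment slopes, left to right
    slopes_se: np.ndarray
    intercept: float
    sigma: float               # residual SD
    rss: float
    n: int
    converged: bool
    n_iter: int
    selection_trace: list = field(default_factory=list)

    def predict(self, x):
        x = np.asarray(x, dtype=float)
        out = self.intercept + self.slopes[0] * x
        for j, psi in enumerate(self.psi):
            out = out + (self.slopes[j + 1] - self.slopes[j]) * np.clip(x - psi, 0, None)
        return out


def _ols(X, y):
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    rss = float(resid @ resid)
    n, p = X.shape
    dof = max(n - p, 1)
    sigma2 = rss / dof
    XtX_inv = np.linalg.pinv(X.T @ X)
    se = np.sqrt(np.clip(np.diag(XtX_inv) * sigma2, 0, None))
    return coef, se, rss, sigma2, XtX_inv


def _fit_at_fixed_psi(x, y, psi):
    """OLS of the broken line with frozen breakpoints; returns full summary."""
    cols = [np.ones_like(x), x] + [np.clip(x - p, 0, None) for p in psi]
    X = np.column_stack(cols)
    coef, se, rss, sigma2, XtX_inv = _ols(X, y)
    k = len(psi)
    slopes = np.cumsum(np.concatenate([[coef[1]], coef[2:2 + k]]))
    # var of cumulative sums of (coef[1], diffs)
    cov = XtX_inv * sigma2
    slopes_se = np.empty(k + 1)
    for m in range(k + 1):
        idx = [1] + list(range(2, 2 + m))
        slopes_se[m] = np.sqrt(max(cov[np.ix_(idx, idx)].sum(), 0.0))
    return coef[0], slopes, slopes_se, rss, np.sqrt(sigma2)


def fit_segmented(x, y, k: int, psi0=None, tol: float = 1e-4,
                  max_iter: int = 100, min_segment: int = 5,
                  n_restarts: int = 5, seed: int = 0) -> SegmentedFit:
    """Broken-line fit with ``k`` breakpoints by iterative linearization.

    ``psi0`` defaults to the {1/(k+1), ..., k/(k+1)} quantiles of x.  If a
    segment is left with fewer than ``min_segment`` points during iteration,
    the fit restarts from seeded random quantiles (up to ``n_restarts``
    times); persistent failure raises.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    order = np.argsort(x, kind="stable")
    x, y = x[order], y[order]
    n = len(x)
    if k == 0:
        intercept, slopes, slopes_se, rss, sigma = _fit_at_fixed_psi(x, y, [])
        return SegmentedFit(0, np.array([]), np.array([]), slopes, slopes_se,
                            float(intercept), sigma, rss, n, True, 0)
    n_min = (k + 1) * min_segment + 1
    if n < n_min:
        raise ValueError(f"need n >= {n_min} points for k={k} breakpoints "
                         f"with min_segment={min_segment}")
    rng = np.random.default_rng(seed)
    if psi0 is None:
        qs = np.arange(1, k + 1) / (k + 1)
        psi0 = np.quantile(x, qs)
    psi0 = np.sort(np.asarray(psi0, dtype=float))

    def _segments_ok(psi):
        edges = np.concatenate([[-np.inf], psi, [np.inf]])
        counts = [np.sum((x > edges[i]) & (x <= edges[i + 1]) if i else
                         (x >= edges[i]) & (x <= edges[i + 1]))
                  for i in range(len(edges) - 1)]
        return all(c >= min_segment for c in counts)

    def _finalize(psi, n_iter):
        # delta-method SE(psi) from one linearization at the final psi
        U = [np.clip(x - p, 0, None) for p in psi]
        V = [-(x > p).astype(float) for p in psi]
        Xfull = np.column_stack([np.ones(n), x] + U + V)
        coef, se, _, _, _ = _ols(Xfull, y)
        beta = coef[2:2 + k]
        se_gamma = se[2 + k:2 + 2 * k]
        psi_se = se_gamma / np.maximum(np.abs(beta), 1e-12)
        intercept, slopes, slopes_se, rss, sigma = _fit_at_fixed_psi(x, y, psi)
        return SegmentedFit(k, np.asarray(psi, dtype=float), psi_se, slopes,
                            slopes_se, float(intercept), sigma, rss, n, True, n_iter)

    last_err = None
    best_psi, best_rss = None, np.inf
    for attempt in range(n_restarts + 1):
        if attempt == 0:
            psi = psi0.copy()
        else:
            qs = np.sort(rng.uniform(0.1, 0.9, size=k))
            psi = np.quantile(x, qs)
        if not _segments_ok(psi):
            continue
        for n_iter in range(1, max_iter + 1):
            U = [np.clip(x - p, 0, None) for p in psi]
            V = [-(x > p).astype(float) for p in psi]
            X = np.column_stack([np.ones(n), x] + U + V)
            coef, se, rss, sigma2, _ = _ols(X, y)
            beta = coef[2:2 + k]
            gamma = coef[2 + k:2 + 2 * k]
            if np.any(np.abs(beta) < 1e-12):
                last_err = "slope-change coefficient collapsed to zero"
                break
            step = gamma / beta
            new_psi = psi + np.clip(step, -(x[-1] - x[0]), x[-1] - x[0])
            new_psi = np.sort(new_psi)
            lo, hi = x[min_segment - 1], x[n - min_segment]
            new_psi = np.clip(new_psi, lo + 1e-9, hi - 1e-9)
            if not _segments_ok(new_psi) or np.any(np.diff(new_psi) <= 0):
                last_err = f"degenerate segment during iteration (psi={new_psi})"
                break
            prof_rss = _fit_at_fixed_psi(x, y, new_psi)[3]
            if prof_rss < best_rss - 1e-12:
                best_rss, best_psi = prof_rss, new_psi.copy()
            delta = np.max(np.abs(new_psi - psi))
            psi = new_psi
            if delta < tol:
                return _finalize(psi, n_iter)
        else:
            last_err = "maximum iterations reached"
    # Oscillating or degenerate iteration: fall back to the exact profile-RSS
    # minimizer over candidate break positions (earliest wins on ties), which
    # is the estimator's defining objective.
    psi_grid = _profile_grid_search(x, y, k, min_segment)
    if psi_grid is None:
        raise RuntimeError(f"segmented fit failed after {n_restarts + 1} starts: {last_err}")
    if best_psi is not None and best_rss < _fit_at_fixed_psi(x, y, psi_grid)[3]:
        psi_grid = best_psi
    return _finalize(np.sort(psi_grid), max_iter)


def _profile_grid_search(x, y, k, min_segment):
    """Exact profile-RSS minimization of breakpoint positions on the x grid."""
    xs = np.unique(x)
    cands = xs[min_segment - 1:len(xs) - min_segment] - 1e-9
    if len(cands) < k:
        return None
    if k == 1:
        rss = np.array([_fit_at_fixed_psi(x, y, [c])[3] for c in cands])
        return np.array([cands[int(np.argmin(rss))]])
    # k == 2: coarse pair scan, then refine each psi on the full grid
    coarse = cands[::max(1, len(cands) // 40)]
    best, best_rss = None, np.inf
    for i, a in enumerate(coarse):
        for b in coarse[i + 1:]:
            if np.sum((x > a) & (x <= b)) < min_segment:
                continue
            r = _fit_at_fixed_psi(x, y, [a, b])[3]
            if r < best_rss - 1e-12:
                best_rss, best = r, [a, b]
    if best is None:
        return None
    for j in range(2):
        for c in cands:
            trial = sorted([c, best[1 - j]])
            if np.sum((x > trial[0]) & (x <= trial[1])) < min_segment:
                continue
            r = _fit_at_fixed_psi(x, y, trial)[3]
            if r < best_rss - 1e-12:
                best_rss, best = r, trial
    return np.asarray(best)


def davies_test(x, y, base_psi=(), n_grid: int = 30,
                min_segment: int = 5) -> dict:
    """Davies supremum test for an (additional) change in slope.

    Fits OLS of the base broken line (breakpoints ``base_psi`` frozen) plus
    one extra hinge at each of ``n_grid`` candidate positions, records the
    t-statistic of the extra slope-change term, and bounds the p-value of
    the supremum via Davies' inequality
    p <= 2·Φ(−M) + V·exp(−M²/2)/sqrt(8π), V the total variation of the
    statistic along the grid.  Returns the p-value, the best candidate
    (earliest grid point on ties) and the statistic path.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    order = np.argsort(x, kind="stable")
    x, y = x[order], y[order]
    n = len(x)
    # candidate breaks on the interior 5-95% quantile range (never closer to
    # the boundary than min_segment points) so short edge segments cannot
    # dominate the supremum by chance
    lo = max(x[min_segment - 1], np.quantile(x, 0.05))
    hi = min(x[n - min_segment], np.quantile(x, 0.95))
    grid = np.linspace(lo, hi, n_grid)
    base_cols = [np.ones(n), x] + [np.clip(x - p, 0, None) for p in base_psi]
    tstats = np.full(n_grid, np.nan)
    for i, c in enumerate(grid):
        X = np.column_stack(base_cols + [np.clip(x - c, 0, None)])
        coef, se, _, _, _ = _ols(X, y)
        if se[-1] > 0:
            tstats[i] = coef[-1] / se[-1]
    valid = np.isfinite(tstats)
    if not np.any(valid):
        return {"p_value": 1.0, "psi_best": float(grid[0]), "stat": 0.0,
                "grid": grid, "tstats": tstats}
    tv = tstats[valid]
    M = float(np.max(np.abs(tv)))
    best_idx = int(np.flatnonzero(np.abs(tv) == np.max(np.abs(tv)))[0])
    V = float(np.sum(np.abs(np.diff(tv))))
    p = 2.0 * stats.norm.sf(M) + V * np.exp(-M * M / 2.0) / np.sqrt(8.0 * np.pi)
    return {"p_value": float(min(max(p, 0.0), 1.0)),
            "psi_best": float(np.asarray(grid[valid])[best_idx]),
            "stat": M, "grid": grid, "tstats": tstats}


def select_n_breakpoints(x, y, max_k: int = 2, alpha: float = 0.05,
                         min_segment: int = 5, seed: int = 0,
                         **fit_kwargs) -> SegmentedFit:
    """Forward sequential choice of 0-``max_k`` breakpoints.

    Tests 0->1 and, if rejected, 1->2 with the Davies supremum test, stopping
    at the first non-rejection; returns the selected broken-line fit with
    the test trace attached.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    trace = []
    current = fit_segmented(x, y, 0)
    if max_k >= 1:
        t1 = davies_test(x, y, min_segment=min_segment)
        trace.append({"step": "0->1", "stat": t1["stat"], "p_value": t1["p_value"],
                      "psi_best": t1["psi_best"]})
        if t1["p_value"] < alpha:
            try:
                fit1 = fit_segmented(x, y, 1, psi0=[t1["psi_best"]],
                                     min_segment=min_segment, seed=seed, **fit_kwargs)
                current = fit1
            except (RuntimeError, ValueError) as exc:
                trace.append({"step": "fit k=1", "error": str(exc)})
    if current.n_breakpoints == 1 and max_k >= 2:
        t2 = davies_test(x, y, base_psi=tuple(current.psi), min_segment=min_segment)
        trace.append({"step": "1->2", "stat": t2["stat"], "p_value": t2["p_value"],
                      "psi_best": t2["psi_best"]})
        if t2["p_value"] < alpha:
            psi0 = np.sort(np.concatenate([current.psi, [t2["psi_best"]]]))
            if psi0[1] - psi0[0] > 1e-9:
                try:
                    fit2 = fit_segmented(x, y, 2, psi0=psi0,
                                         min_segment=min_segment, seed=seed, **fit_kwargs)
                    current = fit2
                except (RuntimeError, ValueError) as exc:
                    trace.append({"step": "fit k=2", "error": str(exc)})
    current.selection_trace = trace
    return current


def slope_report(fit: SegmentedFit, scale: str = "per-year") -> pd.DataFrame:
    """Tabulate per-segment slopes ± SE and breakpoint years ± SE.

    ``scale`` is ``per-year`` or ``per-decade`` (×10).
    """
    if not fit.converged:
        raise ValueError("slope_report requires a converged fit")
    factor = {"per-year": 1.0, "per-decade": 10.0}[scale]
    rows = []
    bounds = [np.nan] + list(fit.psi) + [np.nan]
    for m, (slope, se) in enumerate(zip(fit.slopes, fit.slopes_se)):
        rows.append({
            "segment": m + 1,
            "from": bounds[m], "to": bounds[m + 1],
            "slope": slope * factor, "slope_se": se * factor,
            "breakpoint": fit.psi[m] if m < fit.n_breakpoints else np.nan,
            "breakpoint_se": fit.psi_se[m] if m < fit.n_breakpoints else np.nan,
        })
    return pd.DataFrame(rows)
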