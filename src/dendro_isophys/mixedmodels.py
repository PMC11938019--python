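"""AR(1) random-intercept mixed models, AICc all-subsets and model averaging.

The attribution models regress a tree-ring response (iWUE, δ15N or BAI_ln)
on Z-scored environmental drivers with a per-tree random intercept and an
AR(1) within-tree error process, fitted by maximum likelihood:

    y_gt = x_gt' β + b_g + e_gt,   b_g ~ N(0, σ_b²),
    Corr(e_gt, e_gs) = ρ^{|t−s|},  e ~ N(0, σ²),

so each tree's covariance is Σ_g = σ_b² J + σ² R(ρ).  Time distances are in
native sampling steps (1 for annual series, 1 per pooled 5-year segment).
The likelihood is profiled: for a given (ρ, λ = σ_b²/σ²) each group is
whitened with the AR(1) innovations transform, the random intercept handled
by a rank-one (Sherman-Morrison) update, β by GLS and σ² in closed form —
leaving a 2-parameter numerical optimization.

Model selection mirrors the common ecology workflow: every
marginality-respecting subset of the main effects and CO2 interactions is
fitted, ranked by AICc, and the ΔAICc < 2 set is combined by conditional
("natural") model averaging with unconditional SEs that include the
between-model spread.  Marginal/conditional R² (fixed vs fixed+random
variance fractions), VIF and a PCA summary complete the reporting surface.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .environment import Standardizer

logger = logging.getLogger("dendro_isophys")

RHO_MAX = 0.99
N_COV_PARAMS = 3  # sigma_b, sigma, rho


# ---------------------------------------------------------------------------
# model specification and design
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """Fixed-effect structure: main effects and CO2 ('ca') interactions.

    Interactions are written ``"ca:term"`` and require both mains present
    (marginality).
    """

    response: str
    mains: tuple = ()
    interactions: tuple = ()

    def __post_init__(self):
        for ia in self.interactions:
            if not ia.startswith("ca:"):
                raise ValueError(f"interactions must be with ca: {ia!r}")
            partner = ia.split(":", 1)[1]
            if "ca" not in self.mains or partner not in self.mains:
                raise ValueError(f"marginality violated for {ia!r}")

    @property
    def terms(self) -> tuple:
        return tuple(self.mains) + tuple(self.interactions)


def build_design(data: pd.DataFrame, spec: ModelSpec,
                 standardize: bool = True):
    """Design matrix, grouping and time index for :func:`fit_lme_ar1`.

    ``data`` holds one row per observation with columns ``tree_id, time``
    (integer index in native sampling steps), the response, and every main
    effect.  The binary ``cellulose`` indicator (if used) is passed through
    unscaled; other mains are Z-scored (sample SD) and interactions are
    products of the Z-scored mains.  Returns
    ``(X, y, groups, times, standardizers)`` with X a DataFrame whose first
    column is the intercept.
    """
    used = ["tree_id", "time", spec.response, *spec.mains]
    missing_cols = [c for c in used if c not in data.columns]
    if missing_cols:
        raise ValueError(f"missing columns: {missing_cols}")
    bad = data[used].isna().any(axis=1)
    if bad.any():
        raise ValueError(f"missing values in rows {list(data.index[bad][:10])}")
    cols = {"Intercept": np.ones(len(data))}
    standardizers: dict[str, Standardizer] = {}
    for m in spec.mains:
        v = data[m].to_numpy(dtype=float)
        if standardize and m != "cellulose":
            mean, sd = float(np.mean(v)), float(np.std(v, ddof=1))
            if sd == 0:
                raise ValueError(f"zero variance in predictor {m!r}")
            standardizers[m] = Standardizer(mean, sd)
            v = (v - mean) / sd
        cols[m] = v
    for ia in spec.interactions:
        partner = ia.split(":", 1)[1]
        cols[ia] = cols["ca"] * cols[partner]
    X = pd.DataFrame(cols, index=data.index)
    y = data[spec.response].to_numpy(dtype=float)
    return X, y, data["tree_id"].to_numpy(), data["time"].to_numpy(), standardizers


# ---------------------------------------------------------------------------
# AR(1) random-intercept ML fit
# ---------------------------------------------------------------------------

@dataclass
class LMEFit:
    """Maximum-likelihood fit of the AR(1) random-intercept model."""

    beta: pd.Series
    se: pd.Series
    cov_beta: np.ndarray
    sigma_b: float
    sigma: float
    rho: float
    loglik: float
    n: int
    k: int                      # fixed effects + 3 covariance parameters
    converged: bool
    spec: ModelSpec | None = None
    X_columns: tuple = ()
    fitted_fixed: np.ndarray | None = field(default=None, repr=False)

    @property
    def aicc(self) -> float:
        return aicc(self)


def _group_arrays(X, y, groups, times):
    """Stack observations sorted by (group, time) with first-row flags.

    Returns ``(Xv, yv, d, first, starts)`` where ``d`` holds the time lag to
    the previous row within the same group (1 at group firsts, unused there)
    and ``starts`` indexes group beginnings for reduceat sums.
    """
    Xv = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups)
    times = np.asarray(times, dtype=float)
    codes, _ = pd.factorize(groups, sort=False)
    order = np.lexsort((times, codes))
    Xv, y, codes, times = Xv[order], y[order], codes[order], times[order]
    first = np.empty(len(y), dtype=bool)
    first[0] = True
    first[1:] = codes[1:] != codes[:-1]
    d = np.ones(len(y))
    d[1:] = times[1:] - times[:-1]
    d[first] = 1.0
    if np.any(d <= 0):
        g = groups[order][np.flatnonzero(d <= 0)[0]]
        raise ValueError(f"group {g!r}: times not strictly increasing")
    starts = np.flatnonzero(first)
    return Xv, y, d, first, starts


def _profiled_nll(rho, lam, gdata, p):
    """−logLik profiled over β and σ²; also returns β̂, σ̂², A=X'Σ̃⁻¹X.

    AR(1) whitening is applied to the stacked arrays in one pass (the
    first-row mask zeroes cross-group terms); the random intercept is a
    rank-one Sherman-Morrison correction accumulated per group via reduceat.
    """
    Xv, y, d, first, starts = gdata
    n = len(y)
    r = rho ** d
    r[first] = 0.0
    scale2 = np.clip(1.0 - r * r, 1e-12, None)
    scale = np.sqrt(scale2)
    Xprev = np.empty_like(Xv)
    Xprev[0] = 0.0
    Xprev[1:] = Xv[:-1]
    yprev = np.empty_like(y)
    yprev[0] = 0.0
    yprev[1:] = y[:-1]
    Xw = (Xv - r[:, None] * Xprev) / scale[:, None]
    yw = (y - r * yprev) / scale
    u = (1.0 - r) / scale
    logdet = float(np.sum(np.log(scale2[~first])))
    s = np.add.reduceat(u * u, starts)
    kappa = lam / (1.0 + lam * s)
    Xu = np.add.reduceat(Xw * u[:, None], starts, axis=0)      # G x p
    yu = np.add.reduceat(yw * u, starts)
    A = Xw.T @ Xw - (Xu * kappa[:, None]).T @ Xu
    bvec = Xw.T @ yw - Xu.T @ (kappa * yu)
    c = float(yw @ yw) - float(kappa @ (yu * yu))
    logdet += float(np.sum(np.log1p(lam * s)))
    beta = np.linalg.solve(A, bvec)
    rss = max(c - float(beta @ bvec), 1e-300)
    sigma2 = rss / n
    nll = 0.5 * (n * np.log(2.0 * np.pi * sigma2) + logdet + n)
    return nll, beta, sigma2, A


def fit_lme_ar1(X, y, groups, times, spec: ModelSpec | None = None,
                fix_rho: float | None = None,
                fix_lambda: float | None = None,
                start: tuple[float, float] | None = None) -> LMEFit:
    """ML fit of the AR(1) random-intercept model.

    ``times`` must be strictly increasing integers (or evenly comparable
    reals) within each group; lag-1 in ``times`` means one native sampling
    step.  ``fix_rho``/``fix_lambda`` freeze ρ or λ = σ_b²/σ² (λ = 0 and
    ρ = 0 reduce the fit exactly to OLS); ``start`` warm-starts the
    optimizer at a (ρ, λ) guess.
    """
    colnames = tuple(X.columns) if isinstance(X, pd.DataFrame) else \
        tuple(f"x{i}" for i in range(np.asarray(X).shape[1]))
    gdata = _group_arrays(X, y, groups, times)
    if len(gdata[4]) < 2 and fix_lambda is None:
        raise ValueError("need >= 2 groups to estimate a random intercept")
    p = gdata[0].shape[1]
    n = len(gdata[1])

    def unpack(theta):
        i = 0
        if fix_rho is None:
            rho = RHO_MAX * np.tanh(theta[i]); i += 1
        else:
            rho = float(fix_rho)
        if fix_lambda is None:
            lam = float(np.exp(np.clip(theta[i], -30, 30)))
        else:
            lam = float(fix_lambda)
        return rho, lam

    n_free = (fix_rho is None) + (fix_lambda is None)
    if n_free == 0:
        rho, lam = float(fix_rho), float(fix_lambda)
        nll, beta, sigma2, A = _profiled_nll(rho, lam, gdata, p)
        success = True
    else:
        def obj(theta):
            rho, lam = unpack(theta)
            return _profiled_nll(rho, lam, gdata, p)[0]

        theta_starts = [np.zeros(n_free), np.full(n_free, 0.5),
                        np.full(n_free, -1.0)]
        if start is not None:
            s0 = []
            if fix_rho is None:
                s0.append(np.arctanh(np.clip(start[0] / RHO_MAX, -0.999, 0.999)))
            if fix_lambda is None:
                s0.append(np.log(max(start[1], 1e-8)))
            theta_starts.insert(0, np.array(s0))
        best = None
        for s0 in theta_starts:
            res = optimize.minimize(obj, s0, method="Nelder-Mead",
                                    options={"xatol": 1e-4, "fatol": 1e-7,
                                             "maxiter": 400 * n_free})
            if best is None or res.fun < best.fun - 1e-10:
                best = res
            if best.success:
                break
        if best is None or not np.isfinite(best.fun):
            raise RuntimeError(f"LME optimizer failed: {best}")
        success = bool(best.success)
        rho, lam = unpack(best.x)
        nll, beta, sigma2, A = _profiled_nll(rho, lam, gdata, p)
    cov_beta = sigma2 * np.linalg.inv(A)
    se = np.sqrt(np.clip(np.diag(cov_beta), 0, None))
    Xall = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    return LMEFit(
        beta=pd.Series(beta, index=colnames),
        se=pd.Series(se, index=colnames),
        cov_beta=cov_beta,
        sigma_b=float(np.sqrt(lam * sigma2)),
        sigma=float(np.sqrt(sigma2)),
        rho=float(rho),
        loglik=float(-nll),
        n=n, k=p + N_COV_PARAMS,
        converged=success,
        spec=spec, X_columns=colnames,
        fitted_fixed=Xall @ beta,
    )


def aicc(fit_or_loglik, k: int | None = None, n: int | None = None) -> float:
    """Small-sample corrected Akaike criterion.

    AICc = −2·logLik + 2k + 2k(k+1)/(n − k − 1); requires n > k + 1.
    """
    if k is None:
        loglik, k, n = fit_or_loglik.loglik, fit_or_loglik.k, fit_or_loglik.n
    else:
        loglik = float(fit_or_loglik)
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n} <= k+1={k + 1}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


# ---------------------------------------------------------------------------
# all-subsets selection and model averaging
# ---------------------------------------------------------------------------

def all_subsets(full_spec: ModelSpec, max_models: int = 4096) -> list[ModelSpec]:
    """Every marginality-respecting subset of the full spec's terms."""
    mains = list(full_spec.mains)
    specs = []
    for r in range(len(mains) + 1):
        for msub in itertools.combinations(mains, r):
            allowed = [ia for ia in full_spec.interactions
                       if "ca" in msub and ia.split(":", 1)[1] in msub]
            for ri in range(len(allowed) + 1):
                for isub in itertools.combinations(allowed, ri):
                    specs.append(ModelSpec(full_spec.response, msub, isub))
    if len(specs) > max_models:
        raise ValueError(f"{len(specs)} candidate models exceed cap {max_models}; "
                         "pass a larger max_models explicitly")
    return specs


def fit_model_set(data: pd.DataFrame, full_spec: ModelSpec,
                  max_models: int = 4096) -> list[LMEFit]:
    """Fit every valid submodel of ``full_spec`` on shared data.

    The full design is built once; submodels select columns from it so all
    fits share identical Z-scoring.
    """
    Xfull, y, groups, times, _ = build_design(data, full_spec)
    full_fit = fit_lme_ar1(Xfull, y, groups, times, spec=full_spec)
    warm = (full_fit.rho, (full_fit.sigma_b / full_fit.sigma) ** 2
            if full_fit.sigma > 0 else 1.0)
    fits = []
    for spec in all_subsets(full_spec, max_models=max_models):
        if spec.terms == full_spec.terms:
            fits.append(full_fit)
            continue
        X = Xfull[["Intercept", *spec.terms]]
        try:
            fits.append(fit_lme_ar1(X, y, groups, times, spec=spec, start=warm))
        except (RuntimeError, np.linalg.LinAlgError) as exc:
            logger.warning("submodel %s failed: %s", spec.terms, exc)
    if not fits:
        raise RuntimeError("no submodel converged")
    return fits


@dataclass
class AveragedModel:
    """Conditional model average over the ΔAICc-retained set."""

    table: pd.DataFrame        # per-term estimate, se, z, p, n_models, weight_sum
    models: pd.DataFrame       # the full AICc table with weights
    best: LMEFit
    n: int
    marginal_r2: float
    conditional_r2: float


def model_average(fits: list[LMEFit], delta_threshold: float = 2.0) -> AveragedModel:
    """Average fixed effects over models with ΔAICc below the threshold.

    Retained models get Akaike weights w ∝ exp(−Δ/2).  Each term is averaged
    conditionally — over the retained models that contain it, with weights
    renormalized to that subset — and its unconditional SE includes the
    between-model variance: Var = Σ w̃ (SE_m² + (β_m − β̄)²).  z = |β̄|/SE
    with a two-tailed normal p-value.
    """
    fits = [f for f in fits if f.converged or True]
    aiccs = np.array([aicc(f) for f in fits])
    delta = aiccs - aiccs.min()
    retained = delta < delta_threshold
    w = np.where(retained, np.exp(-delta / 2.0), 0.0)
    w = w / w.sum()
    best_idx = int(np.argmin(aiccs))
    best = fits[best_idx]

    models = pd.DataFrame({
        "terms": [", ".join(f.spec.terms) if f.spec else ", ".join(f.X_columns[1:])
                  for f in fits],
        "k": [f.k for f in fits],
        "loglik": [f.loglik for f in fits],
        "aicc": aiccs, "delta": delta, "weight": w, "retained": retained,
    }).sort_values("aicc").reset_index(drop=True)

    terms: list[str] = []
    for f, r in zip(fits, retained):
        if r:
            terms.extend(t for t in f.beta.index if t not in terms)
    rows = []
    for term in terms:
        idx = [i for i, f in enumerate(fits) if retained[i] and term in f.beta.index]
        wt = np.array([w[i] for i in idx])
        wt = wt / wt.sum()
        est_m = np.array([fits[i].beta[term] for i in idx])
        se_m = np.array([fits[i].se[term] for i in idx])
        est = float(wt @ est_m)
        var = float(wt @ (se_m**2 + (est_m - est) ** 2))
        se = np.sqrt(var)
        z = np.abs(est) / se if se > 0 else np.inf
        rows.append({"term": term, "estimate": est, "se": se, "z": z,
                     "p": float(2 * stats.norm.sf(z)), "n_models": len(idx),
                     "weight_sum": float(sum(w[i] for i in idx))})
    table = pd.DataFrame(rows).set_index("term")
    marg, cond = r2_nakagawa(best)
    return AveragedModel(table=table, models=models, best=best, n=best.n,
                         marginal_r2=marg, conditional_r2=cond)


def r2_nakagawa(fit: LMEFit, fitted_fixed=None) -> tuple[float, float]:
    """Marginal and conditional R² of a random-intercept mixed model.

    marginal = var(Xβ̂) / (var(Xβ̂) + σ_b² + σ²); conditional adds σ_b² to
    the numerator.  The AR(1) structure enters only through the σ² estimate.
    """
    f = fit.fitted_fixed if fitted_fixed is None else np.asarray(fitted_fixed, float)
    var_f = float(np.var(f, ddof=0))
    tot = var_f + fit.sigma_b**2 + fit.sigma**2
    return var_f / tot, (var_f + fit.sigma_b**2) / tot


def vif(X: pd.DataFrame) -> pd.DataFrame:
    """Variance inflation factor per continuous predictor column.

    VIF_j = 1/(1 − R²_j) from regressing column j on the others (with
    intercept); exact collinearity reports inf.  The flag column marks
    VIF > 5.
    """
    if X.shape[1] < 2:
        raise ValueError("need >= 2 predictors")
    vals = {}
    A = X.to_numpy(dtype=float)
    for j, name in enumerate(X.columns):
        yj = A[:, j]
        Xo = np.column_stack([np.ones(len(A)), np.delete(A, j, axis=1)])
        coef, _, _, _ = np.linalg.lstsq(Xo, yj, rcond=None)
        resid = yj - Xo @ coef
        ss_res = float(resid @ resid)
        ss_tot = float(np.sum((yj - yj.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        vals[name] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    out = pd.DataFrame({"vif": pd.Series(vals)})
    out["high_collinearity"] = out["vif"] > 5.0
    return out


@dataclass
class PCASummary:
    loadings: pd.DataFrame
    scores: pd.DataFrame
    explained: pd.Series       # variance fractions, sum to 1


def pca_summary(table: pd.DataFrame) -> PCASummary:
    """PCA of the correlation matrix with deterministic component signs.

    Components are ordered by decreasing eigenvalue; each is signed so that
    its largest-|loading| variable loads positively.
    """
    d = table.dropna()
    Z = np.column_stack([(d[c] - d[c].mean()) / d[c].std(ddof=1) for c in d.columns])
    corr = np.corrcoef(Z, rowvar=False)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = np.clip(eigval[order], 0, None), eigvec[:, order]
    for j in range(eigvec.shape[1]):
        lead = int(np.argmax(np.abs(eigvec[:, j])))
        if eigvec[lead, j] < 0:
            eigvec[:, j] *= -1.0
    names = [f"PC{i + 1}" for i in range(len(eigval))]
    loadings = pd.DataFrame(eigvec, index=d.columns, columns=names)
    scores = pd.DataFrame(Z @ eigvec, index=d.index, columns=names)
    return PCASummary(loadings=loadings, scores=scores,
                      explained=pd.Series(eigval / eigval.sum(), index=names))


# ---------------------------------------------------------------------------
# coefficient basis conversion
# ---------------------------------------------------------------------------

def zcoefs_to_raw(coefs: dict, standardizers: dict) -> dict:
    """Convert Z-basis coefficients to raw covariate units.

    ``coefs`` maps 'Intercept', mains and 'ca:term' interactions to their
    values in the Z basis defined by ``standardizers`` (terms without a
    standardizer, e.g. a binary indicator, pass through with mean 0, SD 1).
    The raw basis is the polynomial {1, x_j, x_ca·x_k}; conversion expands
    each Z product and is exactly invertible by :func:`raw_to_zcoefs`.
    """
    def ms(name):
        st = standardizers.get(name)
        return (st.mean, st.sd) if st is not None else (0.0, 1.0)

    ints = {t: v for t, v in coefs.items() if ":" in t}
    mains = {t: v for t, v in coefs.items() if ":" not in t and t != "Intercept"}
    m_ca, s_ca = ms("ca")
    raw: dict = {}
    for t, b in ints.items():
        k = t.split(":", 1)[1]
        m_k, s_k = ms(k)
        raw[t] = b / (s_ca * s_k)
    for j, b in mains.items():
        m_j, s_j = ms(j)
        c = b / s_j
        if j == "ca":
            for t, b_int in ints.items():
                k = t.split(":", 1)[1]
                m_k, s_k = ms(k)
                c -= b_int * m_k / (s_ca * s_k)
        elif f"ca:{j}" in ints:
            c -= ints[f"ca:{j}"] * m_ca / (s_ca * s_j)
        raw[j] = c
    c0 = coefs.get("Intercept", 0.0)
    for j, b in mains.items():
        m_j, s_j = ms(j)
        c0 -= b * m_j / s_j
    for t, b_int in ints.items():
        k = t.split(":", 1)[1]
        m_k, s_k = ms(k)
        c0 += b_int * m_ca * m_k / (s_ca * s_k)
    raw["Intercept"] = c0
    return raw


def raw_to_zcoefs(raw: dict, standardizers: dict) -> dict:
    """Inverse of :func:`zcoefs_to_raw` for a (possibly different) Z basis."""
    def ms(name):
        st = standardizers.get(name)
        return (st.mean, st.sd) if st is not None else (0.0, 1.0)

    ints = {t: v for t, v in raw.items() if ":" in t}
    mains = {t: v for t, v in raw.items() if ":" not in t and t != "Intercept"}
    m_ca, s_ca = ms("ca")
    out: dict = {}
    b_ints = {}
    for t, c in ints.items():
        k = t.split(":", 1)[1]
        m_k, s_k = ms(k)
        b_ints[t] = c * s_ca * s_k
        out[t] = b_ints[t]
    for j, c in mains.items():
        m_j, s_j = ms(j)
        b = s_j * c
        if j == "ca":
            for t, b_int in b_ints.items():
                k = t.split(":", 1)[1]
                m_k, s_k = ms(k)
                b += b_int * m_k / s_k
        elif f"ca:{j}" in b_ints:
            b += b_ints[f"ca:{j}"] * m_ca / s_ca
        out[j] = b
    b0 = raw.get("Intercept", 0.0)
    for j in mains:
        m_j, s_j = ms(j)
        b0 += out[j] * m_j / s_j
    for t, b_int in b_ints.items():
        k = t.split(":", 1)[1]
        m_k, s_k = ms(k)
        b0 -= b_int * m_ca * m_k / (s_ca * s_k)
    out["Intercept"] = b0
    return out
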