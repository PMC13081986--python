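"""Differential-morphometry statistics for perturbation screens.

The workhorse is a random-intercept linear mixed model per metric:
``metric ~ perturbation + (1 | brain)``, fit by REML, with a Wald t-test on
each perturbation coefficient.  Metrics are z-scored within the analysis
cohort before fitting, so effects are standardized mean differences.
Degrees of freedom use a between-within (containment) approximation,
``df = n_brains - rank(X)``, which coincides with Satterthwaite's estimate on
the balanced nested designs simulated here.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1).

    NaNs are propagated and excluded from the adjustment."""
    p = np.asarray(pvals, dtype=float)
    out = np.full_like(p, np.nan)
    mask = ~np.isnan(p)
    pm = p[mask]
    n = pm.size
    if n == 0:
        return out
    order = np.argsort(pm, kind="mergesort")
    ranked = pm[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    res = np.empty(n)
    res[order] = np.minimum(adj, 1.0)
    out[mask] = res
    return out


# ---------------------------------------------------------------------------
# linear mixed model
# ---------------------------------------------------------------------------

@dataclass
class LMMFit:
    """Per-contrast fixed-effect estimates from one mixed-model fit."""

    table: pd.DataFrame         # index: group label; effect, se, p, df
    method: str                 # "lmm" or "ols"
    brain_variance: float
    residual_variance: float


def reml_random_intercept(y: np.ndarray, X: np.ndarray, groups: np.ndarray):
    """Profiled REML for ``y = X beta + b_group + e`` with a single random
    intercept.

    The variance ratio ``lambda = var_b / var_e`` is profiled out: for fixed
    lambda the per-group covariance ``I + lambda * J`` inverts in closed form
    (Woodbury), giving GLS estimates and the restricted likelihood as a 1-D
    function maximized by bounded scalar search.  Returns
    (beta, cov_beta, var_brain, var_resid, lambda).
    """
    from scipy import optimize

    y = np.asarray(y, float)
    n, p = X.shape
    codes, inv = np.unique(groups, return_inverse=True)
    blocks = [np.flatnonzero(inv == i) for i in range(len(codes))]
    pre = []
    for idx in blocks:
        Xi, yi = X[idx], y[idx]
        pre.append((len(idx), Xi.T @ Xi, Xi.T @ yi, float(yi @ yi),
                    Xi.sum(axis=0), float(yi.sum())))

    def profile(lam: float):
        XtVX = np.zeros((p, p))
        XtVy = np.zeros(p)
        ytVy = 0.0
        logdetV = 0.0
        for ni, XtX, Xty, yty, sx, sy in pre:
            c = lam / (1.0 + lam * ni)
            XtVX += XtX - c * np.outer(sx, sx)
            XtVy += Xty - c * sx * sy
            ytVy += yty - c * sy * sy
            logdetV += math.log1p(lam * ni)
        beta = np.linalg.solve(XtVX, XtVy)
        rss = ytVy - 2.0 * beta @ XtVy + beta @ XtVX @ beta
        sigma2 = max(rss / (n - p), 1e-300)
        sign, logdet_xvx = np.linalg.slogdet(XtVX)
        ll = -0.5 * ((n - p) * (1.0 + math.log(2.0 * math.pi * sigma2))
                     + logdetV + logdet_xvx)
        return ll, beta, XtVX, sigma2

    def neg(loglam: float) -> float:
        return -profile(math.exp(loglam))[0]

    res = optimize.minimize_scalar(neg, bounds=(math.log(1e-10), math.log(1e6)),
                                   method="bounded", options={"xatol": 1e-8})
    lam = math.exp(res.x)
    if profile(0.0)[0] >= profile(lam)[0]:
        lam = 0.0
    ll, beta, XtVX, sigma2 = profile(lam)
    cov = sigma2 * np.linalg.inv(XtVX)
    return beta, cov, lam * sigma2, sigma2, lam


def fit_lmm(values, group_labels, brain_ids, ref_group) -> LMMFit:
    """Fit ``value ~ group + (1 | brain)`` by REML and test each non-reference
    group against ``ref_group`` (Wald t, containment df).

    Missing values are dropped.  When the random-effect variance is
    unidentifiable (a group confined entirely to a single brain that carries
    no other group, or a degenerate fit), falls back to ordinary least
    squares with a warning.
    """
    import statsmodels.api as sm

    df = pd.DataFrame({"y": np.asarray(values, float),
                       "group": np.asarray(group_labels, dtype=object),
                       "brain": np.asarray(brain_ids, dtype=object)}).dropna()
    groups = [g for g in pd.unique(df["group"])]
    if ref_group not in groups:
        raise ValueError(f"reference group {ref_group!r} absent")
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if df["brain"].nunique() < 2:
        raise ValueError("need at least 2 brains")
    alts = [g for g in groups if g != ref_group]
    X = np.column_stack([np.ones(len(df))] +
                        [(df["group"] == g).to_numpy(float) for g in alts])
    n_brains = df["brain"].nunique()
    dof = max(n_brains - X.shape[1], 1)

    # unidentifiable layout: some group sits in one brain that is exclusively
    # its own, so the group effect and the brain intercept are confounded
    confounded = False
    for g in groups:
        brains_g = df.loc[df["group"] == g, "brain"].unique()
        if len(brains_g) == 1:
            others = df.loc[df["brain"] == brains_g[0], "group"].nunique()
            if others == 1:
                confounded = True

    method = "lmm"
    try:
        if confounded:
            raise ValueError("group confounded with a single brain")
        params, cov, brain_var, resid_var, _lam = reml_random_intercept(
            df["y"].to_numpy(), X, df["brain"].to_numpy())
        bse = np.sqrt(np.diag(cov))
        if not np.all(np.isfinite(bse)):
            raise ValueError("non-finite standard errors")
    except Exception:
        warnings.warn("mixed model unidentifiable; falling back to OLS",
                      stacklevel=2)
        method = "ols"
        ols = sm.OLS(df["y"].to_numpy(), X).fit()
        params, bse = ols.params, ols.bse
        brain_var, resid_var = 0.0, float(ols.mse_resid)
        dof = int(ols.df_resid)

    rows = []
    for i, g in enumerate(alts, start=1):
        t = params[i] / bse[i]
        p = 2.0 * sps.t.sf(abs(t), dof)
        n_alt = int((df["group"] == g).sum())
        rows.append({"group": g, "effect": float(params[i]), "se": float(bse[i]),
                     "p": float(p), "df": dof,
                     "n_ref": int((df["group"] == ref_group).sum()),
                     "n_alt": n_alt})
    return LMMFit(table=pd.DataFrame(rows).set_index("group"), method=method,
                  brain_variance=brain_var, residual_variance=resid_var)


def differential_morphometry(table: pd.DataFrame, metadata: pd.DataFrame,
                             ref_group: str, panel: list[str] | None = None,
                             group_col: str = "perturbation",
                             brain_col: str = "brain_id",
                             standardize: str = "model") -> pd.DataFrame:
    """Per-metric mixed-model screen with BH adjustment across metrics
    within each contrast.

    ``table`` is neurons x metrics (raw, possibly with missing values —
    neurons missing a metric are excluded from that metric's model);
    ``metadata`` is indexed like ``table`` with perturbation and brain
    columns.  ``standardize`` controls the effect scale: ``model`` (default)
    divides the raw coefficient by the model's total SD
    ``sqrt(var_brain + var_resid)`` — an unbiased standardized mean
    difference even under large effects; ``cohort`` z-scores each metric over
    the whole cohort before fitting (inflated slightly by the effect itself);
    ``none`` reports raw units.
    """
    if standardize not in ("model", "cohort", "none"):
        raise ValueError("standardize must be 'model', 'cohort', or 'none'")
    metrics = list(panel) if panel is not None else list(table.columns)
    meta = metadata.loc[table.index]
    rows = []
    for m in metrics:
        y = table[m].astype(float)
        ok = y.notna()
        cohort_sd = y[ok].std(ddof=1)
        if not np.isfinite(cohort_sd) or cohort_sd == 0:
            continue                    # constant metric: no contrast to test
        if standardize == "cohort":
            y = (y - y[ok].mean()) / cohort_sd
        try:
            fit = fit_lmm(y[ok], meta.loc[ok, group_col], meta.loc[ok, brain_col],
                          ref_group)
        except ValueError:
            continue
        scale = 1.0
        if standardize == "model":
            total_sd = math.sqrt(fit.brain_variance + fit.residual_variance)
            # guard against numerically zero residual variance (metrics that
            # are constant up to the group/brain structure)
            if not np.isfinite(total_sd) or total_sd <= 1e-9 * cohort_sd:
                continue
            scale = 1.0 / total_sd
        for g, r in fit.table.iterrows():
            rows.append({"feature": m, "contrast": f"{g} vs {ref_group}",
                         "group": g, "effect": r["effect"] * scale,
                         "se": r["se"] * scale,
                         "p": r["p"], "n_ref": r["n_ref"], "n_alt": r["n_alt"],
                         "method": fit.method})
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adj"] = np.nan
        for c in out["contrast"].unique():
            sel = out["contrast"] == c
            out.loc[sel, "p_adj"] = bh_adjust(out.loc[sel, "p"])
    return out


# ---------------------------------------------------------------------------
# Sholl radius-wise tests
# ---------------------------------------------------------------------------

def sholl_radius_tests(profiles_by_group: dict[str, list]) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum test per Sholl radius between two groups
    (neurons as replicates), BH-corrected across radii.

    Profiles shorter than the longest grid are zero-padded (a neuron that
    does not reach a shell crosses it zero times).
    """
    if len(profiles_by_group) != 2:
        raise ValueError("exactly two groups required")
    (ga, profs_a), (gb, profs_b) = profiles_by_group.items()
    if not profs_a or not profs_b:
        raise ValueError("both groups need profiles")
    step = None
    max_len = 0
    for p in list(profs_a) + list(profs_b):
        if len(p.radii):
            s = float(p.radii[0])
            step = s if step is None else step
            max_len = max(max_len, len(p.radii))
    if step is None:
        raise ValueError("all profiles empty")

    def padded(p):
        out = np.zeros(max_len)
        out[: len(p.intersections)] = p.intersections
        return out

    A = np.array([padded(p) for p in profs_a])
    B = np.array([padded(p) for p in profs_b])
    radii = step * np.arange(1, max_len + 1)
    rows = []
    for i, r in enumerate(radii):
        a, b = A[:, i], B[:, i]
        if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
            p = 1.0
        else:
            p = float(sps.mannwhitneyu(a, b, alternative="two-sided",
                                       method="auto").pvalue)
        rows.append({"radius": r, "effect": float(np.median(b) - np.median(a)),
                     "p": p, "n_ref": len(a), "n_alt": len(b)})
    out = pd.DataFrame(rows)
    out["p_adj"] = bh_adjust(out["p"])
    return out


# ---------------------------------------------------------------------------
# NMF metric modules
# ---------------------------------------------------------------------------

@dataclass
class NMFModel:
    W: np.ndarray                  # neurons x k module scores
    H: np.ndarray                  # k x metrics loadings
    k: int
    error_trace: np.ndarray        # Frobenius error per iteration
    offsets: np.ndarray            # per-metric shift applied before fitting
    scales: np.ndarray             # per-metric sd used for z-scoring
    means: np.ndarray
    seed: int
    metric_names: list = field(default_factory=list)

    @property
    def reconstruction_error(self) -> float:
        return float(self.error_trace[-1])


def _mu_nmf(V: np.ndarray, k: int, rng: np.random.Generator,
            max_iter: int, tol: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n, m = V.shape
    scale = math.sqrt(max(V.mean(), 1e-12) / k)
    W = rng.uniform(0.1, 1.0, (n, k)) * scale
    H = rng.uniform(0.1, 1.0, (k, m)) * scale
    eps = 1e-12
    errs = []
    prev = None
    for _ in range(max_iter):
        H *= (W.T @ V) / (W.T @ W @ H + eps)
        W *= (V @ H.T) / (W @ (H @ H.T) + eps)
        err = float(np.linalg.norm(V - W @ H))
        errs.append(err)
        if prev is not None and prev - err < tol * max(prev, 1e-30):
            break
        prev = err
    return W, H, np.array(errs)


def nmf_metric_modules(table: pd.DataFrame, k: int = 5, seed: int = 0,
                       max_iter: int = 2000, tol: float = 1e-10,
                       n_init: int = 12, preprocess: bool = True) -> NMFModel:
    """Non-negative factorization of the morphometric matrix into metric
    modules.

    With ``preprocess`` each metric is z-scored then min-shifted to
    non-negative (offset recorded); multiplicative updates minimize the
    Frobenius error; the best of ``n_init`` seeded restarts is kept.  W
    columns are per-neuron module scores usable by :func:`fit_lmm`.
    """
    X = table.to_numpy(float)
    if np.isnan(X).any():
        raise ValueError("impute the table before NMF")
    n, m = X.shape
    if k > min(n, m):
        raise ValueError(f"k={k} exceeds min(n_neurons, n_metrics)={min(n, m)}")
    if preprocess:
        means = X.mean(axis=0)
        scales = X.std(axis=0, ddof=1)
        scales[scales == 0] = 1.0
        Z = (X - means) / scales
        offsets = Z.min(axis=0)
        V = Z - offsets
    else:
        means = np.zeros(m)
        scales = np.ones(m)
        offsets = np.zeros(m)
        V = X
    if np.any(V < 0):
        raise ValueError("matrix must be non-negative after preprocessing")

    rng = np.random.default_rng(seed)
    best = None
    for _ in range(max(n_init, 1)):
        W, H, errs = _mu_nmf(V, k, rng, max_iter, tol)
        if best is None or errs[-1] < best[2][-1]:
            best = (W, H, errs)
    W, H, errs = best
    return NMFModel(W=W, H=H, k=k, error_trace=errs, offsets=offsets,
                    scales=scales, means=means, seed=seed,
                    metric_names=list(table.columns))


# ---------------------------------------------------------------------------
# spine density group tests
# ---------------------------------------------------------------------------

def spine_group_tests(densities, group_labels):
    """One-way ANOVA across groups plus Tukey HSD pairwise adjusted p-values.

    Returns (F, p, tukey frame with group1/group2/meandiff/p_adj)."""
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    d = np.asarray(densities, float)
    g = np.asarray(group_labels, dtype=object)
    labels = pd.unique(g)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    samples = [d[g == lab] for lab in labels]
    F, p = sps.f_oneway(*samples)
    tk = pairwise_tukeyhsd(d, g)
    frame = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
    frame = frame.rename(columns={"p-adj": "p_adj"})
    return float(F), float(p), frame
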