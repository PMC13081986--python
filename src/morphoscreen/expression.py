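"""Perturbation and developmental expression analysis.

Covers cell-level QC with the screen's printed thresholds, dual-guide vector
assignment, pseudobulk aggregation, median-of-ratios size factors,
negative-binomial GLM differential expression with Wald tests and BH
correction, temporal signature classification, locally weighted trajectory
smoothing, Fisher-exact risk-gene enrichment, and cross-dataset sign
concordance.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps

from .stats import bh_adjust


@dataclass
class CountMatrix:
    """Genes x units (cells or pseudobulk samples) integer counts with unit
    metadata (rows of ``unit_meta`` indexed by unit id)."""

    counts: pd.DataFrame
    unit_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        missing = set(self.counts.columns) - set(self.unit_meta.index)
        if missing:
            raise ValueError(f"metadata missing for units: {sorted(missing)[:5]}")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_units(self) -> int:
        return self.counts.shape[1]

    def subset_units(self, units) -> "CountMatrix":
        units = list(units)
        return CountMatrix(self.counts[units], self.unit_meta.loc[units])

    # -- I/O ---------------------------------------------------------------

    def write_mtx(self, prefix: str) -> None:
        from scipy.io import mmwrite
        from scipy.sparse import csr_matrix

        mmwrite(f"{prefix}.mtx", csr_matrix(self.counts.to_numpy()))
        pd.Series(self.counts.index).to_csv(f"{prefix}.genes.tsv", sep="\t",
                                            index=False, header=False)
        self.unit_meta.to_csv(f"{prefix}.units.tsv", sep="\t")

    @classmethod
    def read_mtx(cls, prefix: str) -> "CountMatrix":
        from scipy.io import mmread

        m = np.asarray(mmread(f"{prefix}.mtx").todense())
        genes = pd.read_csv(f"{prefix}.genes.tsv", sep="\t", header=None)[0]
        meta = pd.read_csv(f"{prefix}.units.tsv", sep="\t", index_col=0)
        counts = pd.DataFrame(m, index=genes, columns=meta.index)
        return cls(counts=counts, unit_meta=meta)


# ---------------------------------------------------------------------------
# cell QC
# ---------------------------------------------------------------------------

QC_DEFAULTS = dict(min_genes=250, max_doublet_score=1.2, max_umi=30_000,
                   max_mito_fraction=0.02)


def qc_cells(matrix: CountMatrix, multiplet_cells=None,
             **thresholds) -> tuple[pd.Series, dict[str, int]]:
    """Retain cells passing every screen QC gate.

    A cell is kept iff detected genes >= 250, doublet score <= 1.2,
    UMIs <= 30,000, mitochondrial fraction <= 2% (exclusions are strict
    inequalities, so boundary cells are retained), and it is not assigned to
    multiple perturbations.  Returns (boolean mask over cells, per-filter
    exclusion counts; a cell may fail several filters).
    """
    th = {**QC_DEFAULTS, **thresholds}
    meta = matrix.unit_meta
    fails = {
        "low_genes": meta["n_genes_detected"] < th["min_genes"],
        "doublet_score": meta["doublet_score"] > th["max_doublet_score"],
        "high_umi": meta["n_umi"] > th["max_umi"],
        "high_mito": meta["mito_fraction"] > th["max_mito_fraction"],
    }
    multiplet = pd.Series(False, index=meta.index)
    if multiplet_cells is not None:
        multiplet.loc[multiplet.index.intersection(pd.Index(multiplet_cells))] = True
    fails["multiplet"] = multiplet
    mask = ~pd.concat(fails, axis=1).any(axis=1)
    counts = {k: int(v.sum()) for k, v in fails.items()}
    counts["retained"] = int(mask.sum())
    return mask, counts


# ---------------------------------------------------------------------------
# guide assignment
# ---------------------------------------------------------------------------

def assign_guides(raw_calls: pd.DataFrame, library: pd.DataFrame) -> pd.DataFrame:
    """Combine per-guide calls into per-vector perturbation assignments.

    A cell with a single called guide is a singlet of that guide's vector; a
    cell whose two called guides form the matched pair of one vector is
    reclassified as a singlet of that vector; any other multi-guide cell is a
    multiplet; no calls leaves the cell unassigned.  Idempotent on its own
    output.
    """
    vec_of = dict(zip(library["guide"], library["vector"]))
    pert_of = dict(zip(library["vector"], library["perturbation"]))
    rows = []
    for cell, guides in zip(raw_calls["cell_id"], raw_calls["guides"]):
        gset = list(guides)
        unknown = [g for g in gset if g not in vec_of]
        if unknown:
            raise ValueError(f"guide(s) not in library: {unknown}")
        vecs = {vec_of[g] for g in gset}
        if len(gset) == 0:
            status, pert = "unassigned", None
        elif len(vecs) == 1 and len(gset) <= 2:
            status, pert = "singlet", pert_of[vecs.pop()]
        else:
            status, pert = "multiplet", None
        rows.append({"cell_id": cell, "status": status, "perturbation": pert,
                     "guides": sorted(gset)})
    return pd.DataFrame(rows)


def pairing_stats(raw_calls: pd.DataFrame, library: pd.DataFrame,
                  freq_mode: str = "empirical") -> dict[str, float]:
    """Matched-pair fraction among two-guide cells, with the chance level.

    ``chance = sum over pairs of 2 f_i f_j / sum over i != j of f_i f_j``
    where f is the guide frequency vector: empirical single-guide-call
    frequencies (default) or uniform.  Under uniform frequencies the chance
    reduces to 1/(G-1) for G guides.
    """
    vec_of = dict(zip(library["guide"], library["vector"]))
    guides = library["guide"].tolist()
    two_guide = [g for g in raw_calls["guides"] if len(g) == 2]
    matched = sum(1 for g in two_guide if vec_of[g[0]] == vec_of[g[1]])
    observed = matched / len(two_guide) if two_guide else float("nan")

    if freq_mode == "uniform":
        f = np.full(len(guides), 1.0 / len(guides))
    elif freq_mode == "empirical":
        singles = [g[0] for g in raw_calls["guides"] if len(g) == 1]
        if singles:
            counts = pd.Series(singles).value_counts()
            f = np.array([counts.get(g, 0) for g in guides], float)
        else:  # fall back to all guide occurrences
            allg = [g for gs in raw_calls["guides"] for g in gs]
            counts = pd.Series(allg).value_counts()
            f = np.array([counts.get(g, 0) for g in guides], float)
        f = f / f.sum()
    else:
        raise ValueError("freq_mode must be 'empirical' or 'uniform'")

    idx = {g: i for i, g in enumerate(guides)}
    num = 0.0
    for vec, grp in library.groupby("vector"):
        gs = grp["guide"].tolist()
        num += 2.0 * f[idx[gs[0]]] * f[idx[gs[1]]]
    den = 1.0 - float((f ** 2).sum())
    chance = num / den if den > 0 else float("nan")
    return {"observed": observed, "chance": chance,
            "n_two_guide_cells": len(two_guide), "n_matched": matched}


# ---------------------------------------------------------------------------
# aggregation / filtering / normalization
# ---------------------------------------------------------------------------

def pseudobulk(matrix: CountMatrix, by: list[str] | str = "sample_id") -> CountMatrix:
    """Sum raw counts over units sharing the ``by`` metadata columns."""
    by = [by] if isinstance(by, str) else list(by)
    groups = matrix.unit_meta.groupby(by, sort=True, observed=True)
    cols, meta_rows = {}, []
    for key, idx in groups.groups.items():
        key_t = key if isinstance(key, tuple) else (key,)
        name = "_".join(str(k) for k in key_t)
        cols[name] = matrix.counts[list(idx)].sum(axis=1)
        row = dict(zip(by, key_t))
        row["unit_id"] = name
        row["n_cells"] = len(idx)
        # carry metadata constant within the group
        for c in matrix.unit_meta.columns:
            vals = matrix.unit_meta.loc[idx, c].unique()
            if len(vals) == 1 and c not in row:
                row[c] = vals[0]
        meta_rows.append(row)
    counts = pd.DataFrame(cols)
    counts.index = matrix.counts.index
    meta = pd.DataFrame(meta_rows).set_index("unit_id")
    if (counts.sum(axis=0) == 0).any():
        warnings.warn("pseudobulk produced an all-zero sample", stacklevel=2)
    return CountMatrix(counts=counts, unit_meta=meta)


def filter_genes(matrix: CountMatrix, min_count: int = 10,
                 min_units: int = 2) -> CountMatrix:
    """Keep genes with at least ``min_count`` counts in at least
    ``min_units`` units (parameterizes the pseudobulk, shared-dataset, and
    percent-of-cells detection rules)."""
    ok = (matrix.counts >= min_count).sum(axis=1) >= min_units
    out = CountMatrix(counts=matrix.counts[ok], unit_meta=matrix.unit_meta)
    out.counts.attrs["n_removed"] = int((~ok).sum())
    return out


def size_factors(matrix: CountMatrix) -> pd.Series:
    """Median-of-ratios (DESeq-style) size factors.

    The reference is the per-gene geometric mean over units, restricted to
    genes positive in every unit; each unit's factor is the median ratio to
    the reference."""
    X = matrix.counts.to_numpy(float)
    pos = (X > 0).all(axis=1)
    if not pos.any():
        raise ValueError("no gene is positive in all units; consider a "
                         "pseudocount mode")
    logs = np.log(X[pos])
    ref = logs.mean(axis=1)
    factors = np.exp(np.median(logs - ref[:, None], axis=0))
    return pd.Series(factors, index=matrix.counts.columns, name="size_factor")


# ---------------------------------------------------------------------------
# negative-binomial GLM differential expression
# ---------------------------------------------------------------------------

def _nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: float) -> float:
    if alpha <= 0:
        return float(np.sum(sps.poisson.logpmf(y, mu)))
    r = 1.0 / alpha
    return float(np.sum(sps.nbinom.logpmf(y, r, r / (r + mu))))


def _alpha_mle(y: np.ndarray, mu: np.ndarray,
               X: np.ndarray | None = None) -> float:
    """Cox-Reid adjusted profile MLE of the NB dispersion given fitted
    means, with a method-of-moments fallback.

    The adjustment ``-0.5 log|X' W X|`` (W the GLM working weights)
    compensates the downward bias of the plain profile MLE when the sample
    size is small relative to the number of coefficients."""
    mom = float(np.mean(((y - mu) ** 2 - mu) / np.maximum(mu, 1e-8) ** 2))
    mom = max(mom, 1e-8)

    def crit(la: float) -> float:
        alpha = math.exp(la)
        ll = _nb_loglik(y, mu, alpha)
        if X is not None:
            w = mu / (1.0 + alpha * mu)
            sign, logdet = np.linalg.slogdet((X * w[:, None]).T @ X)
            ll -= 0.5 * logdet
        return -ll

    try:
        res = optimize.minimize_scalar(
            crit, bounds=(math.log(1e-8), math.log(100.0)), method="bounded",
            options={"xatol": 1e-6})
        if res.success:
            return float(math.exp(res.x))
    except Exception:
        pass
    return mom


def _fit_nb_gene(y: np.ndarray, X: np.ndarray, offset: np.ndarray,
                 n_rounds: int = 2):
    """NB2 GLM with log link and offsets: Poisson start, alternate profile
    dispersion MLE and GLM refits.  Returns (beta, bse, alpha, converged)."""
    import statsmodels.api as sm

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset).fit()
        alpha = _alpha_mle(y, fit.mu, X)
        for _ in range(n_rounds):
            fam = sm.families.NegativeBinomial(alpha=max(alpha, 1e-8))
            fit = sm.GLM(y, X, family=fam, offset=offset).fit(
                start_params=fit.params)
            alpha = _alpha_mle(y, fit.mu, X)
    conv = bool(np.all(np.isfinite(fit.bse)) and fit.converged)
    return fit.params, fit.bse, alpha, conv


def nb_glm_de(matrix: CountMatrix, ref_level: str,
              design: list[str] = ("perturbation",),
              factors: pd.Series | None = None,
              min_cells_per_pert: int | None = None,
              min_detect_frac: float | None = None) -> pd.DataFrame:
    """Per-gene negative-binomial regression Wald test against ``ref_level``.

    The design is perturbation (vs the reference level) plus any extra
    metadata columns in ``design`` (e.g. batch), with log size-factor
    offsets.  Dispersion is estimated per gene by profile maximum likelihood
    (method-of-moments fallback); p-values use a t reference with residual
    df and are BH-adjusted across genes within each contrast.  For
    cell-level runs pass ``min_cells_per_pert`` (screen gate: perturbations
    with more cells than the gate are tested) and ``min_detect_frac`` to
    drop rarely detected genes.

    Non-converged genes are flagged and their p set missing.
    """
    meta = matrix.unit_meta
    pert = meta["perturbation"].astype(str)
    if pert.nunique() < 2:
        raise ValueError("contrast not estimable: perturbation column constant")
    if ref_level not in set(pert):
        raise ValueError(f"reference level {ref_level!r} absent")

    keep_units = pd.Series(True, index=meta.index)
    if min_cells_per_pert is not None:
        sizes = pert.value_counts()
        good = set(sizes[sizes > min_cells_per_pert].index) | {ref_level}
        keep_units = pert.isin(good)
    m = matrix.subset_units(meta.index[keep_units])
    if min_detect_frac is not None:
        det = (m.counts > 0).mean(axis=1)
        m = CountMatrix(m.counts[det >= min_detect_frac], m.unit_meta)

    sf = size_factors(m) if factors is None else factors.loc[m.counts.columns]
    offset = np.log(sf.to_numpy(float))

    pert = m.unit_meta["perturbation"].astype(str)
    alts = [g for g in pd.unique(pert) if g != ref_level]
    Xcols = [np.ones(m.n_units)]
    names = ["intercept"]
    for g in alts:
        Xcols.append((pert == g).to_numpy(float))
        names.append(f"pert_{g}")
    for col in design:
        if col == "perturbation":
            continue
        levels = pd.unique(m.unit_meta[col].astype(str))
        for lv in levels[1:]:
            Xcols.append((m.unit_meta[col].astype(str) == lv).to_numpy(float))
            names.append(f"{col}_{lv}")
    X = np.column_stack(Xcols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("contrast not estimable: design matrix is singular")
    dof = max(m.n_units - X.shape[1], 1)

    ln2 = math.log(2.0)
    rows = []
    Y = m.counts.to_numpy(float)
    for gi, gene in enumerate(m.counts.index):
        y = Y[gi]
        try:
            beta, bse, alpha, conv = _fit_nb_gene(y, X, offset)
        except Exception:
            conv = False
            beta = np.full(X.shape[1], np.nan)
            bse = np.full(X.shape[1], np.nan)
            alpha = np.nan
        for i, g in enumerate(alts, start=1):
            if conv and np.isfinite(bse[i]) and bse[i] > 0:
                t = beta[i] / bse[i]
                p = 2.0 * sps.t.sf(abs(t), dof)
            else:
                p = np.nan
            rows.append({"gene": gene, "contrast": f"{g} vs {ref_level}",
                         "log2fc": beta[i] / ln2, "se": bse[i] / ln2,
                         "p": p, "dispersion": alpha, "converged": conv})
    out = pd.DataFrame(rows)
    out["p_adj"] = np.nan
    for c in out["contrast"].unique():
        sel = out["contrast"] == c
        out.loc[sel, "p_adj"] = bh_adjust(out.loc[sel, "p"])
    return out


# ---------------------------------------------------------------------------
# temporal signatures
# ---------------------------------------------------------------------------

def classify_signatures(de_early: pd.DataFrame, de_late: pd.DataFrame,
                        p_thresh: float = 0.05,
                        lfc_thresh: float = 0.3) -> pd.DataFrame:
    """Assign eligible genes to Progressing / Stabilizing / Transient.

    Eligibility: up-regulated in the early contrast (adjusted p < 0.05 and
    log2FC > 0.3).  Classes use the late (P28 vs P14) log2FC with strict
    inequalities: > 0.3 Progressing, < -0.3 Transient, strictly between
    Stabilizing; genes exactly on a boundary fall in no class and are
    reported as ``Boundary``.
    """
    genes = de_early.index.intersection(de_late.index)
    early = de_early.loc[genes]
    late = de_late.loc[genes]
    eligible = (early["p_adj"] < p_thresh) & (early["effect"] > lfc_thresh)
    lfc = late["effect"]
    cls = pd.Series("Ineligible", index=genes, name="class")
    cls[eligible & (lfc > lfc_thresh)] = "Progressing"
    cls[eligible & (lfc < -lfc_thresh)] = "Transient"
    cls[eligible & (lfc.abs() < lfc_thresh)] = "Stabilizing"
    cls[eligible & (lfc.abs() == lfc_thresh)] = "Boundary"
    return pd.DataFrame({"class": cls, "eligible": eligible,
                         "early_log2fc": early["effect"],
                         "late_log2fc": lfc})


def scale_to_reference(expr: pd.DataFrame, sample_ages: pd.Series,
                       ref_age: str = "P14") -> pd.DataFrame:
    """Scale per-gene expression relative to a reference age: subtract the
    mean expression at ``ref_age`` and divide by the gene's SD across all
    samples.  Genes with zero SD become missing with a warning."""
    ref_cols = sample_ages.index[sample_ages == ref_age]
    if len(ref_cols) == 0:
        raise ValueError(f"no samples at reference age {ref_age!r}")
    ref = expr[ref_cols].mean(axis=1)
    sd = expr.std(axis=1, ddof=1)
    zero = sd == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} gene(s) with zero SD set to missing",
                      stacklevel=2)
    sd = sd.where(~zero)
    return expr.sub(ref, axis=0).div(sd, axis=0)


def smooth_trajectory(x, y, span: float = 0.3, grid=None,
                      n_grid: int = 100) -> pd.DataFrame:
    """Locally weighted (tricube) linear regression evaluated on a grid.

    The bandwidth at each evaluation point is the distance to the
    ``ceil(span*n)``-th nearest data point; spans above 1 inflate the
    bandwidth proportionally, so the fit approaches the global least-squares
    line in the large-span limit.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 2:
        raise ValueError("need matching x/y with at least 2 points")
    if grid is None:
        grid = np.linspace(x.min(), x.max(), n_grid)
    grid = np.asarray(grid, float)
    n = x.size
    q = min(max(int(math.ceil(min(span, 1.0) * n)), 2), n)
    out = np.empty(grid.size)
    for i, x0 in enumerate(grid):
        d = np.abs(x - x0)
        h = np.sort(d)[q - 1]
        if span > 1.0:
            h *= span
        h = max(h, 1e-12)
        w = np.clip(1.0 - (d / h) ** 3, 0.0, None) ** 3
        if w.sum() <= 0 or np.count_nonzero(w) < 2:
            w = np.ones(n)
        W = w
        xm = np.sum(W * x) / W.sum()
        ym = np.sum(W * y) / W.sum()
        sxx = np.sum(W * (x - xm) ** 2)
        if sxx <= 1e-24:
            out[i] = ym
        else:
            beta = np.sum(W * (x - xm) * (y - ym)) / sxx
            out[i] = ym + beta * (x0 - xm)
    return pd.DataFrame({"x": grid, "fitted": out})


# ---------------------------------------------------------------------------
# enrichment and concordance
# ---------------------------------------------------------------------------

def fisher_enrichment(signature_sets: dict[str, set], risk_sets: dict[str, set],
                      universe: set) -> pd.DataFrame:
    """One-sided (enrichment) Fisher exact tests of each signature against
    each risk-gene set over ``universe``, BH-corrected across all tests."""
    universe = set(universe)
    rows = []
    for sname, sig in signature_sets.items():
        sig = set(sig) & universe
        for rname, risk in risk_sets.items():
            risk_u = set(risk) & universe
            a = len(sig & risk_u)
            b = len(sig - risk_u)
            c = len(risk_u - sig)
            d = len(universe) - a - b - c
            odds, p = sps.fisher_exact([[a, b], [c, d]], alternative="greater")
            rows.append({"signature": sname, "gene_set": rname, "a": a, "b": b,
                         "c": c, "d": d, "odds_ratio": odds, "p": p})
    out = pd.DataFrame(rows)
    out["p_adj"] = bh_adjust(out["p"])
    return out


@dataclass
class ConcordanceResult:
    shared_nominal: pd.Index
    shared_fdr: pd.Index
    concordance: float
    pearson_r: float


def sign_concordance(de_a: pd.DataFrame, de_b: pd.DataFrame,
                     nominal_alpha: float = 0.05,
                     effect_col: str = "effect") -> ConcordanceResult:
    """Cross-dataset agreement of differential effects.

    Shared-nominal genes have p < alpha in both tables; shared-FDR genes have
    adjusted p < alpha in both.  The sign-concordance fraction and Pearson r
    are computed on the shared-FDR set.
    """
    genes = de_a.index.intersection(de_b.index)
    a, b = de_a.loc[genes], de_b.loc[genes]
    nominal = genes[(a["p"] < nominal_alpha) & (b["p"] < nominal_alpha)]
    fdr = genes[(a["p_adj"] < nominal_alpha) & (b["p_adj"] < nominal_alpha)]
    if len(fdr) == 0:
        return ConcordanceResult(nominal, fdr, float("nan"), float("nan"))
    ea, eb = a.loc[fdr, effect_col], b.loc[fdr, effect_col]
    conc = float(np.mean(np.sign(ea) == np.sign(eb)))
    r = float(np.corrcoef(ea, eb)[0, 1]) if len(fdr) > 1 else float("nan")
    return ConcordanceResult(nominal, fdr, conc, r)
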