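"""Metric-space de-redundancy, subtype clustering, and reference-based
transcriptomic-type mapping.

The metric panel workflow mirrors standard co-expression module practice:
drop derived summary-statistic variants, impute, z-score, cluster metrics on
correlation distance with an adaptive tree cut, test module separation by
permutation, then pick a reduced panel with at least one metric per module.
The adaptive cut is a documented simplification of dynamic hybrid tree
cutting: the dendrogram is cut at the largest gap in sorted merge heights and
undersized clusters are merged into their most correlated module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform


# ---------------------------------------------------------------------------
# imputation
# ---------------------------------------------------------------------------

def impute_knn(table: pd.DataFrame, k: int = 5) -> pd.DataFrame:
    """k-nearest-neighbour imputation on z-scored metrics.

    Each missing cell becomes the mean of that metric over the k nearest
    neurons (Euclidean distance on pairwise-complete z-scored metrics);
    complete cells are untouched and values are returned in original units.
    """
    from sklearn.impute import KNNImputer

    if table.isna().all(axis=1).any():
        bad = table.index[table.isna().all(axis=1)][0]
        raise ValueError(f"neuron {bad!r} is missing all metrics")
    mu = table.mean(axis=0)
    sd = table.std(axis=0, ddof=1).replace(0, 1.0).fillna(1.0)
    Z = (table - mu) / sd
    imputer = KNNImputer(n_neighbors=min(k, len(table) - 1), weights="uniform")
    Zi = pd.DataFrame(imputer.fit_transform(Z), index=table.index,
                      columns=table.columns)
    return Zi * sd + mu


def impute_mean(table: pd.DataFrame) -> pd.DataFrame:
    """Column-mean imputation (used before k-means and NMF)."""
    if table.isna().all(axis=0).any():
        bad = table.columns[table.isna().all(axis=0)][0]
        raise ValueError(f"metric {bad!r} has no observed values")
    return table.fillna(table.mean(axis=0))


def drop_derived_variants(table: pd.DataFrame,
                          definitions: pd.DataFrame) -> pd.DataFrame:
    """Remove metrics tagged as derived summary-statistic variants
    (min/median/max/sd of other metrics) ahead of module detection."""
    tagged = set(definitions.loc[definitions["derived_variant"], "metric"])
    keep = [c for c in table.columns if c not in tagged]
    if not keep:
        raise ValueError("all metrics are tagged derived variants")
    out = table[keep].copy()
    out.attrs["n_dropped"] = len(table.columns) - len(keep)
    return out


# ---------------------------------------------------------------------------
# correlation modules
# ---------------------------------------------------------------------------

@dataclass
class MetricModules:
    assignment: pd.Series          # metric -> module id (1-based)
    linkage: np.ndarray
    merge_heights: np.ndarray
    statistic: float               # mean within-module |r| - between |r|
    corr: pd.DataFrame             # signed Pearson correlation
    p_value: float | None = None

    @property
    def n_modules(self) -> int:
        return int(self.assignment.nunique())


def _modularity(abs_corr: np.ndarray, labels: np.ndarray) -> float:
    n = abs_corr.shape[0]
    iu = np.triu_indices(n, k=1)
    same = labels[iu[0]] == labels[iu[1]]
    vals = abs_corr[iu]
    within = vals[same].mean() if same.any() else 0.0
    between = vals[~same].mean() if (~same).any() else 0.0
    return float(within - between)


def correlation_modules(table: pd.DataFrame,
                        min_module_size: int = 3) -> MetricModules:
    """Average-linkage clustering of metrics on distance 1 - |r| with an
    adaptive cut at the largest merge-height gap; clusters below
    ``min_module_size`` are merged into the module they correlate with most.

    The statistic is mean within-module |r| minus mean between-module |r|
    (sign-agnostic, so the module structure is invariant to metric sign
    flips).
    """
    if table.shape[1] < 2:
        raise ValueError("need at least 2 metrics")
    corr = table.corr()
    A = np.abs(corr.to_numpy())
    np.fill_diagonal(A, 1.0)
    D = 1.0 - A
    np.fill_diagonal(D, 0.0)
    D = np.clip((D + D.T) / 2.0, 0.0, None)
    Z = hierarchy.linkage(squareform(D, checks=False), method="average")
    heights = np.sort(Z[:, 2])
    if len(heights) >= 2:
        gaps = np.diff(heights)
        gi = int(np.argmax(gaps))
        threshold = (heights[gi] + heights[gi + 1]) / 2.0
    else:
        threshold = heights[-1] / 2.0 if len(heights) else 0.0
    labels = hierarchy.fcluster(Z, t=threshold, criterion="distance")

    # merge undersized clusters into their most-correlated module
    labels = labels.astype(int)
    while True:
        sizes = pd.Series(labels).value_counts()
        small = [m for m in sizes.index if sizes[m] < min_module_size]
        big = [m for m in sizes.index if sizes[m] >= min_module_size]
        if not small or not big:
            break
        m = small[0]
        members = labels == m
        best, best_r = None, -np.inf
        for o in big:
            r = A[np.ix_(members, labels == o)].mean()
            if r > best_r:
                best, best_r = o, r
        labels[members] = best
    # re-number 1..k
    remap = {old: new for new, old in enumerate(pd.unique(labels), start=1)}
    labels = np.array([remap[v] for v in labels])
    stat = _modularity(A, labels)
    return MetricModules(assignment=pd.Series(labels, index=table.columns),
                         linkage=Z, merge_heights=np.sort(Z[:, 2]),
                         statistic=stat, corr=corr)


def module_permutation_test(table: pd.DataFrame, modules: MetricModules,
                            n_perm: int = 1000, seed: int = 0,
                            min_module_size: int = 3) -> float:
    """Permutation p-value for module separation: each metric column is
    independently permuted across neurons, modules are re-detected, and the
    modularity statistic recorded; p = (1 + #{null >= observed})/(n_perm+1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be positive")
    rng = np.random.default_rng(seed)
    obs = modules.statistic
    X = table.to_numpy(float)
    hits = 0
    for _ in range(n_perm):
        P = np.column_stack([rng.permutation(X[:, j]) for j in range(X.shape[1])])
        perm = pd.DataFrame(P, columns=table.columns)
        stat = correlation_modules(perm, min_module_size).statistic
        if stat >= obs:
            hits += 1
    return (1 + hits) / (n_perm + 1)


# ---------------------------------------------------------------------------
# panel selection
# ---------------------------------------------------------------------------

@dataclass
class PanelSelection:
    selected: list
    coverage: dict                 # module id -> covered
    rationale: dict                # metric -> "module-representative"/"fill"


def select_panel(modules: MetricModules, preference_list: list[str],
                 target_n: int = 36) -> PanelSelection:
    """Pick a reduced metric panel: one highest-preference metric per module,
    then fill to ``target_n`` greedily minimizing the maximum within-panel
    |r| (ties broken alphabetically)."""
    module_ids = sorted(modules.assignment.unique())
    if target_n < len(module_ids):
        raise ValueError(f"target_n={target_n} cannot cover "
                         f"{len(module_ids)} modules")
    pref_rank = {m: i for i, m in enumerate(preference_list)}

    def sort_key(m: str):
        return (pref_rank.get(m, len(pref_rank)), m)

    selected: list[str] = []
    rationale: dict[str, str] = {}
    for mod in module_ids:
        members = sorted(modules.assignment.index[modules.assignment == mod],
                         key=sort_key)
        selected.append(members[0])
        rationale[members[0]] = "module-representative"

    A = modules.corr.abs()
    remaining = [m for m in modules.assignment.index if m not in selected]
    while len(selected) < min(target_n, len(modules.assignment)):
        best, best_score = None, None
        for m in sorted(remaining):
            score = float(A.loc[m, selected].max())
            if best_score is None or score < best_score:
                best, best_score = m, score
        selected.append(best)
        rationale[best] = "fill"
        remaining.remove(best)
    coverage = {mod: any(modules.assignment[m] == mod for m in selected)
                for mod in module_ids}
    return PanelSelection(selected=selected, coverage=coverage,
                          rationale=rationale)


# ---------------------------------------------------------------------------
# subtype clustering and type mapping
# ---------------------------------------------------------------------------

@dataclass
class SubtypeAssignment:
    labels: pd.Series              # neuron -> "M1".."Mk"
    k: int
    inertia: float
    seed: int


def kmeans_subtypes(table: pd.DataFrame, k: int = 5, seed: int = 0,
                    n_init: int = 25) -> SubtypeAssignment:
    """K-means (k-means++ init, best of ``n_init`` restarts) on the imputed,
    z-scored metric table.  Deterministic given ``seed``."""
    from sklearn.cluster import KMeans

    if k > len(table):
        raise ValueError(f"k={k} exceeds n_neurons={len(table)}")
    if table.isna().any().any():
        raise ValueError("impute the table before clustering")
    X = table.to_numpy(float)
    X = (X - X.mean(axis=0)) / np.where(X.std(axis=0) == 0, 1, X.std(axis=0))
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(X)
    labels = pd.Series([f"M{c + 1}" for c in km.labels_], index=table.index)
    return SubtypeAssignment(labels=labels, k=k, inertia=float(km.inertia_),
                             seed=seed)


@dataclass
class TypeClassifier:
    pipeline: object
    feature_names: list
    classes: list
    provenance: str = ""


def train_type_classifier(ref_table: pd.DataFrame, ref_labels,
                          kernel: str = "rbf",
                          provenance: str = "") -> TypeClassifier:
    """Train an SVM on scaled reference morphometrics to map neurons onto
    reference transcriptomic types (e.g. L2/3 IT vs L4/5 IT)."""
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler
    from sklearn.svm import SVC

    y = np.asarray(ref_labels)
    pipe = make_pipeline(StandardScaler(), SVC(kernel=kernel))
    pipe.fit(ref_table.to_numpy(float), y)
    return TypeClassifier(pipeline=pipe, feature_names=list(ref_table.columns),
                          classes=sorted(set(y)), provenance=provenance)


def predict_types(model: TypeClassifier, table: pd.DataFrame) -> pd.Series:
    """Hard-label prediction; features are aligned by name and a missing
    reference feature is an error naming it."""
    missing = [f for f in model.feature_names if f not in table.columns]
    if missing:
        raise ValueError(f"missing reference feature(s): {missing}")
    X = table[model.feature_names].to_numpy(float)
    return pd.Series(model.pipeline.predict(X), index=table.index,
                     name="predicted_type")


def pca_scores(table: pd.DataFrame, n_components: int = 10) -> pd.DataFrame:
    """Principal-component scores of the z-scored metric table."""
    from sklearn.decomposition import PCA

    X = table.to_numpy(float)
    X = (X - X.mean(axis=0)) / np.where(X.std(axis=0) == 0, 1, X.std(axis=0))
    n = min(n_components, min(X.shape))
    S = PCA(n_components=n, random_state=0).fit_transform(X)
    return pd.DataFrame(S, index=table.index,
                        columns=[f"PC{i + 1}" for i in range(n)])


# ---------------------------------------------------------------------------
# heatmap ordering
# ---------------------------------------------------------------------------

def heatmap_order(table: pd.DataFrame, subtypes: SubtypeAssignment,
                  rank_metric: str = "tuft_branch_number",
                  clip: float = 3.0):
    """Display ordering for the subtype heatmap.

    Subtype blocks are ranked by mean of ``rank_metric`` descending; within a
    block neurons sort by their mean z over the subtype's signature metrics
    (metrics whose maximal subtype mean lands in that subtype); metric rows
    are ordered by hierarchical clustering on 1 - Pearson r.  Returns
    (column order, row order, z-matrix clipped to +-clip with missing values
    retained).
    """
    Z = (table - table.mean(axis=0)) / table.std(axis=0, ddof=1)
    Zc = Z.clip(-clip, clip)

    labels = subtypes.labels.loc[table.index]
    rank_col = [c for c in table.columns if rank_metric in c]
    if not rank_col:
        raise ValueError(f"no metric matching {rank_metric!r}")
    block_means = table.groupby(labels)[rank_col[0]].mean()
    block_order = list(block_means.sort_values(ascending=False).index)

    subtype_means = Z.groupby(labels).mean()
    signature_of = subtype_means.idxmax(axis=0)      # metric -> subtype

    col_order: list = []
    for st in block_order:
        sig_metrics = signature_of.index[signature_of == st]
        members = labels.index[labels == st]
        if len(sig_metrics):
            score = Z.loc[members, sig_metrics].mean(axis=1)
        else:
            score = Z.loc[members].mean(axis=1)
        col_order.extend(score.sort_values(ascending=False).index)

    corr = Z.corr()
    D = 1.0 - corr.to_numpy()
    np.fill_diagonal(D, 0.0)
    D = np.clip((D + D.T) / 2.0, 0.0, None)
    link = hierarchy.linkage(squareform(D, checks=False), method="average")
    row_order = [table.columns[i] for i in hierarchy.leaves_list(link)]
    return col_order, row_order, Zc
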