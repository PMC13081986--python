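"""Cross-modality joint analysis: aggregate perturbation impact and energy
distances between perturbation groups in morphology or expression feature
space.

The transcriptome/morphome-wide impact (TWI) is a method-of-moments,
noise-corrected mean squared effect: ``max(0, mean(effect^2 - se^2))``.  It
is an unbiased estimator of the mean squared *true* effect across features
(before flooring), summarizing how strongly a perturbation moves the whole
feature space.

Energy distances use the V-statistic convention (all ordered pairs,
including self-pairs), so ``E(A, A) = 0`` exactly; with the squared-Euclidean
kernel ``E`` converges to ``2 * ||mean(A) - mean(B)||^2``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist


@dataclass
class TWIEstimate:
    perturbation: str
    modality: str
    twi: float
    n_features: int
    method: str = "method-of-moments"


def twi(effects: pd.DataFrame, perturbation: str = "",
        modality: str = "RNA") -> TWIEstimate:
    """Noise-corrected aggregate impact from a per-feature effect table.

    ``effects`` needs ``effect`` and ``se`` columns for one contrast; rows
    with missing values are dropped, but a missing ``se`` column is an
    error (the correction is the point of the estimator).
    """
    if "se" not in effects.columns or "effect" not in effects.columns:
        raise ValueError("effect table must carry 'effect' and 'se' columns")
    t = effects[["effect", "se"]].dropna()
    if len(t) == 0:
        raise ValueError("no complete (effect, se) rows")
    raw = float(np.mean(t["effect"] ** 2 - t["se"] ** 2))
    return TWIEstimate(perturbation=perturbation, modality=modality,
                       twi=max(0.0, raw), n_features=len(t))


def batch_center(features: pd.DataFrame, batch_labels) -> pd.DataFrame:
    """Location-scale batch standardization: per batch and feature, subtract
    the batch mean and divide by the batch SD, then restore the pooled mean
    and SD.  Size-1 batches are centred to the pooled mean with a warning
    (their SD is undefined).
    """
    b = pd.Series(np.asarray(batch_labels, dtype=object), index=features.index)
    pooled_mean = features.mean(axis=0)
    pooled_sd = features.std(axis=0, ddof=1).replace(0, 1.0)
    out = features.copy().astype(float)
    for batch, idx in features.groupby(b).groups.items():
        block = features.loc[idx]
        if len(idx) == 1:
            warnings.warn(f"batch {batch!r} has a single sample; centred only",
                          stacklevel=2)
            out.loc[idx] = pooled_mean.to_numpy()
            continue
        bm = block.mean(axis=0)
        bs = block.std(axis=0, ddof=1).replace(0, 1.0)
        out.loc[idx] = ((block - bm) / bs * pooled_sd + pooled_mean).to_numpy()
    return out


def energy_distance(A: np.ndarray, B: np.ndarray,
                    kernel: str = "sqeuclidean") -> float:
    """Energy distance between two point clouds:
    ``2 mean d(a,b) - mean d(a,a') - mean d(b,b')`` over all ordered pairs.

    ``kernel`` is ``sqeuclidean`` (default) or ``euclidean``.
    """
    A = np.atleast_2d(np.asarray(A, float))
    B = np.atleast_2d(np.asarray(B, float))
    if A.shape[1] != B.shape[1]:
        raise ValueError("dimension mismatch")
    if len(A) == 0 or len(B) == 0:
        raise ValueError("empty point set")
    metric = {"sqeuclidean": "sqeuclidean", "euclidean": "euclidean"}[kernel]
    ab = cdist(A, B, metric).mean()
    aa = cdist(A, A, metric).mean()
    bb = cdist(B, B, metric).mean()
    return float(2.0 * ab - aa - bb)


@dataclass
class EDistMatrix:
    matrix: pd.DataFrame
    modality: str
    n_dims: int | None
    batch_corrected: bool
    excluded_groups: list


def edist_matrix(features: pd.DataFrame, group_labels,
                 batch_labels=None, n_dims: int | None = 25,
                 min_group_size: int = 5, kernel: str = "sqeuclidean",
                 modality: str = "morphology") -> EDistMatrix:
    """Pairwise energy distances among perturbation groups.

    Features are optionally batch-centred, reduced to ``n_dims`` principal
    components (skipped when ``n_dims`` is None or exceeds the feature
    count), and groups smaller than ``min_group_size`` are excluded and
    reported."""
    g = pd.Series(np.asarray(group_labels, dtype=object), index=features.index)
    X = features
    corrected = False
    if batch_labels is not None:
        X = batch_center(X, batch_labels)
        corrected = True
    if n_dims is not None and n_dims < X.shape[1]:
        from sklearn.decomposition import PCA

        M = X.to_numpy(float)
        M = M - M.mean(axis=0)
        X = pd.DataFrame(PCA(n_components=n_dims, random_state=0).fit_transform(M),
                         index=X.index)
    sizes = g.value_counts()
    kept = [lab for lab in sizes.index if sizes[lab] >= min_group_size]
    excluded = [lab for lab in sizes.index if sizes[lab] < min_group_size]
    mat = pd.DataFrame(0.0, index=kept, columns=kept)
    for i, a in enumerate(kept):
        Xa = X.loc[g == a].to_numpy()
        for bl in kept[i + 1:]:
            Xb = X.loc[g == bl].to_numpy()
            e = energy_distance(Xa, Xb, kernel)
            mat.loc[a, bl] = mat.loc[bl, a] = e
    return EDistMatrix(matrix=mat, modality=modality, n_dims=n_dims,
                       batch_corrected=corrected, excluded_groups=excluded)


def cross_modality(twis_a: pd.Series, twis_b: pd.Series
                   ) -> tuple[float, pd.DataFrame]:
    """Correlate per-perturbation impact across two modalities.

    Inputs are indexed by a shared pairing key (e.g. perturbation or
    perturbation x cell type).  Returns the Pearson r over matched pairs and
    a scatter table with per-modality percent-of-maximum normalization and
    their average (the labeling rule used for joint impact displays).
    """
    keys = twis_a.index.intersection(twis_b.index)
    if len(keys) < 2:
        raise ValueError("need at least 2 matched perturbations")
    a = twis_a.loc[keys].astype(float)
    b = twis_b.loc[keys].astype(float)
    r = float(np.corrcoef(a, b)[0, 1])
    pct_a = 100.0 * a / a.max() if a.max() > 0 else a * 0.0
    pct_b = 100.0 * b / b.max() if b.max() > 0 else b * 0.0
    table = pd.DataFrame({"twi_a": a, "twi_b": b, "pct_a": pct_a,
                          "pct_b": pct_b, "pct_mean": (pct_a + pct_b) / 2.0})
    return r, table
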