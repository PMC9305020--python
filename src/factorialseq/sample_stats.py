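"""Sample-level ordination and group-separation statistics.

PCA follows the usual count-PCA recipe: log2(normalized count + 1), the
``n_top`` most variable features, per-feature centering, SVD.  PERMANOVA is
the one-factor permutational multivariate ANOVA on a distance matrix: the
pseudo-F from the among/within partition of squared distances, with a
permutation p value of (1 + #{F_perm >= F_obs}) / (1 + n_perm).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform


@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame      # samples x PCs
    variance_explained: np.ndarray
    features_used: list


def pca_counts(
    counts: pd.DataFrame,
    size_factors: pd.Series | None = None,
    n_top: int = 500,
    n_components: int | None = None,
) -> OrdinationResult:
    """PCA of log2(normalized counts + 1) on the most variable features."""
    if counts.shape[1] < 3:
        raise ValueError("PCA needs at least 3 samples")
    if size_factors is None:
        from .nbglm import estimate_size_factors

        size_factors = estimate_size_factors(counts)
    norm = counts.to_numpy(float) / size_factors.to_numpy()[None, :]
    logn = np.log2(norm + 1.0)
    variances = logn.var(axis=1)
    if n_top < len(variances):
        top = np.argsort(variances, kind="stable")[::-1][:n_top]
    else:
        import warnings

        if n_top > len(variances):
            warnings.warn(f"only {len(variances)} features available; n_top={n_top} reduced")
        top = np.arange(len(variances))
    X = logn[top].T  # samples x features
    Xc = X - X.mean(axis=0, keepdims=True)
    U, S, _ = np.linalg.svd(Xc, full_matrices=False)
    k = n_components or min(Xc.shape)
    coords = U[:, :k] * S[:k]
    var_frac = (S**2) / (S**2).sum()
    return OrdinationResult(
        coordinates=pd.DataFrame(coords, index=counts.columns, columns=[f"PC{i+1}" for i in range(coords.shape[1])]),
        variance_explained=var_frac[:k],
        features_used=list(counts.index[top]),
    )


def log_normal_matrix(counts: pd.DataFrame, size_factors: pd.Series, n_top: int = 500) -> pd.DataFrame:
    """The samples x features matrix PCA operates on (for distance computations)."""
    norm = counts.to_numpy(float) / size_factors.to_numpy()[None, :]
    logn = np.log2(norm + 1.0)
    variances = logn.var(axis=1)
    top = np.argsort(variances, kind="stable")[::-1][: min(n_top, len(variances))]
    return pd.DataFrame(logn[top].T, index=counts.columns, columns=counts.index[top])


@dataclass
class PermanovaResult:
    factor: str
    pseudo_f: float
    r2: float
    p: float
    n_perm: int


def _pseudo_f(d2: np.ndarray, labels: np.ndarray):
    """Among/within partition of squared distances (Anderson's formulation)."""
    n = d2.shape[0]
    iu = np.triu_indices(n, 1)
    sst = d2[iu].sum() / n
    ssw = 0.0
    groups = np.unique(labels)
    for g in groups:
        idx = np.where(labels == g)[0]
        if len(idx) < 2:
            continue
        sub = d2[np.ix_(idx, idx)]
        ssw += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    ssa = sst - ssw
    a = len(groups)
    f = (ssa / (a - 1)) / (ssw / (n - a))
    return f, ssa / sst


def permanova(
    distance: pd.DataFrame | np.ndarray,
    labels,
    n_perm: int = 999,
    seed: int = 0,
    factor: str = "factor",
) -> PermanovaResult:
    """One-factor PERMANOVA with seeded label permutations.

    R^2 = SS_among / SS_total is permutation-free; the p value can never go
    below the floor 1 / (n_perm + 1).  Singleton groups are rejected.
    """
    D = distance.to_numpy() if isinstance(distance, pd.DataFrame) else np.asarray(distance, float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    labels = np.asarray(labels)
    if len(labels) != D.shape[0]:
        raise ValueError("one label per sample required")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need >= 2 groups")
    if (counts < 2).any():
        raise ValueError(f"singleton group(s): {list(uniq[counts < 2])}")
    d2 = D**2
    f_obs, r2 = _pseudo_f(d2, labels)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        f_perm, _ = _pseudo_f(d2, rng.permutation(labels))
        if f_perm >= f_obs:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return PermanovaResult(factor=factor, pseudo_f=float(f_obs), r2=float(r2), p=float(p), n_perm=n_perm)


def euclidean_distance(matrix: pd.DataFrame) -> pd.DataFrame:
    D = squareform(pdist(matrix.to_numpy(), metric="euclidean"))
    return pd.DataFrame(D, index=matrix.index, columns=matrix.index)
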