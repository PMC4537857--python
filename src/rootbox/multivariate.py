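"""Multivariate summaries of entry-level trait data.

Per-entry-class Pearson correlations, maturity adjustment by covariate
regression, Z-standardization, PCA on the trait correlation matrix, and
hierarchical clustering of hybrids on Euclidean phenotypic distances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

__all__ = [
    "PCAResult",
    "ClusterResult",
    "class_correlations",
    "maturity_adjust",
    "zscore",
    "pca_correlation",
    "hcluster",
]


@dataclass(frozen=True)
class PCAResult:
    eigenvalues: np.ndarray
    loadings: np.ndarray            # traits x components, orthonormal columns
    variance_explained: np.ndarray  # fractions summing to 1
    trait_names: tuple[str, ...]

    def loadings_frame(self) -> pd.DataFrame:
        cols = [f"PC{i+1}" for i in range(self.loadings.shape[1])]
        return pd.DataFrame(self.loadings, index=list(self.trait_names), columns=cols)


@dataclass(frozen=True)
class ClusterResult:
    linkage_matrix: np.ndarray
    labels: pd.Series               # cluster id per entry at the requested cut
    cluster_means: pd.DataFrame     # per-cluster trait means


def class_correlations(
    records: pd.DataFrame,
    entry_class: str | None = None,
    trait_cols: tuple[str, ...] = ("FD", "FA", "RA", "SD"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise-complete Pearson correlations among traits, with p-values.

    When ``entry_class`` is given the table is first restricted to that
    class; missing values are handled pairwise, matching an unbalanced
    design. Returns (r, p) matrices, symmetric with unit/zero diagonals.
    """
    df = records
    if entry_class is not None:
        df = df[df["entry_class"] == entry_class]
    cols = [c for c in trait_cols if c in df.columns]
    X = df[cols].apply(pd.to_numeric, errors="coerce")
    k = len(cols)
    r = np.eye(k)
    p = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            pair = X.iloc[:, [i, j]].dropna()
            if len(pair) < 3:
                raise ValueError(
                    f"fewer than 3 complete pairs for {cols[i]}/{cols[j]}"
                )
            xi = pair.iloc[:, 0].to_numpy()
            xj = pair.iloc[:, 1].to_numpy()
            if np.std(xi) == 0 or np.std(xj) == 0:
                raise ValueError(f"constant trait in pair {cols[i]}/{cols[j]}")
            rr, pp = stats.pearsonr(xi, xj)
            r[i, j] = r[j, i] = rr
            p[i, j] = p[j, i] = pp
    rm = pd.DataFrame(r, index=cols, columns=cols)
    pm = pd.DataFrame(p, index=cols, columns=cols)
    return rm, pm


def maturity_adjust(values: pd.Series, days_to_silking: pd.Series) -> pd.Series:
    """Remove the linear maturity trend from a trait.

    Fits trait ~ days-to-silking by simple regression and returns the
    residuals re-centered at the trait mean, so adjusted values stay on the
    trait's original scale.
    """
    y = pd.to_numeric(values, errors="coerce").to_numpy(dtype=float)
    x = pd.to_numeric(days_to_silking, errors="coerce").to_numpy(dtype=float)
    ok = np.isfinite(y) & np.isfinite(x)
    if ok.sum() < 3:
        raise ValueError("need at least 3 complete (trait, covariate) pairs")
    if np.std(x[ok]) == 0:
        raise ValueError("constant maturity covariate")
    slope, intercept = np.polyfit(x[ok], y[ok], 1)
    out = np.full_like(y, np.nan)
    out[ok] = y[ok] - (slope * x[ok] + intercept) + np.nanmean(y[ok])
    return pd.Series(out, index=values.index, name=values.name)


def zscore(matrix: pd.DataFrame) -> pd.DataFrame:
    """Standardize each column to mean 0, sd 1 (ddof=1)."""
    X = matrix.apply(pd.to_numeric, errors="coerce")
    sd = X.std(ddof=1)
    if (sd == 0).any() or sd.isna().any():
        bad = sd.index[(sd == 0) | sd.isna()].tolist()
        raise ValueError(f"zero-variance column(s): {bad}")
    return (X - X.mean()) / sd


def pca_correlation(matrix: pd.DataFrame) -> PCAResult:
    """PCA as an eigendecomposition of the trait Pearson correlation matrix.

    Components are ordered by decreasing eigenvalue; the eigenvalues sum to
    the number of traits; each component's sign is fixed so its
    largest-magnitude loading is positive. A rank-deficient correlation
    matrix simply yields (near-)zero trailing eigenvalues.
    """
    if matrix.shape[1] < 2 or matrix.shape[0] < 3:
        raise ValueError("need at least 2 traits and 3 entries")
    X = matrix.apply(pd.to_numeric, errors="coerce")
    corr = X.corr().to_numpy()
    if not np.all(np.isfinite(corr)):
        raise ValueError("correlation matrix has undefined entries")
    vals, vecs = np.linalg.eigh(corr)
    order = np.argsort(vals)[::-1]
    vals = np.clip(vals[order], 0.0, None)
    vecs = vecs[:, order]
    for j in range(vecs.shape[1]):
        i = int(np.argmax(np.abs(vecs[:, j])))
        if vecs[i, j] < 0:
            vecs[:, j] = -vecs[:, j]
    return PCAResult(
        eigenvalues=vals,
        loadings=vecs,
        variance_explained=vals / vals.sum(),
        trait_names=tuple(map(str, X.columns)),
    )


def hcluster(z_matrix: pd.DataFrame, k: int, method: str = "ward") -> ClusterResult:
    """Agglomerative clustering of entries on Euclidean distances.

    Rows are sorted by entry id before linkage so the partition does not
    depend on input order; Ward linkage is the default for compact,
    balanced groups, but any scipy linkage method can be requested.
    """
    if k > len(z_matrix):
        raise ValueError(f"k={k} exceeds the number of entries {len(z_matrix)}")
    X = z_matrix.sort_index()
    Z = linkage(pdist(X.to_numpy(dtype=float), metric="euclidean"), method=method)
    labels = fcluster(Z, t=k, criterion="maxclust")
    lab = pd.Series(labels, index=X.index, name="cluster")
    means = X.groupby(lab).mean()
    return ClusterResult(linkage_matrix=Z, labels=lab, cluster_means=means)
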