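"""Temporal pattern clustering and stage-to-stage sample correlation.

Expression profiles are clustered on log2(RPKM + pseudocount) with
Euclidean K-means (Lloyd's algorithm, k-means++ seeding, best of
``n_init`` restarts), the standard way to summarise developmental
time-course shapes into a small number of pattern groups.  Profiles are
deliberately *not* z-scored per gene: grouping acts on the log abundance
courses themselves.  Group labels 1..k are assigned by descending group
size so reruns give stable, reportable numbering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .data_model import ExpressionMatrix

__all__ = [
    "ClusterAssignment",
    "StageCorrelationMatrix",
    "log2_profiles",
    "kmeans_profiles",
    "stage_correlation_matrix",
]


@dataclass
class ClusterAssignment:
    k: int
    labels: dict[str, int]            # gene_id -> group in 1..k
    centroids: np.ndarray             # k x n_stages, log2 units, label order
    sse: float                        # total within-cluster sum of squares
    seed: int

    def __post_init__(self) -> None:
        if self.sse < -1e-9:
            raise ValueError("sse must be >= 0")
        if not np.isfinite(self.centroids).all():
            raise ValueError("centroids must be finite")
        bad = [g for g, lab in self.labels.items() if not (1 <= lab <= self.k)]
        if bad:
            raise ValueError(f"labels out of 1..{self.k} for {bad[:5]}")

    def group_sizes(self) -> dict[int, int]:
        sizes: dict[int, int] = {g: 0 for g in range(1, self.k + 1)}
        for lab in self.labels.values():
            sizes[lab] += 1
        return sizes


@dataclass
class StageCorrelationMatrix:
    sample_labels: list[str]
    values: np.ndarray                # square grid of Pearson r

    def __post_init__(self) -> None:
        v = self.values
        n = len(self.sample_labels)
        if v.shape != (n, n):
            raise ValueError("correlation grid shape does not match labels")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(v), 1.0, atol=1e-12):
            raise ValueError("correlation matrix must have unit diagonal")
        if (v < -1 - 1e-12).any() or (v > 1 + 1e-12).any():
            raise ValueError("correlations must lie in [-1, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_labels,
                            columns=self.sample_labels)


def log2_profiles(m: ExpressionMatrix, pseudocount: float = 1.0) -> pd.DataFrame:
    """log2(RPKM + pseudocount) profiles, same gene x stage shape.

    Requires pseudocount > 0 unless every value is strictly positive.
    """
    values = m.values()
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    if pseudocount == 0 and (values <= 0).any():
        raise ValueError(
            "zero expression with pseudocount 0 would produce -inf; "
            "use a positive pseudocount"
        )
    return pd.DataFrame(np.log2(values + pseudocount), index=m.data.index,
                        columns=m.data.columns)


def _hartigan_polish(X: np.ndarray, labels: np.ndarray, k: int,
                     max_moves: int = 200) -> np.ndarray:
    """Greedy single-point improvement of a Lloyd solution.

    Moves one point at a time to the cluster that most reduces the total
    within-cluster sum of squares, accounting for the centroid shift the
    move itself causes (Hartigan's criterion).  Hartigan-stable
    partitions are a strict subset of Lloyd-stable ones, so this escapes
    local optima whose basin Lloyd cannot leave.  Never empties a
    cluster; stops after ``max_moves`` moves or when no move improves.
    """
    labels = labels.copy()
    n = len(X)
    for _ in range(max_moves):
        sizes = np.bincount(labels, minlength=k).astype(float)
        cent = np.vstack([X[labels == j].mean(axis=0) for j in range(k)])
        d2 = ((X[:, None, :] - cent[None, :, :]) ** 2).sum(axis=-1)
        n_own = sizes[labels]
        own = d2[np.arange(n), labels]
        with np.errstate(divide="ignore", invalid="ignore"):
            loss_remove = np.where(n_own > 1, n_own / (n_own - 1.0) * own,
                                   -np.inf)   # singleton: moving it would
        gain_add = sizes[None, :] / (sizes[None, :] + 1.0) * d2
        delta = gain_add - loss_remove[:, None]  # empty a cluster -> +inf
        delta[np.arange(n), labels] = 0.0
        i, j = np.unravel_index(np.argmin(delta), delta.shape)
        if delta[i, j] >= -1e-12:
            break
        labels[i] = j
    return labels


def _sse_of(X: np.ndarray, labels: np.ndarray, k: int) -> float:
    return float(sum(((X[labels == j] - X[labels == j].mean(axis=0)) ** 2).sum()
                     for j in range(k) if (labels == j).any()))


def kmeans_profiles(
    profiles: pd.DataFrame,
    k: int = 20,
    seed: int = 0,
    n_init: int = 10,
    max_iter: int = 300,
    init: str = "mixed",
) -> ClusterAssignment:
    """K-means on temporal profiles; best of ``n_init`` Lloyd restarts,
    each finished with a Hartigan single-point polish.

    ``init`` selects the restart scheme: "k-means++" (point-based
    seeding), "random-partition" (centroids from random assignments), or
    "mixed" (default: half each).  Point seeding converges fast on large
    well-separated data, while partition seeding reaches optima whose
    basin contains no data-point seed pair; the Hartigan polish then
    escapes Lloyd-stable-but-suboptimal fixed points.  Deterministic for
    a fixed seed.  Groups are renumbered 1..k by descending size (ties
    broken by original centroid order).
    """
    X = profiles.to_numpy(dtype=float)
    n = len(X)
    if k < 1 or k > n:
        raise ValueError(f"k must be in [1, n_genes={n}], got {k}")
    if init not in ("k-means++", "random-partition", "mixed"):
        raise ValueError(f"unknown init scheme {init!r}")
    if init == "mixed":
        n_pp = max(1, n_init // 2)
        n_part = max(1, n_init - n_pp)
    elif init == "k-means++":
        n_pp, n_part = n_init, 0
    else:
        n_pp, n_part = 0, n_init
    candidates: list[np.ndarray] = []
    if n_pp:
        km = KMeans(n_clusters=k, n_init=n_pp, max_iter=max_iter,
                    random_state=seed).fit(X)
        candidates.append(km.labels_)
    rng = np.random.default_rng(seed)
    for _ in range(n_part):
        labels0 = rng.integers(0, k, size=n)
        labels0[rng.permutation(n)[:k]] = np.arange(k)  # every group nonempty
        centroids0 = np.vstack([X[labels0 == j].mean(axis=0) for j in range(k)])
        cand = KMeans(n_clusters=k, init=centroids0, n_init=1,
                      max_iter=max_iter, random_state=seed).fit(X)
        candidates.append(cand.labels_)
    best_labels, best_sse = None, np.inf
    for raw in candidates:
        polished = _hartigan_polish(X, np.asarray(raw), k)
        sse = _sse_of(X, polished, k)
        if sse < best_sse - 1e-12:
            best_labels, best_sse = polished, sse
    raw_labels = best_labels
    sizes = np.bincount(raw_labels, minlength=k)
    order = np.lexsort((np.arange(k), -sizes))      # descending size, stable
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(1, k + 1)
    labels = {gene: int(remap[lab]) for gene, lab in zip(profiles.index, raw_labels)}
    centroids = np.vstack([
        X[raw_labels == j].mean(axis=0) if (raw_labels == j).any()
        else np.full(X.shape[1], np.nan)
        for j in order])
    if not np.isfinite(centroids).all():
        raise ValueError("empty cluster after polish; reduce k")
    return ClusterAssignment(k=k, labels=labels, centroids=centroids,
                             sse=best_sse, seed=seed)


def stage_correlation_matrix(
    matrices: list[ExpressionMatrix] | ExpressionMatrix,
) -> StageCorrelationMatrix:
    """Pearson r over genes between every pair of genotype x stage samples.

    All matrices are intersected on their common gene set; each sample
    column is labelled ``<genotype>:DAF<k>``.  A zero-variance column is
    an error (its correlation is undefined), reported by name.
    """
    if isinstance(matrices, ExpressionMatrix):
        matrices = [matrices]
    if not matrices:
        raise ValueError("need at least one expression matrix")
    common = matrices[0].data.index
    for m in matrices[1:]:
        common = common.intersection(m.data.index)
    if len(common) == 0:
        raise ValueError("matrices share no gene ids")
    common = sorted(common)
    columns: list[np.ndarray] = []
    labels: list[str] = []
    for m in matrices:
        sub = m.data.loc[common]
        for stage in m.axis.stages:
            col = sub[stage].to_numpy(dtype=float)
            label = f"{m.genotype_id}:DAF{stage}"
            if np.ptp(col) == 0:
                raise ValueError(f"zero-variance sample column {label!r}")
            columns.append(col)
            labels.append(label)
    grid = np.corrcoef(np.vstack(columns))
    # exact unit diagonal / symmetry despite float round-off
    grid = np.clip((grid + grid.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(grid, 1.0)
    return StageCorrelationMatrix(sample_labels=labels, values=grid)
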