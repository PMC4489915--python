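"""The stage-course co-expression screen.

Every transcription factor (TF) is correlated with every structural gene
(SG) of a biosynthetic pathway across the developmental stages of one
genotype.  A pair is called significant when BOTH conditions hold:

* |r| >= ``r_threshold`` (the screening cut, default 0.8), and
* the correlation t-test rejects at level ``alpha``:
  t = r * sqrt(n - 2) / sqrt(1 - r^2) with df = n - 2, two-sided
  (for n = 7 stages at alpha = 0.05 this is equivalent to |r| > 0.754).

Per TF, the counts of significant and positively correlated structural
genes in each genotype give the familiar "N(P)" candidate table, from
which candidates are selected by per-pathway count thresholds.
Genotypes are always screened independently (n = 7 each), never pooled.

Zero-variance series after the expression filter (a gene with identical
RPKM in all stages) have no defined correlation: such pairs are excluded
with a recorded reason, never scored as r = 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import ExpressionMatrix, GeneCatalog, ScreenConfig, TFSummaryRow
from .quantification import expression_filter

__all__ = [
    "CorrelationRecord",
    "pearson_r",
    "corr_t_statistic",
    "significance_threshold_r",
    "pairwise_pearson",
    "correlate_sources_targets",
    "screen_pathway",
    "summarize_tf",
    "select_candidates",
    "cross_dataset_validate",
    "benjamini_hochberg",
]


class UndefinedCorrelationError(ValueError):
    """Raised when a series has zero variance (correlation undefined)."""


@dataclass(frozen=True)
class CorrelationRecord:
    """One source-target pair's correlation evidence in one genotype.

    ``source_id`` is a TF (or a metabolite); ``target_id`` a structural
    gene.  Excluded pairs (zero variance, failed expression filter) carry
    ``excluded_reason`` and no statistics.
    """

    source_id: str
    target_id: str
    genotype_id: str
    pathway: str | None = None
    r: float | None = None
    n: int | None = None
    t_stat: float | None = None
    df: int | None = None
    p_value: float | None = None
    significant: bool = False
    sign: str | None = None           # "positive" | "negative"
    excluded_reason: str | None = None

    def __post_init__(self) -> None:
        if self.excluded_reason is None:
            if self.r is None or not (-1.0 <= self.r <= 1.0):
                raise ValueError(f"{self.source_id}-{self.target_id}: bad r {self.r}")
            if self.df is None or self.df < 1:
                raise ValueError("df must be >= 1")
            expected = "positive" if self.r >= 0 else "negative"
            if self.sign != expected:
                raise ValueError(
                    f"{self.source_id}-{self.target_id}: sign {self.sign!r} "
                    f"does not match r = {self.r}"
                )
        elif self.significant:
            raise ValueError("an excluded pair cannot be significant")


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson product-moment correlation of two stage series.

    Requires equal length >= 3 and nonzero variance in both series
    (:class:`UndefinedCorrelationError` otherwise — an undefined
    correlation is never reported as 0).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"series must be equal-length 1-D, got {x.shape}, {y.shape}")
    if len(x) < 3:
        raise ValueError("correlation needs at least 3 points (df = n - 2 >= 1)")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = math.sqrt(float(xc @ xc))
    sy = math.sqrt(float(yc @ yc))
    if sx == 0.0 or sy == 0.0:
        raise UndefinedCorrelationError("zero-variance series")
    r = float(xc @ yc) / (sx * sy)
    return min(1.0, max(-1.0, r))


def corr_t_statistic(r: float, n: int) -> float:
    """t = r * sqrt(n - 2) / sqrt(1 - r^2), the correlation t-test statistic
    with df = n - 2.  Odd in r and strictly increasing in |r|."""
    if n < 3:
        raise ValueError("t statistic needs n >= 3")
    if not (-1.0 < r < 1.0):
        raise ValueError(f"|r| must be < 1 for a finite t, got r = {r}")
    return r * math.sqrt(n - 2) / math.sqrt(1.0 - r * r)


def significance_threshold_r(n: int, alpha: float = 0.05) -> float:
    """Smallest |r| significant at two-sided level alpha with n points.

    Inverts the t formula at the critical value t*_{alpha/2, n-2}:
    r* = t* / sqrt(n - 2 + t*^2).  For n = 7, alpha = 0.05 this gives the
    familiar 0.754 cut (critical t = 2.571).
    """
    if n < 3:
        raise ValueError("need n >= 3")
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    t_crit = float(stats.t.ppf(1.0 - alpha / 2.0, df=n - 2))
    return t_crit / math.sqrt(n - 2 + t_crit * t_crit)


def pairwise_pearson(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """All-pairs Pearson r between rows of A (p x n) and rows of B (q x n).

    Rows with zero variance yield NaN in their row/column of the result
    (callers must treat NaN as "undefined", not zero).
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    Ac = A - A.mean(axis=1, keepdims=True)
    Bc = B - B.mean(axis=1, keepdims=True)
    sa = np.linalg.norm(Ac, axis=1)
    sb = np.linalg.norm(Bc, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        R = (Ac @ Bc.T) / np.outer(sa, sb)
    R[sa == 0, :] = np.nan
    R[:, sb == 0] = np.nan
    return np.clip(R, -1.0, 1.0, out=R)


def _to_scale(values: np.ndarray, cfg: ScreenConfig) -> np.ndarray:
    if cfg.correlation_scale == "log2":
        if cfg.log2_pseudocount == 0 and (values <= 0).any():
            raise ValueError(
                "log2 scale with pseudocount 0 requires strictly positive values"
            )
        return np.log2(values + cfg.log2_pseudocount)
    return values


def correlate_sources_targets(
    sources: pd.DataFrame,
    targets: pd.DataFrame,
    genotype_id: str,
    cfg: ScreenConfig,
    pathway: str | None = None,
    source_scale: str | None = None,
) -> list[CorrelationRecord]:
    """Shared correlation core for the TF screen and the metabolite screen.

    ``sources`` and ``targets`` are row-per-series frames over the same
    stage columns.  Each (source, target) pair yields one record; pairs
    involving a zero-variance series are excluded with a reason.
    ``source_scale`` overrides the config scale for the source rows
    (metabolites are correlated on their measured scale).
    """
    n = sources.shape[1]
    if targets.shape[1] != n:
        raise ValueError("sources and targets must share the stage axis")
    df = n - 2
    t_crit = float(stats.t.ppf(1.0 - cfg.alpha / 2.0, df=df))
    S = _to_scale(sources.to_numpy(dtype=float), cfg) if source_scale is None else (
        _to_scale(sources.to_numpy(dtype=float),
                  replace(cfg, correlation_scale=source_scale)))
    T = _to_scale(targets.to_numpy(dtype=float), cfg)
    R = pairwise_pearson(S, T)
    src_const = np.ptp(S, axis=1) == 0
    tgt_const = np.ptp(T, axis=1) == 0
    # vectorised t statistics and two-sided p-values (|r| = 1 -> t = +/-inf)
    with np.errstate(divide="ignore", invalid="ignore"):
        T_STAT = np.where(np.abs(R) < 1.0,
                          R * math.sqrt(n - 2) / np.sqrt(1.0 - R * R),
                          np.sign(R) * np.inf)
        P_VAL = 2.0 * stats.t.sf(np.abs(T_STAT), df=df)
    SIG = (np.abs(R) >= cfg.r_threshold) & (np.abs(T_STAT) > t_crit)
    records: list[CorrelationRecord] = []
    for i, sid in enumerate(sources.index):
        for j, tid in enumerate(targets.index):
            if src_const[i] or tgt_const[j]:
                which = "source" if src_const[i] else "target"
                records.append(CorrelationRecord(
                    source_id=str(sid), target_id=str(tid),
                    genotype_id=genotype_id, pathway=pathway,
                    excluded_reason=f"zero-variance {which} series"))
                continue
            r = float(R[i, j])
            records.append(CorrelationRecord(
                source_id=str(sid), target_id=str(tid),
                genotype_id=genotype_id, pathway=pathway,
                r=r, n=n, t_stat=float(T_STAT[i, j]), df=df,
                p_value=float(P_VAL[i, j]),
                significant=bool(SIG[i, j]),
                sign="positive" if r >= 0 else "negative"))
    return records


def screen_pathway(
    m: ExpressionMatrix,
    catalog: GeneCatalog,
    pathway: str,
    cfg: ScreenConfig = ScreenConfig(),
) -> list[CorrelationRecord]:
    """Correlate every TF with every structural gene of ``pathway``.

    The expression filter (RPKM >= cfg.min_rpkm in at least
    cfg.min_stages_expressed stages) is applied internally to both the TF
    and structural-gene universes; TFs or genes absent from the matrix or
    failing the filter yield excluded records.  Raises if no TF or no
    structural gene survives.
    """
    genes = catalog.pathway_genes(pathway)
    filtered = expression_filter(m, cfg)
    present = set(filtered.data.index)
    tf_kept = [t for t in catalog.tf_ids if t in present]
    sg_kept = [g for g in genes if g in present]
    if not tf_kept:
        raise ValueError(
            f"no transcription factor passed the expression filter in "
            f"{m.genotype_id}"
        )
    if not sg_kept:
        raise ValueError(
            f"no structural gene of pathway {pathway!r} passed the "
            f"expression filter in {m.genotype_id}"
        )
    records = correlate_sources_targets(
        filtered.data.loc[tf_kept], filtered.data.loc[sg_kept],
        genotype_id=m.genotype_id, cfg=cfg, pathway=pathway)
    # excluded records for TFs / SGs dropped by the filter or absent
    for tf in catalog.tf_ids:
        if tf in present:
            continue
        reason = ("below expression floor" if tf in m.data.index
                  else "absent from matrix")
        for g in sg_kept:
            records.append(CorrelationRecord(
                source_id=tf, target_id=g, genotype_id=m.genotype_id,
                pathway=pathway, excluded_reason=f"TF {reason}"))
    for g in genes:
        if g in present:
            continue
        reason = ("below expression floor" if g in m.data.index
                  else "absent from matrix")
        for tf in tf_kept:
            records.append(CorrelationRecord(
                source_id=tf, target_id=g, genotype_id=m.genotype_id,
                pathway=pathway, excluded_reason=f"structural gene {reason}"))
    return records


def summarize_tf(
    records: Iterable[CorrelationRecord],
    catalog: GeneCatalog | None = None,
) -> list[TFSummaryRow]:
    """Collapse pair records into per-TF "N(P)" rows across genotypes.

    N = significant structural genes, P = the positively correlated
    subset; one row per TF, genotype counts side by side.  Records must
    all belong to one pathway.
    """
    records = list(records)
    if not records:
        raise ValueError("no correlation records to summarize")
    pathways = {rec.pathway for rec in records}
    if len(pathways) != 1:
        raise ValueError(f"records mix pathways: {sorted(map(str, pathways))}")
    pathway = next(iter(pathways)) or ""
    genotypes: list[str] = []
    tf_order: list[str] = []
    counts: dict[str, dict[str, list[int]]] = {}
    for rec in records:
        if rec.genotype_id not in genotypes:
            genotypes.append(rec.genotype_id)
        if rec.source_id not in counts:
            counts[rec.source_id] = {}
            tf_order.append(rec.source_id)
        pair = counts[rec.source_id].setdefault(rec.genotype_id, [0, 0])
        if rec.significant:
            pair[0] += 1
            if rec.sign == "positive":
                pair[1] += 1
    family = (catalog.tf_family if catalog is not None else {})
    rows = []
    for tf in tf_order:
        per_geno = {g: tuple(counts[tf].get(g, [0, 0])) for g in genotypes}
        rows.append(TFSummaryRow(tf_id=tf, family=family.get(tf, ""),
                                 pathway=pathway, counts=per_geno))
    return rows


def select_candidates(
    rows: Sequence[TFSummaryRow],
    min_count: int,
    require_both: bool = True,
) -> list[TFSummaryRow]:
    """Keep TFs with >= min_count correlated structural genes in every
    genotype (require_both) or in at least one; sorted by max count
    descending, tf_id ascending on ties."""
    if min_count < 0:
        raise ValueError("min_count must be >= 0")
    if require_both:
        kept = [r for r in rows
                if r.counts and all(n >= min_count for n, _ in r.counts.values())]
    else:
        kept = [r for r in rows
                if any(n >= min_count for n, _ in r.counts.values())]
    return sorted(kept, key=lambda r: (-r.max_count(), r.tf_id))


def cross_dataset_validate(
    primary_rows: Sequence[TFSummaryRow],
    extra_matrices: Sequence[ExpressionMatrix],
    catalog: GeneCatalog,
    pathway: str,
    cfg: ScreenConfig = ScreenConfig(),
    min_count: int = 1,
) -> pd.DataFrame:
    """Re-run the screen on independent datasets and cross-tabulate counts.

    Returns one row per TF of ``primary_rows`` with per-dataset
    ``<dataset>_n_correlated`` / ``_n_positive`` columns and a
    ``significant_in_all`` flag (n_correlated >= min_count in every
    dataset, primary genotypes included).  With no extra matrices the
    primary counts are returned unchanged.
    """
    tf_ids = [r.tf_id for r in primary_rows]
    if not tf_ids:
        raise ValueError("no primary rows")
    table: dict[str, dict[str, int]] = {tf: {} for tf in tf_ids}
    datasets: list[str] = []
    for row in primary_rows:
        for geno, (n, n_pos) in row.counts.items():
            if geno not in datasets:
                datasets.append(geno)
            table[row.tf_id][f"{geno}_n_correlated"] = n
            table[row.tf_id][f"{geno}_n_positive"] = n_pos
    for m in extra_matrices:
        shared = set(m.data.index) & (set(catalog.tf_ids)
                                      | set(catalog.pathway_genes(pathway)))
        if not shared:
            raise ValueError(
                f"dataset {m.genotype_id!r} shares no gene ids with the catalog"
            )
        rows = summarize_tf(screen_pathway(m, catalog, pathway, cfg), catalog)
        datasets.append(m.genotype_id)
        by_tf = {r.tf_id: r.counts.get(m.genotype_id, (0, 0)) for r in rows}
        for tf in tf_ids:
            n, n_pos = by_tf.get(tf, (0, 0))
            table[tf][f"{m.genotype_id}_n_correlated"] = n
            table[tf][f"{m.genotype_id}_n_positive"] = n_pos
    df = pd.DataFrame.from_dict(table, orient="index").fillna(0).astype(int)
    df.index.name = "tf_id"
    df["significant_in_all"] = np.all(
        [df[f"{d}_n_correlated"] >= min_count for d in datasets], axis=0)
    return df


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """BH-adjusted q-values (optional extension; the screen applies no
    multiple-testing correction by default)."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p)
    ranked = p[order] * m / (np.arange(m) + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(q, 0.0, 1.0)
    return out
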