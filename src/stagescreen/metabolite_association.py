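"""Metabolite-transcript correlation.

A metabolite's stage course (ascorbate forms, carotenoids, flavonoids)
is correlated with the expression of each structural gene and candidate
transcription factor under exactly the same significance rule as the
TF-gene screen (|r| >= threshold and the correlation t-test at level
alpha, n = stages, df = n - 2).  The metabolite series enters on its
measured concentration scale; no transform is applied to it.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .coexpression_screen import CorrelationRecord, correlate_sources_targets
from .data_model import ExpressionMatrix, GeneCatalog, MetaboliteSeries, ScreenConfig
from .quantification import expression_filter

__all__ = ["metabolite_gene_correlation", "pathway_metabolite_report"]


def metabolite_gene_correlation(
    met: MetaboliteSeries,
    m: ExpressionMatrix,
    gene_ids: Sequence[str],
    cfg: ScreenConfig = ScreenConfig(),
    pathway: str | None = None,
) -> list[CorrelationRecord]:
    """Correlate one metabolite with a set of genes in one genotype.

    Shares the correlation/significance code path with the TF screen
    (the metabolite simply plays the source role).  The stage axes and
    genotypes must match; a constant metabolite series is an error
    because its correlation is undefined for every gene.
    """
    if met.axis != m.axis:
        raise ValueError(
            f"stage axis mismatch: metabolite {met.axis.stages} vs "
            f"expression {m.axis.stages}"
        )
    if met.genotype_id != m.genotype_id:
        raise ValueError(
            f"genotype mismatch: {met.genotype_id!r} vs {m.genotype_id!r}"
        )
    if np.ptp(met.values) == 0:
        raise ValueError(
            f"metabolite {met.metabolite_id!r} is constant across stages; "
            "correlation undefined"
        )
    filtered = expression_filter(m, cfg)
    kept = [g for g in gene_ids if g in filtered.data.index]
    records: list[CorrelationRecord] = []
    if kept:
        sources = pd.DataFrame([met.values], index=[met.metabolite_id],
                               columns=m.data.columns)
        records = correlate_sources_targets(
            sources, filtered.data.loc[kept], genotype_id=m.genotype_id,
            cfg=cfg, pathway=pathway, source_scale="raw")
    for g in gene_ids:
        if g in filtered.data.index:
            continue
        reason = ("below expression floor" if g in m.data.index
                  else "absent from matrix")
        records.append(CorrelationRecord(
            source_id=met.metabolite_id, target_id=g,
            genotype_id=m.genotype_id, pathway=pathway,
            excluded_reason=f"gene {reason}"))
    return records


def pathway_metabolite_report(
    records: Iterable[CorrelationRecord],
    catalog: GeneCatalog,
    pathway: str,
) -> pd.DataFrame:
    """Per-metabolite summary of significant correlations by gene class.

    For each metabolite and each class (structural genes of ``pathway``
    vs TFs): tested/significant/positive/negative counts and the
    corresponding percentages of tested genes.  positive% + negative% =
    significant% by construction.
    """
    records = list(records)
    if not records:
        raise ValueError("no correlation records")
    sg_set = set(catalog.pathway_genes(pathway))
    tf_set = set(catalog.tf_ids)
    rows = []
    by_met: dict[str, list[CorrelationRecord]] = {}
    for rec in records:
        by_met.setdefault(rec.source_id, []).append(rec)
    for met_id, recs in by_met.items():
        for cls, members in (("structural", sg_set), ("tf", tf_set)):
            scored = [r for r in recs
                      if r.target_id in members and r.excluded_reason is None]
            if not scored:
                continue
            n_sig = sum(r.significant for r in scored)
            n_pos = sum(r.significant and r.sign == "positive" for r in scored)
            n_neg = n_sig - n_pos
            n = len(scored)
            rows.append({
                "metabolite_id": met_id,
                "gene_class": cls,
                "n_tested": n,
                "n_significant": n_sig,
                "n_positive": n_pos,
                "n_negative": n_neg,
                "pct_significant": 100.0 * n_sig / n,
                "pct_positive": 100.0 * n_pos / n,
                "pct_negative": 100.0 * n_neg / n,
            })
    if not rows:
        raise ValueError(
            "no scorable records for either gene class; check gene ids"
        )
    return pd.DataFrame(rows)
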