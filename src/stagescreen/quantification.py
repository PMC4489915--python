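"""RPKM computation, expression filtering and fold-change labeling.

RPKM (reads per kilobase of gene per million mapped reads) is
``10^9 * count / (library_size * gene_length)``.  The stage-over-stage
fold-change table reproduces the reporting conventions of developmental
RNA-seq studies: a numeric ratio when both stages are expressed, "-" when
neither stage is, "<value>/0" when a gene switches on between stages, and
"0" when it switches off.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .data_model import ExpressionMatrix, ReadCountRecord, ScreenConfig

__all__ = [
    "FoldChangeKind",
    "FoldChangeRecord",
    "DEConfig",
    "compute_rpkm",
    "rpkm_matrix",
    "count_expressed",
    "expression_filter",
    "fold_change_table",
    "de_flag",
    "write_fold_change_table",
    "read_fold_change_table",
]


def compute_rpkm(rec: ReadCountRecord) -> float:
    """RPKM = 10^9 * count / (library_size * gene_length)."""
    return 1e9 * rec.count / (rec.library_size * rec.gene_length)


def rpkm_matrix(
    counts: pd.DataFrame, gene_lengths: pd.Series, library_sizes: pd.Series
) -> pd.DataFrame:
    """Vectorised RPKM over a gene x sample count table.

    ``gene_lengths`` is indexed by gene (bases), ``library_sizes`` by
    sample column (total uniquely mapped reads).
    """
    lengths = gene_lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()].tolist()[:5]
        raise ValueError(f"missing gene lengths for {missing}")
    if (lengths <= 0).any() or (library_sizes <= 0).any():
        raise ValueError("gene lengths and library sizes must be > 0")
    libs = library_sizes.reindex(counts.columns)
    return 1e9 * counts.div(lengths, axis=0).div(libs, axis=1)


def count_expressed(counts: Iterable[int], floor: int = 0) -> int:
    """Number of genes whose read count exceeds ``floor`` in one sample."""
    if floor < 0:
        raise ValueError(f"floor must be >= 0, got {floor}")
    arr = np.asarray(list(counts))
    if (arr < 0).any():
        raise ValueError("read counts must be >= 0")
    return int((arr > floor).sum())


def expression_filter(m: ExpressionMatrix, cfg: ScreenConfig) -> ExpressionMatrix:
    """Keep genes with RPKM >= cfg.min_rpkm in >= cfg.min_stages_expressed
    stages (default: >= 5.0 in at least one stage).  Idempotent; may
    return an empty matrix."""
    values = m.values()
    keep = (values >= cfg.min_rpkm).sum(axis=1) >= cfg.min_stages_expressed
    return ExpressionMatrix(m.genotype_id, m.axis, m.data.loc[keep])


class FoldChangeKind(str, Enum):
    RATIO = "RATIO"              # both stages expressed: value = later/earlier
    FROM_ZERO = "FROM_ZERO"      # switched on: value = later-stage RPKM
    TO_ZERO = "TO_ZERO"          # switched off (rendered "0")
    NOT_DETECTED = "NOT_DETECTED"  # expressed in neither stage (rendered "-")


@dataclass(frozen=True)
class FoldChangeRecord:
    gene_id: str
    stage_pair: tuple[int, int]
    kind: FoldChangeKind
    value: float | None

    def __post_init__(self) -> None:
        if self.kind is FoldChangeKind.RATIO:
            if self.value is None or self.value <= 0:
                raise ValueError(
                    f"{self.gene_id} {self.stage_pair}: RATIO needs value > 0"
                )
        elif self.kind is FoldChangeKind.FROM_ZERO:
            if self.value is None or self.value <= 0:
                raise ValueError(
                    f"{self.gene_id} {self.stage_pair}: FROM_ZERO carries the "
                    "later-stage expression (> 0)"
                )
        elif self.value is not None:
            raise ValueError(
                f"{self.gene_id} {self.stage_pair}: {self.kind.value} carries "
                "no value"
            )

    @property
    def pair_label(self) -> str:
        earlier, later = self.stage_pair
        return f"{later}v{earlier}"

    def rendered(self) -> str:
        """Cell text using the published conventions."""
        if self.kind is FoldChangeKind.NOT_DETECTED:
            return "-"
        if self.kind is FoldChangeKind.TO_ZERO:
            return "0"
        if self.kind is FoldChangeKind.FROM_ZERO:
            return f"{_fmt(self.value)}/0"
        return _fmt(self.value)


def _fmt(x: float) -> str:
    return format(float(x), "g")


@dataclass(frozen=True)
class DEConfig:
    """Differential-expression call: |log2 ratio| > log2_cut and (when an
    external p-value is supplied) p < p_cut."""

    log2_cut: float = 2.0
    p_cut: float = 0.01

    def __post_init__(self) -> None:
        if self.log2_cut <= 0:
            raise ValueError("log2_cut must be > 0")
        if not (0.0 < self.p_cut < 1.0):
            raise ValueError("p_cut must be in (0, 1)")


def fold_change_table(
    m: ExpressionMatrix,
    mode: str = "consecutive",
    detection_floor: float = 0.0,
) -> list[FoldChangeRecord]:
    """Stage-over-stage fold changes for every gene.

    mode="consecutive" pairs each stage with the previous one;
    mode="vs_first" pairs every later stage with the first (7 DAF
    baseline).  A stage is "not detected" when its RPKM <= detection_floor
    (default: exactly 0).
    """
    if mode not in ("consecutive", "vs_first"):
        raise ValueError(f"mode must be 'consecutive' or 'vs_first', got {mode!r}")
    if detection_floor < 0:
        raise ValueError("detection_floor must be >= 0")
    stages = m.axis.stages
    if len(stages) < 2:
        raise ValueError("fold changes need at least 2 stages")
    if mode == "consecutive":
        pairs = list(zip(stages, stages[1:]))
    else:
        pairs = [(stages[0], s) for s in stages[1:]]
    records: list[FoldChangeRecord] = []
    values = m.data
    for gene_id, row in values.iterrows():
        for earlier, later in pairs:
            e, l = float(row[earlier]), float(row[later])
            e_on = e > detection_floor
            l_on = l > detection_floor
            if not e_on and not l_on:
                rec = FoldChangeRecord(gene_id, (earlier, later),
                                       FoldChangeKind.NOT_DETECTED, None)
            elif not e_on:
                rec = FoldChangeRecord(gene_id, (earlier, later),
                                       FoldChangeKind.FROM_ZERO, l)
            elif not l_on:
                rec = FoldChangeRecord(gene_id, (earlier, later),
                                       FoldChangeKind.TO_ZERO, None)
            else:
                rec = FoldChangeRecord(gene_id, (earlier, later),
                                       FoldChangeKind.RATIO, l / e)
            records.append(rec)
    return records


def de_flag(
    fc: FoldChangeRecord,
    p_value: float | None = None,
    cfg: DEConfig = DEConfig(),
    from_zero_is_de: bool = False,
) -> bool:
    """Differential-expression call for one fold-change record.

    RATIO records are DE when |log2(value)| > cfg.log2_cut and, if an
    externally computed p-value is supplied, p < cfg.p_cut.  NOT_DETECTED
    and TO_ZERO are never DE; FROM_ZERO (infinite fold change) is DE only
    when ``from_zero_is_de`` is enabled.
    """
    if p_value is not None and not (0.0 <= p_value <= 1.0):
        raise ValueError(f"p-value must be in [0, 1], got {p_value}")
    if fc.kind in (FoldChangeKind.NOT_DETECTED, FoldChangeKind.TO_ZERO):
        return False
    if fc.kind is FoldChangeKind.FROM_ZERO:
        return from_zero_is_de and (p_value is None or p_value < cfg.p_cut)
    passes_fc = abs(math.log2(fc.value)) > cfg.log2_cut
    passes_p = p_value is None or p_value < cfg.p_cut
    return passes_fc and passes_p


def write_fold_change_table(
    records: Sequence[FoldChangeRecord], path: str | Path
) -> Path:
    """Wide TSV: gene_id then one rendered cell per stage pair."""
    path = Path(path)
    table: dict[str, dict[str, str]] = {}
    pair_order: list[str] = []
    for rec in records:
        if rec.pair_label not in pair_order:
            pair_order.append(rec.pair_label)
        table.setdefault(rec.gene_id, {})[rec.pair_label] = rec.rendered()
    df = pd.DataFrame.from_dict(table, orient="index").reindex(columns=pair_order)
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")
    return path


def _parse_cell(gene_id: str, label: str, cell: str) -> FoldChangeRecord:
    later, earlier = (int(x) for x in label.split("v"))
    pair = (earlier, later)
    if cell == "-":
        return FoldChangeRecord(gene_id, pair, FoldChangeKind.NOT_DETECTED, None)
    if cell == "0":
        return FoldChangeRecord(gene_id, pair, FoldChangeKind.TO_ZERO, None)
    if cell.endswith("/0"):
        return FoldChangeRecord(gene_id, pair, FoldChangeKind.FROM_ZERO,
                                float(cell[:-2]))
    return FoldChangeRecord(gene_id, pair, FoldChangeKind.RATIO, float(cell))


def read_fold_change_table(path: str | Path) -> list[FoldChangeRecord]:
    """Inverse of :func:`write_fold_change_table` (round-trip contract for
    the rendered conventions)."""
    df = pd.read_csv(Path(path), sep="\t", dtype=str).set_index("gene_id")
    records = []
    for gene_id, row in df.iterrows():
        for label, cell in row.items():
            records.append(_parse_cell(str(gene_id), str(label), str(cell)))
    return records
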