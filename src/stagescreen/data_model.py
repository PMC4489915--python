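"""Shared domain types and tabular I/O for the stage-course screen.

Everything downstream works on three in-memory containers: an
:class:`ExpressionMatrix` (gene x stage RPKM grid for one genotype), a
:class:`GeneCatalog` (pathway structural-gene sets plus the transcription
factor list), and a :class:`MetaboliteSeries` (one metabolite's stage
course in one genotype).  All tabular files are plain TSV (UTF-8, '.'
decimal); stage columns are identified *by name* ("DAF7", "DAF14", ...)
rather than by position so that columns can never be silently swapped
between genotypes.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "StageAxis",
    "ExpressionMatrix",
    "ReadCountRecord",
    "GeneCatalog",
    "MetaboliteSeries",
    "ScreenConfig",
    "GeneListResult",
    "TFSummaryRow",
    "ParseError",
    "DEFAULT_STAGES",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_gene_list",
    "read_catalog_manifest",
    "read_metabolite_table",
    "write_metabolite_table",
    "write_tf_summary",
]

#: The weekly sampling axis used throughout: 7-49 days after flowering.
DEFAULT_STAGES: tuple[int, ...] = (7, 14, 21, 28, 35, 42, 49)

_STAGE_RE = re.compile(r"^DAF(\d+)$")


class ParseError(ValueError):
    """Structured error for malformed tabular inputs (names row/column)."""


@dataclass(frozen=True)
class StageAxis:
    """Ordered developmental time axis in days after flowering (DAF).

    Must be strictly increasing and hold at least 3 stages — Pearson
    significance needs df = n - 2 >= 1.
    """

    stages: tuple[int, ...] = DEFAULT_STAGES

    def __post_init__(self) -> None:
        stages = tuple(int(s) for s in self.stages)
        object.__setattr__(self, "stages", stages)
        if len(stages) < 3:
            raise ValueError(f"stage axis needs >= 3 stages, got {len(stages)}")
        if any(b <= a for a, b in zip(stages, stages[1:])):
            raise ValueError(f"stage axis must be strictly increasing: {stages}")

    def __len__(self) -> int:
        return len(self.stages)

    @property
    def labels(self) -> list[str]:
        return [f"DAF{s}" for s in self.stages]


@dataclass
class ExpressionMatrix:
    """Gene x stage grid of non-negative RPKM values for one genotype.

    ``data`` is indexed by gene id with one column per DAF stage (integer
    column labels matching ``axis.stages``).
    """

    genotype_id: str
    axis: StageAxis
    data: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.data.columns) != list(self.axis.stages):
            self.data = self.data.copy()
            self.data.columns = list(self.axis.stages)[: len(self.data.columns)]
            if list(self.data.columns) != list(self.axis.stages):
                raise ValueError("data columns do not match stage axis")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups}")
        self.data.index.name = "gene_id"
        values = self.data.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise ValueError("expression values must be finite")
        if (values < 0).any():
            gi, si = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative expression for gene {self.data.index[gi]!r} "
                f"at DAF{self.axis.stages[si]}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def n_genes(self) -> int:
        return len(self.data)

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def subset(self, gene_ids: Iterable[str]) -> "ExpressionMatrix":
        ids = [g for g in gene_ids if g in self.data.index]
        return ExpressionMatrix(self.genotype_id, self.axis, self.data.loc[ids])


@dataclass(frozen=True)
class ReadCountRecord:
    """Inputs of the RPKM formula for one gene in one sample."""

    gene_id: str
    count: int
    gene_length: float
    library_size: int

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError(f"{self.gene_id}: read count must be >= 0")
        if self.gene_length <= 0:
            raise ValueError(f"{self.gene_id}: gene length must be > 0")
        if self.library_size <= 0:
            raise ValueError(f"{self.gene_id}: library size must be > 0")
        if self.count > self.library_size:
            raise ValueError(
                f"{self.gene_id}: count {self.count} exceeds library size "
                f"{self.library_size}"
            )


@dataclass
class GeneCatalog:
    """Pathway -> structural-gene sets plus the TF universe.

    ``pathways`` maps a pathway name ("ascorbate", "carotenoid",
    "flavonoid", ...) to the ordered list of its structural (enzyme
    encoding) gene ids.  ``tf_ids`` is the screened transcription-factor
    universe; ``tf_family`` optionally annotates each TF with its family
    (MYB, NAC, bHLH, Dof, ...).
    """

    pathways: dict[str, list[str]]
    tf_ids: list[str]
    tf_family: dict[str, str] = field(default_factory=dict)
    allow_tf_overlap: bool = False

    def __post_init__(self) -> None:
        for name, genes in self.pathways.items():
            if not genes:
                raise ValueError(f"pathway {name!r} has an empty gene set")
            if len(set(genes)) != len(genes):
                raise ValueError(f"pathway {name!r} has duplicate gene ids")
        if len(set(self.tf_ids)) != len(self.tf_ids):
            raise ValueError("duplicate TF ids")
        if not self.allow_tf_overlap:
            tfs = set(self.tf_ids)
            for name, genes in self.pathways.items():
                overlap = tfs & set(genes)
                if overlap:
                    raise ValueError(
                        f"TF ids overlap pathway {name!r}: {sorted(overlap)}"
                    )

    def pathway_genes(self, pathway: str) -> list[str]:
        try:
            return list(self.pathways[pathway])
        except KeyError:
            raise KeyError(
                f"unknown pathway {pathway!r}; have {sorted(self.pathways)}"
            ) from None


@dataclass
class MetaboliteSeries:
    """One metabolite's concentration course over the stage axis."""

    metabolite_id: str
    genotype_id: str
    axis: StageAxis
    values: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.axis),):
            raise ValueError(
                f"{self.metabolite_id}: expected {len(self.axis)} values, "
                f"got {self.values.shape}"
            )
        if not np.isfinite(self.values).all() or (self.values < 0).any():
            raise ValueError(
                f"{self.metabolite_id}: concentrations must be finite and >= 0"
            )


@dataclass(frozen=True)
class ScreenConfig:
    """Thresholds of the co-expression screen.

    min_rpkm / min_stages_expressed implement the expression floor
    ("RPKM >= 5.0 in at least one stage"); r_threshold is the |r| cut for
    calling a pair correlated; alpha is the two-sided level of the
    correlation t-test.  ``correlation_scale`` selects raw RPKM (the
    default, matching a spreadsheet CORREL on the RPKM table) or
    log2(RPKM + log2_pseudocount).
    """

    min_rpkm: float = 5.0
    min_stages_expressed: int = 1
    r_threshold: float = 0.8
    alpha: float = 0.05
    correlation_scale: str = "raw"
    log2_pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.r_threshold <= 1.0):
            raise ValueError(f"r_threshold must be in (0, 1], got {self.r_threshold}")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.min_rpkm < 0:
            raise ValueError(f"min_rpkm must be >= 0, got {self.min_rpkm}")
        if self.min_stages_expressed < 1:
            raise ValueError("min_stages_expressed must be >= 1")
        if self.correlation_scale not in ("raw", "log2"):
            raise ValueError(
                f"correlation_scale must be 'raw' or 'log2', got "
                f"{self.correlation_scale!r}"
            )
        if self.correlation_scale == "log2" and self.log2_pseudocount < 0:
            raise ValueError("log2_pseudocount must be >= 0")


@dataclass(frozen=True)
class GeneListResult:
    """De-duplicated, order-preserving gene list plus a duplicate tally."""

    ids: tuple[str, ...]
    n_duplicates_dropped: int

    def __len__(self) -> int:
        return len(self.ids)

    def __iter__(self):
        return iter(self.ids)


@dataclass
class TFSummaryRow:
    """Per-TF, per-pathway correlated-gene counts ("25(20)" notation).

    ``counts`` maps genotype id -> (n_correlated, n_positive) where
    n_correlated counts structural genes significantly correlated with the
    TF and n_positive the subset with r > 0.
    """

    tf_id: str
    family: str
    pathway: str
    counts: dict[str, tuple[int, int]]

    def __post_init__(self) -> None:
        for geno, (n, n_pos) in self.counts.items():
            if not (0 <= n_pos <= n):
                raise ValueError(
                    f"{self.tf_id}/{geno}: n_positive ({n_pos}) must be in "
                    f"[0, n_correlated={n}]"
                )

    def rendered(self, genotype_id: str) -> str:
        n, n_pos = self.counts[genotype_id]
        return f"{n}({n_pos})"

    def n_correlated(self, genotype_id: str) -> int:
        return self.counts[genotype_id][0]

    def max_count(self) -> int:
        return max((n for n, _ in self.counts.values()), default=0)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _parse_stage_header(columns: Sequence[str], path: Path) -> StageAxis:
    if not columns or columns[0] != "gene_id":
        raise ParseError(
            f"{path}: first header column must be 'gene_id', got "
            f"{columns[0] if columns else 'nothing'!r}"
        )
    stages = []
    for col in columns[1:]:
        m = _STAGE_RE.match(col)
        if not m:
            raise ParseError(f"{path}: stage column {col!r} does not match 'DAF<k>'")
        stages.append(int(m.group(1)))
    try:
        return StageAxis(tuple(stages))
    except ValueError as exc:
        raise ParseError(f"{path}: bad stage axis: {exc}") from exc


def read_expression_matrix(path: str | Path, genotype_id: str) -> ExpressionMatrix:
    """Read a gene x stage RPKM TSV (header ``gene_id\\tDAF7\\t...``).

    Raises :class:`ParseError` naming the offending row/column for a
    malformed header, a non-numeric or negative cell, or a duplicated
    gene id.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    axis = _parse_stage_header(list(df.columns), path)
    df = df.set_index("gene_id")
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ParseError(f"{path}: duplicate gene ids: {dups}")
    numeric = pd.DataFrame(index=df.index)
    for col, stage in zip(df.columns, axis.stages):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() | df[col].isna()
        if bad.any():
            gene = df.index[bad.to_numpy().argmax()]
            raise ParseError(
                f"{path}: non-numeric or missing value for gene {gene!r} "
                f"in column {col}"
            )
        if (converted < 0).any():
            gene = converted.index[(converted < 0).to_numpy().argmax()]
            raise ParseError(
                f"{path}: negative RPKM for gene {gene!r} in column {col}"
            )
        # re-parse via the correctly-rounded strtod for exact round-trips
        # (pd.to_numeric's fast parser can be one ulp off)
        numeric[stage] = df[col].astype(float)
    return ExpressionMatrix(genotype_id=genotype_id, axis=axis, data=numeric)


def write_expression_matrix(
    m: ExpressionMatrix, path: str | Path, float_format: str | None = None
) -> Path:
    """Write the expression TSV; by default floats use their full repr so
    that ``read(write(X)) == X`` bit-for-bit."""
    path = Path(path)
    out = m.data.copy()
    out.columns = m.axis.labels
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", float_format=float_format)
    return path


def read_gene_list(path: str | Path) -> GeneListResult:
    """Read a one-id-per-line gene list ('#' comments and blanks ignored).

    Returns the order-preserving de-duplicated ids and the number of
    duplicates dropped; an effectively empty file is an error.
    """
    path = Path(path)
    seen: dict[str, None] = {}
    n_dup = 0
    for line in path.read_text().splitlines():
        token = line.strip()
        if not token or token.startswith("#"):
            continue
        if token in seen:
            n_dup += 1
        else:
            seen[token] = None
    if not seen:
        raise ParseError(f"{path}: gene list is empty after removing comments")
    return GeneListResult(ids=tuple(seen), n_duplicates_dropped=n_dup)


def read_catalog_manifest(path: str | Path) -> GeneCatalog:
    """Build a :class:`GeneCatalog` from a JSON manifest.

    Schema::

        {"pathways": {"ascorbate": "asc_genes.txt", ...},
         "tf_list": "tfs.txt",
         "tf_family": {"TF0001": "MYB", ...}}      # optional

    List paths are resolved relative to the manifest's directory.
    """
    path = Path(path)
    spec = json.loads(path.read_text())
    base = path.parent
    pathways = {
        name: list(read_gene_list(base / listfile).ids)
        for name, listfile in spec["pathways"].items()
    }
    tf_ids = list(read_gene_list(base / spec["tf_list"]).ids)
    return GeneCatalog(
        pathways=pathways,
        tf_ids=tf_ids,
        tf_family=dict(spec.get("tf_family", {})),
        allow_tf_overlap=bool(spec.get("allow_tf_overlap", False)),
    )


def read_metabolite_table(path: str | Path) -> list[MetaboliteSeries]:
    """Read the metabolite TSV (metabolite_id, genotype, units, DAF...)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    required = ["metabolite_id", "genotype", "units"]
    if list(df.columns[:3]) != required:
        raise ParseError(
            f"{path}: header must start with {required}, got {list(df.columns[:3])}"
        )
    stages = []
    for col in df.columns[3:]:
        m = _STAGE_RE.match(col)
        if not m:
            raise ParseError(f"{path}: stage column {col!r} does not match 'DAF<k>'")
        stages.append(int(m.group(1)))
    axis = StageAxis(tuple(stages))
    out = []
    for _, row in df.iterrows():
        out.append(
            MetaboliteSeries(
                metabolite_id=str(row["metabolite_id"]),
                genotype_id=str(row["genotype"]),
                units=str(row["units"]),
                axis=axis,
                values=row.iloc[3:].to_numpy(dtype=float),
            )
        )
    return out


def write_metabolite_table(series: Sequence[MetaboliteSeries], path: str | Path) -> Path:
    path = Path(path)
    if not series:
        raise ValueError("no metabolite series to write")
    axis = series[0].axis
    rows = []
    for s in series:
        if s.axis != axis:
            raise ValueError("metabolite series must share one stage axis")
        rows.append([s.metabolite_id, s.genotype_id, s.units, *s.values])
    df = pd.DataFrame(rows, columns=["metabolite_id", "genotype", "units", *axis.labels])
    df.to_csv(path, sep="\t", index=False)
    return path


def write_tf_summary(rows: Sequence[TFSummaryRow], path: str | Path) -> Path:
    """Write the per-TF summary TSV with the Table-3-style "N(P)" cells.

    Columns: tf_id, family, pathway, then per genotype
    ``<geno>_n_correlated``, ``<geno>_n_positive`` and ``<geno>_summary``.
    Refuses to write any row with n_positive > n_correlated (re-validated
    here in case a row was mutated after construction).
    """
    path = Path(path)
    genotypes: list[str] = []
    for row in rows:
        for geno, (n, n_pos) in row.counts.items():
            if n_pos > n:
                raise ValueError(
                    f"{row.tf_id}/{geno}: n_positive {n_pos} > n_correlated {n}"
                )
            if geno not in genotypes:
                genotypes.append(geno)
    records = []
    for row in rows:
        rec: dict[str, object] = {
            "tf_id": row.tf_id,
            "family": row.family,
            "pathway": row.pathway,
        }
        for geno in genotypes:
            n, n_pos = row.counts.get(geno, (0, 0))
            rec[f"{geno}_n_correlated"] = n
            rec[f"{geno}_n_positive"] = n_pos
            rec[f"{geno}_summary"] = f"{n}({n_pos})"
        records.append(rec)
    pd.DataFrame(records).to_csv(path, sep="\t", index=False)
    return path
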