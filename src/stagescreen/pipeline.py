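"""End-to-end orchestration: simulate -> filter -> cluster -> screen ->
metabolite correlation, with a config snapshot and a digest manifest so a
run can be reproduced and verified byte for byte.

The run is driven by a single JSON config with one section per stage;
unknown keys and invalid thresholds are rejected *before* any stage
executes.  Identical config + seed produces identical tabular outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import pandas as pd

from . import __version__
from .coexpression_screen import (
    CorrelationRecord,
    screen_pathway,
    select_candidates,
    summarize_tf,
)
from .data_model import (
    ExpressionMatrix,
    ScreenConfig,
    write_expression_matrix,
    write_metabolite_table,
    write_tf_summary,
)
from .metabolite_association import (
    metabolite_gene_correlation,
    pathway_metabolite_report,
)
from .quantification import expression_filter
from .synthetic_data import SimConfig, simulate_experiment
from .temporal_clustering import (
    kmeans_profiles,
    log2_profiles,
    stage_correlation_matrix,
)

__all__ = ["ConfigError", "RunManifest", "run_pipeline", "records_to_frame",
           "validate_config", "DEFAULT_SELECTION"]

log = logging.getLogger("stagescreen")

#: Default per-pathway candidate selection rules.
DEFAULT_SELECTION: dict[str, dict[str, Any]] = {
    "ascorbate": {"min_count": 15, "require_both": False},
    "carotenoid": {"min_count": 5, "require_both": True},
    "flavonoid": {"min_count": 2, "require_both": False},
}

_TOP_KEYS = {"seed", "simulate", "filter", "cluster", "screen", "metabolites"}


class ConfigError(ValueError):
    """Raised for a malformed pipeline config, before any computation."""


@dataclass
class RunManifest:
    """Record of one pipeline run: config, seed, outputs and digests."""

    seed: int
    config: dict[str, Any]
    version: str = __version__
    started: float = 0.0
    finished: float = 0.0
    stages: dict[str, dict[str, Any]] = field(default_factory=dict)

    def add_stage(self, name: str, out_dir: Path, outputs: Sequence[Path],
                  counts: Mapping[str, int]) -> None:
        self.stages[name] = {
            "outputs": {str(p.relative_to(out_dir)): _sha256(p) for p in outputs},
            "counts": dict(counts),
        }

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    def verify(self, out_dir: str | Path) -> bool:
        """Re-digest every referenced output and compare."""
        out_dir = Path(out_dir)
        for stage in self.stages.values():
            for rel, digest in stage["outputs"].items():
                if _sha256(out_dir / rel) != digest:
                    return False
        return True


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def records_to_frame(records: Sequence[CorrelationRecord]) -> pd.DataFrame:
    """Flatten pair-level correlation records into a tidy table."""
    return pd.DataFrame([dataclasses.asdict(r) for r in records])


def validate_config(config: Mapping[str, Any]) -> dict[str, Any]:
    """Validate the pipeline config and materialise stage configs.

    Returns a dict with keys seed, sim_cfg, screen_cfg, cluster, selection,
    raising :class:`ConfigError` on unknown keys or invalid values — all
    threshold validation happens here, before any stage runs.
    """
    unknown = set(config) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown config sections: {sorted(unknown)}")
    seed = int(config.get("seed", 0))
    try:
        sim_cfg = SimConfig(seed=seed, **config.get("simulate", {}))
        filt = dict(config.get("filter", {}))
        screen_section = dict(config.get("screen", {}))
        selection = {**DEFAULT_SELECTION,
                     **screen_section.pop("selection", {})}
        screen_cfg = ScreenConfig(
            min_rpkm=filt.get("min_rpkm", 5.0),
            min_stages_expressed=filt.get("min_stages_expressed", 1),
            **screen_section,
        )
        cluster = {"k": 20, "n_init": 10, "pseudocount": 1.0, "joint": False,
                   **config.get("cluster", {})}
        if cluster["k"] < 1:
            raise ConfigError("cluster.k must be >= 1")
    except ConfigError:
        raise
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc
    return {"seed": seed, "sim_cfg": sim_cfg, "screen_cfg": screen_cfg,
            "cluster": cluster, "selection": selection}


def run_pipeline(config: Mapping[str, Any] | str | Path,
                 out_dir: str | Path) -> RunManifest:
    """Execute all stages in dependency order; returns the manifest.

    ``config`` may be a mapping or a path to a JSON file.  Outputs land
    under ``out_dir``; the manifest itself is written to
    ``out_dir/manifest.json``.  A stage failure leaves the outputs of the
    completed stages plus a ``failure.json`` record.
    """
    if isinstance(config, (str, Path)):
        config = json.loads(Path(config).read_text())
    config = dict(config)
    parsed = validate_config(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(seed=parsed["seed"], config=config,
                           started=time.time())
    try:
        _run_stages(parsed, out_dir, manifest)
    except Exception as exc:
        (out_dir / "failure.json").write_text(json.dumps(
            {"failed_after_stages": list(manifest.stages), "error": str(exc)},
            indent=2))
        raise
    manifest.finished = time.time()
    (out_dir / "manifest.json").write_text(manifest.to_json())
    return manifest


def _run_stages(parsed: dict[str, Any], out_dir: Path,
                manifest: RunManifest) -> None:
    sim_cfg: SimConfig = parsed["sim_cfg"]
    screen_cfg: ScreenConfig = parsed["screen_cfg"]
    seed: int = parsed["seed"]

    # -- simulate ----------------------------------------------------------
    sim = simulate_experiment(sim_cfg)
    outputs = []
    for geno, m in sim.matrices.items():
        p = out_dir / f"expression_{_safe(geno)}.tsv"
        write_expression_matrix(m, p)
        outputs.append(p)
    p = out_dir / "metabolites.tsv"
    write_metabolite_table(sim.metabolites, p)
    outputs.append(p)
    truth_path = out_dir / "truth.json"
    truth_path.write_text(json.dumps({
        "seed": sim.truth.seed,
        "noise_sd": sim.truth.noise_sd,
        "links": [dataclasses.asdict(l) for l in sim.truth.links],
        "library_sizes": sim.truth.library_sizes,
    }, indent=2))
    outputs.append(truth_path)
    manifest.add_stage("simulate", out_dir, outputs, {
        "n_genes": next(iter(sim.matrices.values())).n_genes,
        "n_genotypes": len(sim.matrices),
        "n_planted_links": len(sim.truth.links),
        "n_metabolite_series": len(sim.metabolites),
    })
    log.info("simulate: %d genes x %d genotypes, %d planted links",
             next(iter(sim.matrices.values())).n_genes, len(sim.matrices),
             len(sim.truth.links))

    # -- filter ------------------------------------------------------------
    filtered: dict[str, ExpressionMatrix] = {}
    outputs = []
    counts = {}
    for geno, m in sim.matrices.items():
        f = expression_filter(m, screen_cfg)
        filtered[geno] = f
        p = out_dir / f"filtered_{_safe(geno)}.tsv"
        write_expression_matrix(f, p)
        outputs.append(p)
        counts[f"kept_{_safe(geno)}"] = f.n_genes
        log.info("filter %s: kept %d / %d genes", geno, f.n_genes, m.n_genes)
    manifest.add_stage("filter", out_dir, outputs, counts)

    # -- cluster -----------------------------------------------------------
    cluster_cfg = parsed["cluster"]
    outputs = []
    counts = {}
    for geno, f in filtered.items():
        profiles = log2_profiles(f, pseudocount=cluster_cfg["pseudocount"])
        k = min(cluster_cfg["k"], len(profiles))
        assignment = kmeans_profiles(profiles, k=k, seed=seed,
                                     n_init=cluster_cfg["n_init"])
        labels = pd.DataFrame(sorted(assignment.labels.items()),
                              columns=["gene_id", "group"])
        p = out_dir / f"cluster_labels_{_safe(geno)}.tsv"
        labels.to_csv(p, sep="\t", index=False)
        outputs.append(p)
        centroids = pd.DataFrame(assignment.centroids,
                                 index=range(1, k + 1),
                                 columns=[f"DAF{s}" for s in f.axis.stages])
        centroids.index.name = "group"
        p = out_dir / f"cluster_centroids_{_safe(geno)}.tsv"
        centroids.to_csv(p, sep="\t")
        outputs.append(p)
        counts[f"k_{_safe(geno)}"] = k
    corr = stage_correlation_matrix(list(filtered.values()))
    p = out_dir / "stage_correlation.tsv"
    corr.to_frame().to_csv(p, sep="\t")
    outputs.append(p)
    manifest.add_stage("cluster", out_dir, outputs, counts)

    # -- screen ------------------------------------------------------------
    outputs = []
    counts = {}
    records_by_pathway: dict[str, list[CorrelationRecord]] = {}
    for pathway in sorted(sim.catalog.pathways):
        records: list[CorrelationRecord] = []
        for geno, f in sim.matrices.items():
            records.extend(screen_pathway(f, sim.catalog, pathway, screen_cfg))
        records_by_pathway[pathway] = records
        p = out_dir / f"screen_pairs_{pathway}.tsv"
        records_to_frame(records).to_csv(p, sep="\t", index=False)
        outputs.append(p)
        rows = summarize_tf(records, sim.catalog)
        p = out_dir / f"screen_summary_{pathway}.tsv"
        write_tf_summary(rows, p)
        outputs.append(p)
        rule = parsed["selection"].get(pathway,
                                       {"min_count": 1, "require_both": True})
        candidates = select_candidates(rows, rule["min_count"],
                                       rule["require_both"])
        p = out_dir / f"candidates_{pathway}.tsv"
        write_tf_summary(candidates, p)
        outputs.append(p)
        n_sig = sum(r.significant for r in records)
        counts[f"{pathway}_pairs_tested"] = sum(
            r.excluded_reason is None for r in records)
        counts[f"{pathway}_pairs_significant"] = n_sig
        counts[f"{pathway}_candidates"] = len(candidates)
        log.info("screen %s: %d significant pairs, %d candidate TFs",
                 pathway, n_sig, len(candidates))
    manifest.add_stage("screen", out_dir, outputs, counts)

    # -- metabolite correlation -------------------------------------------
    outputs = []
    counts = {}
    all_reports = []
    met_records: list[CorrelationRecord] = []
    for met in sim.metabolites:
        pathway = next((pw for pw, mets in
                        _pathway_of_metabolite(sim).items()
                        if met.metabolite_id in mets), None)
        if pathway is None:
            continue
        gene_ids = sim.catalog.pathway_genes(pathway) + list(sim.catalog.tf_ids)
        met_records.extend(metabolite_gene_correlation(
            met, sim.matrices[met.genotype_id], gene_ids, screen_cfg,
            pathway=pathway))
    p = out_dir / "metabolite_pairs.tsv"
    records_to_frame(met_records).to_csv(p, sep="\t", index=False)
    outputs.append(p)
    for pathway in sorted(sim.catalog.pathways):
        recs = [r for r in met_records if r.pathway == pathway]
        if not recs:
            continue
        report = pathway_metabolite_report(recs, sim.catalog, pathway)
        report.insert(0, "pathway", pathway)
        all_reports.append(report)
    report = pd.concat(all_reports, ignore_index=True)
    p = out_dir / "metabolite_report.tsv"
    report.to_csv(p, sep="\t", index=False)
    outputs.append(p)
    counts["metabolite_pairs"] = len(met_records)
    manifest.add_stage("metab_corr", out_dir, outputs, counts)


def _pathway_of_metabolite(sim) -> dict[str, tuple[str, ...]]:
    from .synthetic_data import PATHWAY_METABOLITES
    return {pw: PATHWAY_METABOLITES.get(pw, (f"{pw}-product",))
            for pw in sim.catalog.pathways}


def _safe(name: str) -> str:
    return name.replace("/", "-").replace(" ", "_")
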