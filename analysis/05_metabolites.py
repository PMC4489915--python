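#!/usr/bin/env python
"""Metabolite-transcript correlation.

Correlates each metabolite's stage course with its pathway's structural
genes and with all TFs, per genotype, under the same significance rule
as the TF screen, and summarises significant fractions by gene class.
"""

from pathlib import Path

import pandas as pd

from stagescreen.data_model import ScreenConfig, read_catalog_manifest, \
    read_expression_matrix, read_metabolite_table
from stagescreen.metabolite_association import (
    metabolite_gene_correlation,
    pathway_metabolite_report,
)
from stagescreen.pipeline import records_to_frame
from stagescreen.synthetic_data import PATHWAY_METABOLITES

BASE = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    catalog = read_catalog_manifest(BASE / "data" / "catalog" / "manifest.json")
    matrices = {g: read_expression_matrix(BASE / "data" / f"expression_{g}.tsv", g)
                for g in ("AC", "HG6-61")}
    cfg = ScreenConfig()
    met_of_pathway = {m: pw for pw, mets in PATHWAY_METABOLITES.items()
                      for m in mets}
    records = []
    for met in read_metabolite_table(BASE / "data" / "metabolites.tsv"):
        pathway = met_of_pathway.get(met.metabolite_id)
        if pathway is None or met.genotype_id not in matrices:
            continue
        gene_ids = catalog.pathway_genes(pathway) + list(catalog.tf_ids)
        records.extend(metabolite_gene_correlation(
            met, matrices[met.genotype_id], gene_ids, cfg, pathway=pathway))
    records_to_frame(records).to_csv(BASE / "metabolite_pairs.tsv",
                                     sep="\t", index=False)
    reports = []
    for pathway in sorted(catalog.pathways):
        recs = [r for r in records if r.pathway == pathway]
        rep = pathway_metabolite_report(recs, catalog, pathway)
        rep.insert(0, "pathway", pathway)
        reports.append(rep)
    report = pd.concat(reports, ignore_index=True)
    report.round(1).to_csv(BASE / "metabolite_report.tsv", sep="\t", index=False)
    for pathway in sorted(catalog.pathways):
        sub = report[report["pathway"] == pathway]
        sg = sub[sub["gene_class"] == "structural"]["pct_significant"].mean()
        tf = sub[sub["gene_class"] == "tf"]["pct_significant"].mean()
        print(f"{pathway}: mean significant fraction — structural genes "
              f"{sg:.1f}%, TFs {tf:.1f}%")


if __name__ == "__main__":
    main()
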