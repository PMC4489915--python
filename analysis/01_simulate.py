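#!/usr/bin/env python
"""Generate the synthetic two-genotype fruit development experiment.

Produces the default study-scale dataset — two genotypes (an early- and
a late-maturing cultivar) sampled weekly at 7..49 days after flowering,
~25,900 genes (823 TFs, 46/18/14 pathway structural genes, 25,000
background genes) on 20 temporal archetypes, 50 planted TF->target
links, and metabolites accumulating as noisy integrals of pathway
expression — and writes it under results/data/.
"""

import json
from pathlib import Path

from stagescreen.data_model import write_expression_matrix, write_metabolite_table
from stagescreen.synthetic_data import SimConfig, simulate_experiment

OUT = Path(__file__).resolve().parents[1] / "results" / "data"
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = SimConfig(seed=SEED)
    sim = simulate_experiment(cfg)
    for geno, m in sim.matrices.items():
        p = OUT / f"expression_{geno.replace('/', '-')}.tsv"
        write_expression_matrix(m, p)
        print(f"{geno}: {m.n_genes} genes x {len(m.axis)} stages -> {p.name}")
    write_metabolite_table(sim.metabolites, OUT / "metabolites.tsv")
    cat_dir = OUT / "catalog"
    cat_dir.mkdir(exist_ok=True)
    manifest = {"pathways": {}, "tf_list": "tfs.txt",
                "tf_family": sim.catalog.tf_family}
    for name, genes in sim.catalog.pathways.items():
        (cat_dir / f"{name}.txt").write_text("\n".join(genes) + "\n")
        manifest["pathways"][name] = f"{name}.txt"
    (cat_dir / "tfs.txt").write_text("\n".join(sim.catalog.tf_ids) + "\n")
    (cat_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    (OUT / "truth.json").write_text(json.dumps({
        "seed": cfg.seed, "noise_sd": cfg.noise_sd,
        "links": [{"tf_id": l.tf_id, "target_id": l.target_id,
                   "sign": l.sign, "effect_size": l.effect_size}
                  for l in sim.truth.links]}, indent=2))
    print(f"{len(sim.truth.links)} planted links recorded in truth.json; "
          f"{len(sim.metabolites)} metabolite series written")


if __name__ == "__main__":
    main()
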