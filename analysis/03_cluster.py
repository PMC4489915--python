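#!/usr/bin/env python
"""Temporal pattern groups and the all-samples stage correlation.

Clusters each genotype's filtered log2(RPKM + 1) profiles into 20
pattern groups (K-means, best of 10 restarts with Hartigan polish) and
computes the 14 x 14 Pearson correlation among all genotype x stage
samples, which in an early- vs late-maturing pair declines toward
ripening.
"""

from pathlib import Path

import pandas as pd

from stagescreen.data_model import read_expression_matrix
from stagescreen.temporal_clustering import (
    kmeans_profiles,
    log2_profiles,
    stage_correlation_matrix,
)

BASE = Path(__file__).resolve().parents[1] / "results"
K = 20
SEED = 1


def main() -> None:
    matrices = []
    for geno in ("AC", "HG6-61"):
        m = read_expression_matrix(BASE / f"filtered_{geno}.tsv", geno)
        matrices.append(m)
        profiles = log2_profiles(m, pseudocount=1.0)
        res = kmeans_profiles(profiles, k=K, seed=SEED, n_init=10)
        labels = pd.DataFrame(sorted(res.labels.items()),
                              columns=["gene_id", "group"])
        labels.to_csv(BASE / f"cluster_labels_{geno}.tsv", sep="\t", index=False)
        cent = pd.DataFrame(res.centroids, index=range(1, K + 1),
                            columns=[f"DAF{s}" for s in m.axis.stages])
        cent.index.name = "group"
        cent.to_csv(BASE / f"cluster_centroids_{geno}.tsv", sep="\t")
        sizes = res.group_sizes()
        print(f"{geno}: k={K}, SSE={res.sse:.0f}, largest groups "
              f"{[sizes[g] for g in range(1, 4)]}")
    corr = stage_correlation_matrix(matrices)
    corr.to_frame().round(4).to_csv(BASE / "stage_correlation.tsv", sep="\t")
    between = [corr.to_frame().loc[f"AC:DAF{s}", f"HG6-61:DAF{s}"]
               for s in matrices[0].axis.stages]
    print("between-genotype same-stage correlation:",
          " ".join(f"{v:.3f}" for v in between))


if __name__ == "__main__":
    main()
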