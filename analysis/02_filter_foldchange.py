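#!/usr/bin/env python
"""Expression floor and stage-over-stage fold-change tables.

Applies the RPKM >= 5 in-at-least-one-stage filter to each genotype and
writes the fold-change tables in the published cell conventions
(numeric ratio, "-" for never-detected, "value/0" for switch-on, "0"
for switch-off), both stage-over-previous-stage and relative to the
7 DAF baseline.
"""

from pathlib import Path

from stagescreen.data_model import ScreenConfig, read_expression_matrix, \
    write_expression_matrix
from stagescreen.quantification import expression_filter, fold_change_table, \
    write_fold_change_table

BASE = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cfg = ScreenConfig()
    for geno in ("AC", "HG6-61"):
        m = read_expression_matrix(BASE / "data" / f"expression_{geno}.tsv", geno)
        kept = expression_filter(m, cfg)
        write_expression_matrix(kept, BASE / f"filtered_{geno}.tsv")
        print(f"{geno}: {kept.n_genes}/{m.n_genes} genes at RPKM >= "
              f"{cfg.min_rpkm} in >= {cfg.min_stages_expressed} stage(s)")
        for mode in ("consecutive", "vs_first"):
            records = fold_change_table(kept, mode=mode)
            p = BASE / f"fold_change_{mode}_{geno}.tsv"
            write_fold_change_table(records, p)
        print(f"  fold-change tables written "
              f"({kept.n_genes * (len(kept.axis) - 1)} records per mode)")


if __name__ == "__main__":
    main()
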