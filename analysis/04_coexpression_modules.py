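#!/usr/bin/env python
"""Co-expression modules and treatment-correlated module selection.

Builds the soft-threshold (beta = 6, unsigned) adjacency, computes
topological overlap, cuts the average-linkage tree into modules
(minimum size 30), summarizes each module by its eigengene (PC1), and
keeps modules whose eigengene correlates with treatment (|r| > 0.5,
p < 0.05).  DEGs inside selected modules become M_DEGs.
Writes results/modules/.
"""

from pathlib import Path

import pandas as pd

from degfunnel.coexpression import (
    adjacency,
    correlation_matrix,
    detect_modules,
    module_refine_degs,
    module_trait_analysis,
    tom_dissimilarity,
)
from degfunnel.config import PipelineConfig
from degfunnel.io_formats import read_expression, read_sample_sheet, write_gene_list

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cfg = PipelineConfig()
    samples = read_sample_sheet(ROOT / "dataset" / "samples.tsv")
    em = read_expression(ROOT / "expression" / "expression.tsv", samples)
    deg_table = pd.read_csv(ROOT / "deg" / "deg_table.tsv", sep="\t", index_col=0)
    degs = set(deg_table.index[deg_table["is_deg"]])

    corr = correlation_matrix(em.values)
    diss = tom_dissimilarity(adjacency(corr, power=cfg.power, sign=cfg.network_sign))
    labels = detect_modules(diss, min_module_size=cfg.min_module_size,
                            cut_height=cfg.cut_height)
    trait = samples.trait_codes(cfg.trait_code_map).to_numpy()
    ms = module_trait_analysis(em, labels, trait,
                               r_min=cfg.module_r_min, alpha=cfg.module_alpha)
    m_degs = module_refine_degs(degs, ms)

    out = ROOT / "modules"
    out.mkdir(parents=True, exist_ok=True)
    assignments = ms.labels.to_frame()
    assignments.index.name = "gene"
    assignments.to_csv(out / "module_assignments.tsv", sep="\t")
    mt = ms.trait_table.copy()
    for c in ("var_explained", "r", "p"):
        mt[c] = mt[c].map(lambda v: "%.6g" % v)
    mt.to_csv(out / "module_trait.tsv", sep="\t", index=False)
    write_gene_list(m_degs, out / "m_degs.txt")

    n_sel = int(ms.trait_table["selected"].sum())
    pos = int((ms.trait_table["selected"] & (ms.trait_table["r"] > 0)).sum())
    print(f"{len(ms.trait_table)} modules detected "
          f"(grey/unassigned: {(ms.labels == 0).sum()} genes)")
    print(f"{n_sel} treatment-correlated modules "
          f"({pos} positive, {n_sel - pos} negative) at |r| > {cfg.module_r_min}, "
          f"p < {cfg.module_alpha}")
    print(f"{len(degs)} DEGs -> {len(m_degs)} M_DEGs inside selected modules")


if __name__ == "__main__":
    main()
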