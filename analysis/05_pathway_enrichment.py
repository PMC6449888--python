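#!/usr/bin/env python
"""Gene-set enrichment of M_DEGs and pathway-activity filtering.

Runs the hypergeometric over-representation test of the M_DEGs against
the expressed-gene background (set size < 100, enrichment p < 0.1,
unadjusted by design), summarizes each enriched set's expression activity
by its PC1 eigengene, and keeps sets whose activity correlates with
treatment (|r| > 0.7, p < 0.01).  M_DEGs inside the selected pathways are
the final GO_DEG biomarker panel.  Writes results/enrichment/.
"""

from pathlib import Path

from degfunnel.config import PipelineConfig
from degfunnel.enrichment import enrich
from degfunnel.funnel import extract_go_degs, pathway_activity
from degfunnel.io_formats import (
    read_expression,
    read_gene_list,
    read_gmt,
    read_sample_sheet,
    write_gene_list,
)

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cfg = PipelineConfig()
    samples = read_sample_sheet(ROOT / "dataset" / "samples.tsv")
    em = read_expression(ROOT / "expression" / "expression.tsv", samples)
    sets = read_gmt(ROOT / "dataset" / "gene_sets.gmt")
    m_degs = read_gene_list(ROOT / "modules" / "m_degs.txt")
    background = set(em.genes)

    table = enrich(m_degs, background, sets,
                   max_size=cfg.set_max_size, p_max=cfg.set_p_max)
    trait = samples.trait_codes(cfg.trait_code_map).to_numpy()
    activity = pathway_activity(em, table, sets, trait,
                                r_min=cfg.pathway_r_min, alpha=cfg.pathway_alpha)
    go_degs = extract_go_degs(m_degs, activity, sets)

    out = ROOT / "enrichment"
    out.mkdir(parents=True, exist_ok=True)
    exp = table.copy()
    exp["p"] = exp["p"].map(lambda v: "%.6g" % v)
    exp.to_csv(out / "enrichment.tsv", sep="\t", index=False)
    act = activity.copy()
    for c in ("r", "p"):
        act[c] = act[c].map(lambda v: "%.6g" % v)
    act.to_csv(out / "pathway_trait.tsv", sep="\t", index=False)
    write_gene_list(go_degs, out / "go_degs.txt")

    print(f"{len(table)} enriched sets (size < {cfg.set_max_size}, "
          f"p < {cfg.set_p_max}) from {len(m_degs)} M_DEGs "
          f"over {len(background)} background genes")
    print(f"{int(activity['selected'].sum())} treatment-correlated pathways "
          f"at |r| > {cfg.pathway_r_min}, p < {cfg.pathway_alpha}")
    print(f"final GO_DEG biomarker panel: {len(go_degs)} genes "
          f"-> {out / 'go_degs.txt'}")


if __name__ == "__main__":
    main()
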