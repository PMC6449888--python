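#!/usr/bin/env python
"""End-to-end funnel run, recovery check, QC and clinical summary.

Re-runs the whole funnel in one call (verifying it matches the staged
scripts), scores the GO_DEG panel's ability to separate 0W from 12W
samples by unsupervised clustering, checks recovery against the planted
truth, and recomputes the PASI response metrics from the clinical table.
Writes results/funnel/.
"""

import json
from pathlib import Path

import pandas as pd

from degfunnel.config import PipelineConfig
from degfunnel.funnel import cluster_samples, pasi_metrics, run_funnel, sample_qc
from degfunnel.io_formats import (
    read_clinical,
    read_gene_list,
    read_gmt,
    read_probe_matrix,
    read_sample_sheet,
)

REPO = Path(__file__).resolve().parents[1]
ROOT = REPO / "results"


def main() -> None:
    pm = read_probe_matrix(ROOT / "dataset" / "probes.tsv")
    samples = read_sample_sheet(ROOT / "dataset" / "samples.tsv")
    sets = read_gmt(ROOT / "dataset" / "gene_sets.gmt")
    result = run_funnel(pm, samples, sets, PipelineConfig(), outdir=ROOT / "funnel")
    s = result.summary()
    print("funnel:", " -> ".join(
        f"{s[k]} {lbl}" for k, lbl in [
            ("n_expressed_genes", "expressed"), ("n_deg", "DEG"),
            ("n_m_deg", "M_DEG"), ("n_go_deg", "GO_DEG")]))

    staged = read_gene_list(ROOT / "enrichment" / "go_degs.txt")
    print("matches staged scripts:", staged == result.go_degs)

    truth = pd.read_csv(ROOT / "dataset" / "truth_genes.tsv", sep="\t", index_col=0)
    responsive = set(truth.index[truth["responsive"] == 1])
    if result.go_degs:
        inside = len(result.go_degs & responsive)
        print(f"GO_DEGs planted-responsive: {inside}/{len(result.go_degs)}")
        _, sep = cluster_samples(result.expression, result.go_degs)
        print(f"0W/12W separation score on GO_DEGs: {sep:.3f}")

    qc = sample_qc(result.expression)
    print(f"PCA QC: variance explained {qc.attrs['variance_explained'][0]:.1%} (PC1), "
          f"{int(qc['outlier'].sum())} outlier samples flagged")

    clin = pasi_metrics(read_clinical(REPO / "data" / "clinical_pasi.tsv"))
    clin.to_csv(ROOT / "funnel" / "clinical_pasi_metrics.tsv", sep="\t")
    print("PASI % decrease:", ", ".join(
        f"{p}={v}" for p, v in zip(clin.index, clin["percent_decrease"])))
    print(f"PASI75 responders: {int(clin['pasi75'].sum())}/{len(clin)}")


if __name__ == "__main__":
    main()
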