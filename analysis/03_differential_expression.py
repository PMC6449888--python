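#!/usr/bin/env python
"""Paired moderated-t differential expression between 0W and 12W.

Fits per-gene within-patient differences, shrinks variances with the
empirical-Bayes prior, adjusts with Benjamini-Hochberg, and calls DEGs at
adjusted p < 0.05 with >= 1.55-fold change.  Writes results/deg/.
"""

from pathlib import Path

from degfunnel.diffexpr import differential_expression
from degfunnel.io_formats import read_expression, read_sample_sheet

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    samples = read_sample_sheet(ROOT / "dataset" / "samples.tsv")
    em = read_expression(ROOT / "expression" / "expression.tsv", samples)
    table = differential_expression(em, alpha=0.05, fc=1.55)
    out = ROOT / "deg"
    out.mkdir(parents=True, exist_ok=True)
    export = table[["logFC", "s2", "t", "p", "q", "is_deg", "direction"]].copy()
    for c in ("logFC", "s2", "t", "p", "q"):
        export[c] = export[c].map(lambda v: "%.6g" % v)
    export.to_csv(out / "deg_table.tsv", sep="\t")
    print(f"moderated-t prior: d0 = {table.attrs['prior_d0']:.2f}, "
          f"s2_0 = {table.attrs['prior_s2_0']:.4f}")
    print(f"{table.attrs['n_deg']} DEGs "
          f"({table.attrs['n_up']} up, {table.attrs['n_down']} down) "
          f"of {len(table)} genes at adj-p < 0.05, fold-change >= 1.55")
    print(f"table written to {out / 'deg_table.tsv'}")


if __name__ == "__main__":
    main()
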