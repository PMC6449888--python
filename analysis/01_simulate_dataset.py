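#!/usr/bin/env python
"""Generate the synthetic paired-expression study used by all later steps.

Writes a self-contained dataset directory (probe-level TSV with negative
controls and detection p-values, gene-level log2 matrix, sample sheet, GMT
gene sets, ground-truth tables) under results/dataset/.
"""

from pathlib import Path

from degfunnel.config import SimulationConfig
from degfunnel.simulate import write_dataset

OUT = Path(__file__).resolve().parents[1] / "results" / "dataset"
SEED = 1


def main() -> None:
    config = SimulationConfig(seed=SEED)
    write_dataset(config, OUT)
    print(f"dataset written to {OUT}")
    print(f"  {config.n_genes} genes x {2 * config.n_patients} samples "
          f"({config.n_patients} patients, 0W/12W)")
    print(f"  {config.n_modules} planted modules of {config.module_size} genes; "
          f"{config.n_responsive_modules} responsive (effect "
          f"{config.treatment_effect} log2 units)")
    print(f"  {config.n_gene_sets} gene sets "
          f"({config.fraction_true_sets:.0%} built over responsive genes)")


if __name__ == "__main__":
    main()
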