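import numpy as np
import pandas as pd
import pytest

from degfunnel.config import SimulationConfig
from degfunnel.io_formats import ExpressionMatrix, SampleSheet
from degfunnel.simulate import simulate_dataset, simulate_expression


def make_sheet(n_patients: int) -> SampleSheet:
    rows = []
    for i in range(1, n_patients + 1):
        for tp in ("0W", "12W"):
            rows.append({"sample_id": f"P{i}_{tp}", "patient_id": f"P{i}", "timepoint": tp})
    return SampleSheet(pd.DataFrame(rows))


def make_expression(values: np.ndarray, n_patients: int, genes=None) -> ExpressionMatrix:
    sheet = make_sheet(n_patients)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    df = pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=sheet.sample_ids)
    return ExpressionMatrix(df, sheet)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(
        n_genes=400, n_modules=4, module_size=50, n_responsive_modules=2,
        n_patients=6, n_gene_sets=20, gene_set_size_range=(5, 30),
        n_negative_controls=50, seed=7,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    """Probe matrix, gene matrix, samples, gene sets and truth (400 genes)."""
    return simulate_dataset(small_config)


@pytest.fixture(scope="session")
def small_expression(small_config):
    em, truth = simulate_expression(small_config)
    return em, truth
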