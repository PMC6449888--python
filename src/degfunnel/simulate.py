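"""Synthetic paired microarray world with planted structure.

The gene-level model on the log2 scale, for gene g, patient i, timepoint t:

    x(g, i, t) = baseline_g + patient_i + loading · φ_{m(g), i}
                 + Δ_g · 1[t = 12W] + ε_{g,i,t}

where φ_{m,i} ~ N(0, 1) is a latent factor drawn once per (module,
patient) and shared by that patient's two samples — it induces
co-expression within modules while cancelling out of the paired 12W − 0W
differences, mirroring real paired designs where between-patient
variation dominates the global expression pattern.  Δ_g equals
``treatment_effect`` for every gene of the responsive modules and 0
elsewhere, so true differential-expression status is unambiguous.

The probe layer expands each gene into ``probes_per_gene`` probes
(fixed per-probe offsets plus probe noise), adds an additive array
background equal to the per-sample mean of the simulated negative
controls, and computes detection p-values as the empirical exceedance
against the negative controls.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .io_formats import (
    ExpressionMatrix,
    GeneSetCollection,
    ProbeMatrix,
    SampleSheet,
    write_expression,
    write_gmt,
    write_probe_matrix,
    write_sample_sheet,
)


@dataclass
class SimulationTruth:
    """Ground truth of the planted world, for recovery testing."""

    gene_module: pd.Series                  # gene -> module label (0 = background)
    responsive_modules: list[int]
    responsive_genes: set[str]
    true_logfc: pd.Series                   # gene -> planted log2 effect
    true_sets: list[str] = field(default_factory=list)
    decoy_sets: list[str] = field(default_factory=list)

    def validate(self, sets: GeneSetCollection | None = None) -> None:
        module_genes = set(
            self.gene_module.index[self.gene_module.isin(self.responsive_modules)]
        )
        if not self.responsive_genes <= module_genes:
            raise ValueError("responsive genes must lie inside the responsive modules")
        if sets is not None:
            for sid in self.true_sets:
                if not (sets[sid] & self.responsive_genes):
                    raise ValueError(f"true set {sid!r} does not overlap responsive genes")


def _sample_sheet(n_patients: int) -> SampleSheet:
    rows = []
    for i in range(1, n_patients + 1):
        for tp in ("0W", "12W"):
            rows.append({"sample_id": f"P{i}_{tp}", "patient_id": f"P{i}", "timepoint": tp})
    return SampleSheet(pd.DataFrame(rows))


def simulate_expression(config: SimulationConfig) -> tuple[ExpressionMatrix, SimulationTruth]:
    """Gene-level log2 matrix over 2·n_patients samples, plus ground truth."""
    rng = np.random.default_rng(config.seed)
    n_genes, n_pat = config.n_genes, config.n_patients
    genes = [f"G{i:05d}" for i in range(1, n_genes + 1)]
    samples = _sample_sheet(n_pat)

    labels = np.zeros(n_genes, dtype=int)
    for m in range(config.n_modules):
        labels[m * config.module_size : (m + 1) * config.module_size] = m + 1
    responsive_modules = list(range(1, config.n_responsive_modules + 1))
    responsive_mask = np.isin(labels, responsive_modules)
    delta = np.where(responsive_mask, config.treatment_effect, 0.0)
    if config.treatment_effect == 0:
        responsive_mask = np.zeros(n_genes, dtype=bool)

    baseline = rng.uniform(*config.baseline_range, size=n_genes)
    patient_effect = rng.normal(0.0, config.patient_effect_sd, size=n_pat)
    factors = rng.normal(0.0, 1.0, size=(config.n_modules, n_pat))

    X = np.empty((n_genes, 2 * n_pat))
    col = 0
    for i in range(n_pat):
        factor_term = np.where(
            labels > 0, config.module_loading * factors[np.maximum(labels, 1) - 1, i], 0.0
        )
        base = baseline + patient_effect[i] + factor_term
        for t, is_12w in (("0W", 0.0), ("12W", 1.0)):
            noise = rng.normal(0.0, config.noise_sd, size=n_genes)
            X[:, col] = base + delta * is_12w + noise
            col += 1

    values = pd.DataFrame(X, index=pd.Index(genes, name="gene"), columns=samples.sample_ids)
    em = ExpressionMatrix(values, samples, provenance=[{"step": "simulate", "seed": config.seed}])
    truth = SimulationTruth(
        gene_module=pd.Series(labels, index=values.index, name="module"),
        responsive_modules=responsive_modules if config.treatment_effect != 0 else [],
        responsive_genes=set(np.array(genes)[responsive_mask]),
        true_logfc=pd.Series(np.where(responsive_mask, delta, 0.0), index=values.index, name="true_logFC"),
    )
    return em, truth


def simulate_probe_level(em: ExpressionMatrix, config: SimulationConfig) -> ProbeMatrix:
    """Expand genes to probes on the intensity scale with negative controls.

    Probe log2 signal = gene value + per-probe offset + probe noise; the
    intensity adds an array background equal to the per-sample mean of the
    negative-control intensities, so background subtraction removes it
    exactly.  Detection p = fraction of that sample's negative controls
    exceeding the probe intensity.
    """
    if config.probes_per_gene < 1:
        raise ValueError("probes_per_gene must be >= 1")
    if config.n_negative_controls < 1:
        raise ValueError("n_negative_controls must be >= 1")
    # independent stream so the gene-level matrix is reproducible on its own
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 104729]))
    genes = em.values.index.to_numpy()
    n_genes, n_samples = em.values.shape
    ppg = config.probes_per_gene

    nc_ids = [f"NC{i:04d}" for i in range(1, config.n_negative_controls + 1)]
    nc_log2 = rng.normal(
        config.background_log2_mean, config.background_log2_sd,
        size=(config.n_negative_controls, n_samples),
    )
    nc_intensity = 2.0**nc_log2
    background = nc_intensity.mean(axis=0)  # per sample

    offsets = rng.normal(0.0, config.probe_offset_sd, size=(n_genes, ppg))
    probe_ids, symbols = [], []
    signal = np.empty((n_genes * ppg, n_samples))
    expr = em.values.to_numpy()
    for j in range(ppg):
        noise = rng.normal(0.0, config.probe_noise_sd, size=(n_genes, n_samples))
        # slice j::ppg holds gene g's probe j at row g*ppg + j (gene-major blocks)
        signal[j::ppg] = 2.0 ** (expr + offsets[:, [j]] + noise)
    for gene in genes:
        for j in range(ppg):
            probe_ids.append(f"{gene}_p{j + 1}")
            symbols.append(gene)

    intensity = signal + background[None, :]
    all_ids = probe_ids + nc_ids
    all_intensity = np.vstack([intensity, nc_intensity])
    # empirical exceedance: fraction of negative controls strictly above the probe
    detection = (
        (nc_intensity[None, :, :] > all_intensity[:, None, :]).mean(axis=1)
    )
    idx = pd.Index(all_ids, name="ProbeID")
    return ProbeMatrix(
        gene_symbol=pd.Series(symbols + [""] * len(nc_ids), index=idx),
        is_negative_control=pd.Series(
            [False] * len(probe_ids) + [True] * len(nc_ids), index=idx
        ),
        intensity=pd.DataFrame(all_intensity, index=idx, columns=em.values.columns),
        detection_p=pd.DataFrame(detection, index=idx, columns=em.values.columns),
    )


def simulate_gene_sets(
    truth: SimulationTruth, config: SimulationConfig
) -> tuple[GeneSetCollection, SimulationTruth]:
    """GMT-style collection: true sets overlap responsive genes, decoys don't.

    True sets draw a ``true_set_overlap`` fraction of members from the
    responsive genes; decoys are sampled uniformly from non-responsive
    genes.  When there are no responsive genes every set is a decoy.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 224737]))
    genes = np.array(truth.gene_module.index)
    responsive = np.array(sorted(truth.responsive_genes))
    nonresponsive = np.array(sorted(set(genes) - truth.responsive_genes))
    lo, hi = config.gene_set_size_range
    n_true = int(round(config.fraction_true_sets * config.n_gene_sets)) if len(responsive) else 0

    sets: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    true_ids, decoy_ids = [], []
    for s in range(1, config.n_gene_sets + 1):
        sid = f"GS{s:04d}"
        size = int(rng.integers(lo, hi + 1))
        if s <= n_true:
            n_resp = max(1, int(round(config.true_set_overlap * size)))
            n_resp = min(n_resp, len(responsive), size)
            picked = list(rng.choice(responsive, size=n_resp, replace=False))
            n_rest = min(size - n_resp, len(nonresponsive))
            if n_rest > 0:
                picked += list(rng.choice(nonresponsive, size=n_rest, replace=False))
            true_ids.append(sid)
            names[sid] = "planted_responsive_set"
        else:
            size = min(size, len(nonresponsive))
            picked = list(rng.choice(nonresponsive, size=size, replace=False))
            decoy_ids.append(sid)
            names[sid] = "decoy_set"
        sets[sid] = set(picked)
    collection = GeneSetCollection(sets, names)
    truth.true_sets = true_ids
    truth.decoy_sets = decoy_ids
    truth.validate(collection)
    return collection, truth


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[ProbeMatrix, ExpressionMatrix, SampleSheet, GeneSetCollection, SimulationTruth]:
    """The full synthetic study: probe matrix, gene matrix, metadata, sets."""
    em, truth = simulate_expression(config)
    pm = simulate_probe_level(em, config)
    collection, truth = simulate_gene_sets(truth, config)
    return pm, em, em.samples, collection, truth


def write_truth(truth: SimulationTruth, outdir: str | Path) -> None:
    outdir = Path(outdir)
    gene_table = pd.DataFrame({
        "module": truth.gene_module,
        "responsive": [int(g in truth.responsive_genes) for g in truth.gene_module.index],
        "true_logFC": truth.true_logfc,
    })
    gene_table.index.name = "gene"
    gene_table.to_csv(outdir / "truth_genes.tsv", sep="\t")
    set_table = pd.DataFrame({
        "set_id": truth.true_sets + truth.decoy_sets,
        "is_true": [1] * len(truth.true_sets) + [0] * len(truth.decoy_sets),
    })
    set_table.to_csv(outdir / "truth_sets.tsv", sep="\t", index=False)


def write_dataset(config: SimulationConfig, outdir: str | Path) -> None:
    """Emit a self-contained dataset directory (probe TSV, expression TSV,
    sample sheet, GMT, truth tables, config echo)."""
    import yaml

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pm, em, samples, collection, truth = simulate_dataset(config)
    write_probe_matrix(pm, outdir / "probes.tsv")
    write_expression(em, outdir / "expression.tsv")
    write_sample_sheet(samples, outdir / "samples.tsv")
    write_gmt(collection, outdir / "gene_sets.gmt")
    write_truth(truth, outdir)
    with open(outdir / "sim_config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
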