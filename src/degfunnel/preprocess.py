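"""Probe-level preprocessing: background correction, detection filtering,
quantile normalization, log2 transform, probe→gene median summarization and
the low-expression gene filter.

The pipeline order is fixed and recorded in provenance:
background → detection filter → quantile normalize → log2 → summarize →
low-expression filter.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .io_formats import ExpressionMatrix, ProbeMatrix, SampleSheet


class PreprocessError(ValueError):
    pass


def background_correct(pm: ProbeMatrix) -> ProbeMatrix:
    """Subtract, per sample, the mean negative-control intensity.

    Negative-control rows are retained for reference; corrected values may
    be non-positive (the log2 step floors them later).
    """
    nc = pm.is_negative_control.astype(bool)
    if not nc.any():
        raise PreprocessError("background correction requires >= 1 negative-control probe")
    control_mean = pm.intensity.loc[nc].mean(axis=0)
    corrected = pm.intensity.sub(control_mean, axis=1)
    return pm.with_intensity(corrected, step="background_correct")


def detection_filter(
    pm: ProbeMatrix,
    samples: SampleSheet,
    alpha: float = 0.05,
    rule: str = "all",
) -> ProbeMatrix:
    """Remove probes undetected in BOTH timepoint groups; drop controls.

    A probe fails a group when, under rule ``"all"``, its detection p
    exceeds ``alpha`` in every sample of that group (most conservative
    removal), or under rule ``"mean"`` when its group-mean detection p
    exceeds ``alpha``.  A probe is removed iff it fails both the 0W and the
    12W group.  Negative controls are always removed at this stage.
    """
    g0 = samples.samples_at("0W")
    g1 = samples.samples_at("12W")
    if not g0 or not g1:
        raise PreprocessError("detection filter requires non-empty 0W and 12W groups")

    def fails(group: list[str]) -> pd.Series:
        p = pm.detection_p[group]
        if rule == "all":
            return (p > alpha).all(axis=1)
        if rule == "mean":
            return p.mean(axis=1) > alpha
        raise PreprocessError(f"unknown detection rule {rule!r}")

    undetected = fails(g0) & fails(g1)
    keep = ~undetected & ~pm.is_negative_control.astype(bool)
    return pm.subset_probes(pm.intensity.index[keep], step=f"detection_filter(alpha={alpha},rule={rule})")


def quantile_normalize(pm: ProbeMatrix) -> ProbeMatrix:
    """Map every column onto the cross-sample mean of order statistics.

    After normalization all columns share the identical sorted value
    vector.  Tied values within a column receive the mean of the reference
    quantile values their positions span.
    """
    X = pm.intensity.to_numpy(dtype=float)
    if X.shape[1] < 2:
        raise PreprocessError("quantile normalization requires >= 2 samples")
    reference = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        col = X[:, j]
        order = np.argsort(col, kind="mergesort")
        sorted_col = col[order]
        vals = reference.copy()
        # average reference values over each run of ties
        start = 0
        for i in range(1, len(sorted_col) + 1):
            if i == len(sorted_col) or sorted_col[i] != sorted_col[start]:
                if i - start > 1:
                    vals[start:i] = vals[start:i].mean()
                start = i
        out[order, j] = vals
    norm = pd.DataFrame(out, index=pm.intensity.index, columns=pm.intensity.columns)
    return pm.with_intensity(norm, step="quantile_normalize")


def log2_transform(pm: ProbeMatrix, floor: float = 1.0, offset: float = 0.0) -> ProbeMatrix:
    """log2(max(intensity, floor) + offset); monotone in its input."""
    X = pm.intensity.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        bad = np.argwhere(~np.isfinite(X))[0]
        raise PreprocessError(
            f"non-finite intensity at probe {pm.intensity.index[bad[0]]!r}, "
            f"sample {pm.intensity.columns[bad[1]]!r}"
        )
    arg = np.maximum(X, floor) + offset
    if np.any(arg <= 0):
        raise PreprocessError("log2 argument <= 0; raise floor or offset")
    vals = pd.DataFrame(np.log2(arg), index=pm.intensity.index, columns=pm.intensity.columns)
    return pm.with_intensity(vals, step=f"log2(floor={floor},offset={offset})")


def summarize_to_genes(pm: ProbeMatrix, samples: SampleSheet) -> ExpressionMatrix:
    """Per-sample median over each gene's surviving probes.

    Probes without a gene symbol are dropped.  Permutation-invariant in
    probe order.
    """
    has_symbol = pm.gene_symbol != ""
    vals = pm.intensity.loc[has_symbol]
    symbols = pm.gene_symbol.loc[has_symbol]
    med = vals.groupby(symbols.to_numpy()).median()
    med.index.name = "gene"
    med = med.sort_index()
    em = ExpressionMatrix(med[samples.sample_ids], samples,
                          provenance=[{"step": s} for s in pm.steps])
    em.record("summarize_to_genes", n_genes=med.shape[0])
    return em


def gene_detection_counts(pm: ProbeMatrix, alpha: float = 0.05) -> pd.Series:
    """Per gene: number of samples where any of its probes is detected.

    A gene counts as detected in a sample if any probe mapping to it has
    detection p <= alpha there.  Computed on the probe matrix (typically
    pre-summarization), used by the low-expression filter.
    """
    has_symbol = pm.gene_symbol != ""
    detected = (pm.detection_p.loc[has_symbol] <= alpha)
    per_gene = detected.groupby(pm.gene_symbol.loc[has_symbol].to_numpy()).any()
    return per_gene.sum(axis=1).rename("n_detected_samples")


def low_expression_filter(
    em: ExpressionMatrix,
    detected_counts: pd.Series,
    min_samples: int = 3,
) -> ExpressionMatrix:
    """Keep genes detected in at least ``min_samples`` samples."""
    n_samples = em.values.shape[1]
    if min_samples > n_samples:
        raise PreprocessError(
            f"min_samples={min_samples} exceeds sample count {n_samples}"
        )
    counts = detected_counts.reindex(em.values.index).fillna(0)
    keep = counts[counts >= min_samples].index
    out = em.subset_genes(keep)
    out.record("low_expression_filter", min_samples=min_samples, n_retained=len(keep))
    return out


def preprocess_pipeline(
    pm: ProbeMatrix,
    samples: SampleSheet,
    config: PipelineConfig | None = None,
) -> ExpressionMatrix:
    """Run the full fixed-order preprocessing funnel."""
    config = config or PipelineConfig()
    corrected = background_correct(pm)
    filtered = detection_filter(
        corrected, samples, alpha=config.detection_alpha, rule=config.detection_group_rule
    )
    normalized = quantile_normalize(filtered)
    logged = log2_transform(normalized, floor=config.log2_floor, offset=config.log2_offset)
    em = summarize_to_genes(logged, samples)
    counts = gene_detection_counts(filtered, alpha=config.detection_alpha)
    return low_expression_filter(em, counts, min_samples=config.min_detected_samples)
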