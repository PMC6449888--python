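"""Final funnel stages and end-to-end orchestration.

The biomarker funnel nests four gene sets:

    expressed genes ⊇ DEG ⊇ M_DEG ⊇ GO_DEG

DEGs come from the paired moderated t-test; M_DEGs are DEGs inside
treatment-correlated co-expression modules (|r| > 0.5, p < 0.05); GO_DEGs
are M_DEGs inside enriched gene sets (size < 100, enrichment p < 0.1)
whose pathway activity (first principal component, exactly the module
eigengene procedure) correlates with treatment (|r| > 0.7, p < 0.01).

Also provided: sample QC (PCA, outlier flags), 2-group sample clustering
with a timepoint-separation score, and clinical PASI utilities.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import pdist

from . import __version__
from .config import PipelineConfig
from .coexpression import (
    ModuleSet,
    adjacency,
    correlate_with_trait,
    correlation_matrix,
    detect_modules,
    merge_similar_modules,
    module_eigengene,
    module_refine_degs,
    module_trait_analysis,
    tom_dissimilarity,
)
from .diffexpr import deg_set, differential_expression
from .enrichment import enrich
from .io_formats import (
    ExpressionMatrix,
    GeneSetCollection,
    ProbeMatrix,
    SampleSheet,
    write_expression,
    write_gene_list,
)
from .preprocess import preprocess_pipeline


class FunnelError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


# ---------------------------------------------------------------------------
# Pathway activity


def pathway_activity(
    em: ExpressionMatrix,
    enrichment_table: pd.DataFrame,
    sets: GeneSetCollection,
    trait: np.ndarray,
    r_min: float = 0.7,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Trait correlation of each enriched set's expression eigengene.

    Uses the identical PC1 + Pearson procedure as for modules; sets with
    fewer than 2 expressed genes are recorded as unevaluable and excluded
    from selection.
    """
    universe = set(em.values.index)
    rows = []
    for sid in enrichment_table["set_id"]:
        members = sorted(sets[sid] & universe)
        if len(members) < 2:
            rows.append({"set_id": sid, "n_expressed": len(members),
                         "r": np.nan, "p": np.nan, "selected": False,
                         "evaluable": False})
            continue
        e, _ = module_eigengene(em.values.loc[members])
        r, p = correlate_with_trait(e, trait)
        rows.append({"set_id": sid, "n_expressed": len(members), "r": r, "p": p,
                     "selected": (abs(r) > r_min) and (p < alpha), "evaluable": True})
    return pd.DataFrame(
        rows, columns=["set_id", "n_expressed", "r", "p", "selected", "evaluable"]
    )


def extract_go_degs(
    m_degs: set[str], pathway_table: pd.DataFrame, sets: GeneSetCollection
) -> set[str]:
    """GO_DEG = M_DEG ∩ union of the selected pathways' genes."""
    selected = pathway_table.loc[pathway_table["selected"], "set_id"]
    covered: set[str] = set()
    for sid in selected:
        covered |= sets[sid]
    return m_degs & covered


# ---------------------------------------------------------------------------
# QC and clustering


def _standardize(values: pd.DataFrame) -> np.ndarray:
    X = values.to_numpy(dtype=float)
    sd = X.std(axis=1, ddof=1)
    keep = sd > 0
    X = X[keep]
    return (X - X.mean(axis=1, keepdims=True)) / sd[keep][:, None]


def sample_qc(em: ExpressionMatrix, outlier_factor: float = 3.0) -> pd.DataFrame:
    """PCA sample scores plus centroid-distance outlier flags.

    A sample is flagged when its distance to the score-space centroid
    exceeds ``outlier_factor`` times the median distance.
    """
    if len(em.samples) < 3:
        raise ValueError("sample QC requires >= 3 samples")
    Z = _standardize(em.values)
    # PCA over samples: center sample vectors, SVD
    S = Z.T - Z.T.mean(axis=0, keepdims=True)
    _, svals, vt = np.linalg.svd(S, full_matrices=False)
    n_pc = min(3, vt.shape[0])
    scores = S @ vt[:n_pc].T
    dist = np.linalg.norm(scores - scores.mean(axis=0), axis=1)
    med = np.median(dist)
    out = pd.DataFrame(
        scores, index=em.samples.sample_ids, columns=[f"PC{i+1}" for i in range(n_pc)]
    )
    out["centroid_distance"] = dist
    out["outlier"] = dist > outlier_factor * med if med > 0 else False
    var = svals**2
    out.attrs["variance_explained"] = (var / var.sum())[:n_pc].tolist()
    return out


def cluster_samples(
    em: ExpressionMatrix, genes: set[str] | list[str] | None = None
) -> tuple[np.ndarray, float]:
    """Average-linkage 2-group clustering of samples on standardized genes.

    Returns (group labels in sample order, separation score): the score is
    the best-assignment fraction of samples whose group matches their
    timepoint.
    """
    values = em.values if genes is None else em.values.loc[
        em.values.index.intersection(pd.Index(sorted(set(genes))))
    ]
    if values.shape[0] == 0:
        raise ValueError("gene subset is disjoint from the expression matrix")
    Z = _standardize(values)
    if Z.shape[0] == 0:
        raise ValueError("no non-constant genes in the subset")
    D = pdist(Z.T, metric="euclidean")
    labels = fcluster(average(D), t=2, criterion="maxclust")
    timepoints = np.array(em.samples.table["timepoint"])
    is_12w = (timepoints == "12W").astype(int)
    match_a = float(np.mean((labels - 1) == is_12w))
    score = max(match_a, 1.0 - match_a)
    return labels, score


# ---------------------------------------------------------------------------
# Clinical utilities


def pasi_metrics(clinical: pd.DataFrame, responder_cut: float = 75.0) -> pd.DataFrame:
    """Percent PASI decrease (one decimal, half-up) and PASI75 flags."""
    if (clinical["PASI_0"] <= 0).any():
        bad = clinical.index[clinical["PASI_0"] <= 0].tolist()
        raise ValueError(f"PASI_0 must be positive; offending patients: {bad}")
    out = clinical.copy()
    pct = 100.0 * (out["PASI_0"] - out["PASI_12"]) / out["PASI_0"]
    out["percent_decrease"] = [
        float(Decimal(repr(v)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)) for v in pct
    ]
    out["pasi75"] = out["percent_decrease"] >= responder_cut
    return out


# ---------------------------------------------------------------------------
# Orchestration


@dataclass
class FunnelResult:
    """Everything the funnel computed, with nested-set certificates."""

    expression: ExpressionMatrix
    deg_table: pd.DataFrame
    degs: set[str]
    module_set: ModuleSet
    m_degs: set[str]
    enrichment_table: pd.DataFrame
    pathway_table: pd.DataFrame
    go_degs: set[str]
    config: PipelineConfig
    qc: pd.DataFrame | None = None
    counts: dict = field(default_factory=dict)

    def summary(self) -> dict:
        pos, neg = [], []
        tt = self.module_set.trait_table
        if len(tt):
            pos = tt.loc[tt["selected"] & (tt["r"] > 0), "module"].tolist()
            neg = tt.loc[tt["selected"] & (tt["r"] < 0), "module"].tolist()
        return {
            "n_expressed_genes": int(self.expression.n_genes),
            "n_deg": len(self.degs),
            "n_deg_up": int(self.deg_table.attrs.get("n_up", 0)),
            "n_deg_down": int(self.deg_table.attrs.get("n_down", 0)),
            "n_modules": int((self.module_set.trait_table["module"] > 0).sum()),
            "n_selected_modules": len(pos) + len(neg),
            "n_selected_modules_positive": len(pos),
            "n_selected_modules_negative": len(neg),
            "n_m_deg": len(self.m_degs),
            "n_enriched_sets": int(len(self.enrichment_table)),
            "n_selected_pathways": int(self.pathway_table["selected"].sum()) if len(self.pathway_table) else 0,
            "n_go_deg": len(self.go_degs),
        }

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_expression(self.expression, outdir / "expression.tsv")
        deg_out = self.deg_table.copy()
        num_cols = deg_out.select_dtypes(include=[float]).columns
        deg_out[num_cols] = deg_out[num_cols].map(lambda v: "%.6g" % v)
        deg_out.to_csv(outdir / "deg_table.tsv", sep="\t")
        labels = self.module_set.labels.to_frame()
        labels.index.name = "gene"
        labels.to_csv(outdir / "module_assignments.tsv", sep="\t")
        mt = self.module_set.trait_table.copy()
        for c in ("var_explained", "r", "p"):
            if c in mt:
                mt[c] = mt[c].map(lambda v: "%.6g" % v)
        mt.to_csv(outdir / "module_trait.tsv", sep="\t", index=False)
        write_gene_list(self.m_degs, outdir / "m_degs.txt")
        enr = self.enrichment_table.copy()
        if "p" in enr:
            enr["p"] = enr["p"].map(lambda v: "%.6g" % v)
        enr.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
        pt = self.pathway_table.copy()
        for c in ("r", "p"):
            if c in pt:
                pt[c] = pt[c].map(lambda v: "%.6g" % v if pd.notna(v) else "NA")
        pt.to_csv(outdir / "pathway_trait.tsv", sep="\t", index=False)
        write_gene_list(self.go_degs, outdir / "go_degs.txt")
        with open(outdir / "funnel_summary.json", "w") as fh:
            json.dump(self.summary(), fh, indent=2, sort_keys=True)
            fh.write("\n")
        manifest = {
            "package": "degfunnel",
            "version": __version__,
            "config": self.config.to_dict(),
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")


def run_funnel(
    data: ProbeMatrix | ExpressionMatrix,
    samples: SampleSheet,
    sets: GeneSetCollection,
    config: PipelineConfig | None = None,
    outdir: str | Path | None = None,
    qc: bool = True,
) -> FunnelResult:
    """Execute every funnel stage in order and enforce set nesting."""
    config = config or PipelineConfig()

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            raise FunnelError(name, exc) from exc

    if isinstance(data, ProbeMatrix):
        em = stage("preprocess", preprocess_pipeline, data, samples, config)
    else:
        em = data

    deg_table = stage(
        "diffexpr", differential_expression, em, alpha=config.deg_alpha, fc=config.deg_fc
    )
    degs = deg_set(deg_table)

    def modules_stage():
        corr = correlation_matrix(em.values)
        A = adjacency(corr, power=config.power, sign=config.network_sign)
        diss = tom_dissimilarity(A)
        labels = detect_modules(
            diss,
            min_module_size=config.min_module_size,
            cut_height=config.cut_height,
        )
        if config.merge_modules:
            labels = merge_similar_modules(em, labels, config.merge_threshold)
        trait = samples.trait_codes(config.trait_code_map).to_numpy()
        return module_trait_analysis(
            em, labels, trait, r_min=config.module_r_min, alpha=config.module_alpha
        )

    module_set = stage("coexpression", modules_stage)
    m_degs = stage("module_refine", module_refine_degs, degs, module_set)

    background = set(em.values.index)
    enrichment_table = stage(
        "enrichment", enrich, m_degs, background, sets,
        max_size=config.set_max_size, p_max=config.set_p_max,
    )
    trait = samples.trait_codes(config.trait_code_map).to_numpy()
    pathway_table = stage(
        "pathway_activity", pathway_activity, em, enrichment_table, sets, trait,
        r_min=config.pathway_r_min, alpha=config.pathway_alpha,
    )
    go_degs = stage("go_deg", extract_go_degs, m_degs, pathway_table, sets)

    assert go_degs <= m_degs <= degs <= background, "funnel nesting violated"

    qc_table = stage("qc", sample_qc, em, config.outlier_mad_factor) if qc else None
    result = FunnelResult(
        expression=em,
        deg_table=deg_table,
        degs=degs,
        module_set=module_set,
        m_degs=m_degs,
        enrichment_table=enrichment_table,
        pathway_table=pathway_table,
        go_degs=go_degs,
        config=config,
        qc=qc_table,
    )
    result.counts = result.summary()
    if outdir is not None:
        result.write(outdir)
    return result
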