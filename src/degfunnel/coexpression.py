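"""Weighted co-expression network: soft-threshold adjacency, topological
overlap, module detection by average-linkage clustering, eigengenes, and
module–trait correlation filtering.

Adjacency is |cor|^beta (unsigned) or ((1+cor)/2)^beta (signed); the
topological overlap between genes i and j is

    TOM_ij = (L_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij),
    L_ij = Σ_{u≠i,j} a_iu a_uj,   k_i = Σ_{u≠i} a_iu,

with TOM_ii = 1.  Modules come from a static cut of the average-linkage
tree on 1 − TOM; clusters below the minimum size are left unassigned
(label 0, "grey").  Each module is summarized by its eigengene: the first
principal component of the standardized module expression, unit variance,
sign-oriented toward the module mean profile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform

from .io_formats import ExpressionMatrix


class CoexpressionError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Network construction


def correlation_matrix(values: pd.DataFrame) -> pd.DataFrame:
    """Gene × gene Pearson correlation across samples."""
    X = values.to_numpy(dtype=float)
    sd = X.std(axis=1)
    if np.any(sd == 0):
        bad = values.index[sd == 0].tolist()
        raise CoexpressionError(f"constant-expression genes have no defined correlation: {bad[:5]}")
    corr = np.corrcoef(X)
    if not np.isfinite(corr).all():
        bad = values.index[np.argwhere(~np.isfinite(corr))[0][0]]
        raise CoexpressionError(f"non-finite correlation involving gene {bad!r}")
    return pd.DataFrame(corr, index=values.index, columns=values.index)


def adjacency(corr: pd.DataFrame | np.ndarray, power: float = 6.0, sign: str = "unsigned") -> np.ndarray:
    """Soft-threshold adjacency with zero diagonal."""
    C = np.asarray(corr, dtype=float)
    if sign == "unsigned":
        A = np.abs(C) ** power
    elif sign == "signed":
        A = ((1.0 + C) / 2.0) ** power
    else:
        raise CoexpressionError(f"unknown network sign {sign!r}")
    np.fill_diagonal(A, 0.0)
    return A


def tom_similarity(adj: np.ndarray) -> np.ndarray:
    """Topological overlap matrix; symmetric, unit diagonal, entries in [0,1]."""
    A = np.asarray(adj, dtype=float)
    if A.shape[0] != A.shape[1]:
        raise CoexpressionError("adjacency must be square")
    A = A.copy()
    np.fill_diagonal(A, 0.0)
    k = A.sum(axis=1)
    L = A @ A  # diagonal of A is 0, so u = i, j terms vanish
    denom = np.minimum.outer(k, k) + 1.0 - A
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = (L + A) / denom
    tom = np.nan_to_num(tom, nan=0.0)
    np.fill_diagonal(tom, 1.0)
    return tom


def tom_dissimilarity(adj: np.ndarray) -> np.ndarray:
    return 1.0 - tom_similarity(adj)


def scale_free_fit(connectivity: np.ndarray, n_bins: int = 10) -> float:
    """R² of the log10 frequency vs log10 mean-connectivity regression.

    Returns nan when the connectivity distribution is degenerate (fewer
    than 3 usable bins).
    """
    k = np.asarray(connectivity, dtype=float)
    k = k[k > 0]
    if k.size < 3 or np.ptp(k) == 0:
        return float("nan")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        mask = which == b
        if mask.sum() == 0:
            continue
        mean_k = k[mask].mean()
        freq = mask.mean()
        if mean_k > 0 and freq > 0:
            xs.append(np.log10(mean_k))
            ys.append(np.log10(freq))
    if len(xs) < 3 or np.ptp(xs) == 0:
        return float("nan")
    slope, intercept = np.polyfit(xs, ys, 1)
    resid = np.asarray(ys) - (slope * np.asarray(xs) + intercept)
    ss_res = float((resid**2).sum())
    ss_tot = float(((ys - np.mean(ys)) ** 2).sum())
    if ss_tot == 0:
        return float("nan")
    return 1.0 - ss_res / ss_tot


def pick_soft_threshold(
    em: ExpressionMatrix,
    powers: tuple[float, ...] = tuple(range(1, 21)),
    r2_target: float = 0.8,
    sign: str = "unsigned",
    default: float = 6.0,
) -> tuple[float, pd.DataFrame]:
    """Smallest power whose scale-free fit R² reaches the target.

    Falls back to the grid's R²-maximizing power, and to ``default`` if no
    power yields a usable fit (degenerate connectivity distribution).
    Returns (beta, table of power / R² / mean connectivity).
    """
    if not powers:
        raise CoexpressionError("power grid is empty")
    values = em.values
    sd = values.to_numpy().std(axis=1)
    if np.any(sd == 0):
        n_const = int((sd == 0).sum())
        warnings.warn(f"excluding {n_const} constant-expression genes from connectivity")
        values = values.loc[values.index[sd > 0]]
    corr = correlation_matrix(values)
    rows = []
    for beta in powers:
        A = adjacency(corr, power=beta, sign=sign)
        k = A.sum(axis=1)
        rows.append({"power": beta, "r2": scale_free_fit(k), "mean_k": float(k.mean())})
    table = pd.DataFrame(rows)
    usable = table.dropna(subset=["r2"])
    if usable.empty:
        warnings.warn(f"scale-free fit failed for every power; falling back to beta={default}")
        return float(default), table
    hit = usable[usable["r2"] >= r2_target]
    beta = float(hit["power"].iloc[0]) if not hit.empty else float(
        usable.loc[usable["r2"].idxmax(), "power"]
    )
    return beta, table


# ---------------------------------------------------------------------------
# Module detection


def detect_modules(
    diss: np.ndarray,
    min_module_size: int = 30,
    cut_height: float = 0.9,
) -> np.ndarray:
    """Average-linkage clustering of a dissimilarity matrix into modules.

    The tree is cut at the absolute height ``cut_height`` (TOM
    dissimilarity is bounded in [0, 1]: co-expressed genes overlap
    topologically well above the 0.1 the default demands, while unrelated
    gene pairs sit near 1); clusters smaller than ``min_module_size`` are
    assigned label 0, the rest are renumbered by decreasing size.
    """
    D = np.asarray(diss, dtype=float)
    n = D.shape[0]
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T, atol=1e-10):
        raise CoexpressionError("dissimilarity must be square and symmetric")
    if n < min_module_size:
        warnings.warn(
            f"{n} genes < min_module_size={min_module_size}; all genes left unassigned"
        )
        return np.zeros(n, dtype=int)
    condensed = squareform(D, checks=False)
    Z = average(condensed)
    raw = fcluster(Z, t=cut_height, criterion="distance")
    labels = np.zeros(n, dtype=int)
    sizes = pd.Series(raw).value_counts()
    kept = sizes[sizes >= min_module_size].sort_values(ascending=False)
    for new_label, old_label in enumerate(kept.index, start=1):
        labels[raw == old_label] = new_label
    return labels


def merge_similar_modules(
    em: ExpressionMatrix,
    labels: np.ndarray,
    threshold: float = 0.25,
) -> np.ndarray:
    """Greedily merge modules whose eigengenes are closer than ``threshold``
    in correlation dissimilarity (1 − cor), closest pair first.

    Off by default in the pipeline; labels are renumbered by decreasing
    size afterwards.
    """
    labels = np.asarray(labels, dtype=int).copy()
    gene_index = em.values.index
    while True:
        modules = sorted(set(labels) - {0})
        if len(modules) < 2:
            break
        eigs = {
            m: module_eigengene(em.values.loc[gene_index[labels == m]])[0]
            for m in modules
        }
        best = None
        for idx, a in enumerate(modules):
            for b in modules[idx + 1:]:
                d = 1.0 - float(np.corrcoef(eigs[a], eigs[b])[0, 1])
                if d < threshold and (best is None or d < best[0]):
                    best = (d, a, b)
        if best is None:
            break
        labels[labels == best[2]] = best[1]
    out = np.zeros_like(labels)
    sizes = pd.Series(labels[labels > 0]).value_counts()
    for new_label, old_label in enumerate(sizes.index, start=1):
        out[labels == old_label] = new_label
    return out


# ---------------------------------------------------------------------------
# Eigengenes and trait correlation


def module_eigengene(values: pd.DataFrame) -> tuple[np.ndarray, float]:
    """First principal component of a module's standardized expression.

    Returns (eigengene sample scores with unit variance, variance
    explained).  Zero-variance genes are dropped with a warning; the sign
    is oriented so the eigengene correlates non-negatively with the module
    mean standardized profile.
    """
    X = values.to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise CoexpressionError(f"module needs >= 2 genes, got {X.shape[0]}")
    sd = X.std(axis=1, ddof=1)
    if np.any(sd == 0):
        warnings.warn(f"dropping {int((sd == 0).sum())} zero-variance genes from module")
        X = X[sd > 0]
        sd = sd[sd > 0]
        if X.shape[0] < 2:
            raise CoexpressionError("module has < 2 genes after dropping zero-variance genes")
    Z = (X - X.mean(axis=1, keepdims=True)) / sd[:, None]
    # SVD of gene x sample standardized matrix: right singular vector = PC1 scores
    _, svals, vt = np.linalg.svd(Z, full_matrices=False)
    e = vt[0]
    var_explained = float(svals[0] ** 2 / (svals**2).sum())
    mean_profile = Z.mean(axis=0)
    if np.dot(e, mean_profile - mean_profile.mean()) < 0:
        e = -e
    e = e - e.mean()
    e_sd = e.std(ddof=1)
    if e_sd == 0:
        raise CoexpressionError("degenerate eigengene (zero variance)")
    return e / e_sd, var_explained


def correlate_with_trait(e: np.ndarray, trait: np.ndarray) -> tuple[float, float]:
    """Pearson r of a sample-level vector with trait codes, and its
    two-sided p from t = r·sqrt(n−2)/sqrt(1−r²)."""
    e = np.asarray(e, dtype=float)
    trait = np.asarray(trait, dtype=float)
    if e.size != trait.size or e.size < 3:
        raise CoexpressionError("need matching vectors of length >= 3")
    if np.ptp(trait) == 0:
        raise CoexpressionError("trait codes are constant")
    if np.ptp(e) == 0:
        raise CoexpressionError("constant eigengene: correlation undefined")
    r, p = stats.pearsonr(e, trait)
    if abs(r) >= 1.0:
        return float(np.sign(r)), 0.0
    return float(r), float(p)


@dataclass
class ModuleSet:
    """Gene→module labels with per-module eigengenes and trait correlations."""

    labels: pd.Series                  # gene -> module id (0 = unassigned)
    eigengenes: pd.DataFrame           # module id (str column) x samples? stored module x sample
    trait_table: pd.DataFrame          # module, size, var_explained, r, p, selected, sign

    def genes_of(self, modules: list[int]) -> set[str]:
        keep = set(modules)
        return set(self.labels.index[self.labels.isin(keep)])

    @property
    def selected_modules(self) -> list[int]:
        return self.trait_table.loc[self.trait_table["selected"], "module"].tolist()


def module_trait_analysis(
    em: ExpressionMatrix,
    labels: np.ndarray | pd.Series,
    trait: np.ndarray,
    r_min: float = 0.5,
    alpha: float = 0.05,
) -> ModuleSet:
    """Eigengene and trait correlation per module, with selection flags."""
    labels = pd.Series(np.asarray(labels, dtype=int), index=em.values.index, name="module")
    rows = []
    eig_rows = {}
    for module in sorted(set(labels) - {0}):
        genes = labels.index[labels == module]
        e, var_exp = module_eigengene(em.values.loc[genes])
        r, p = correlate_with_trait(e, trait)
        eig_rows[module] = e
        rows.append({
            "module": module,
            "size": len(genes),
            "var_explained": var_exp,
            "r": r,
            "p": p,
        })
    trait_table = pd.DataFrame(rows, columns=["module", "size", "var_explained", "r", "p"])
    if len(trait_table):
        trait_table["selected"] = (trait_table["r"].abs() > r_min) & (trait_table["p"] < alpha)
        trait_table["sign"] = np.where(trait_table["r"] > 0, "positive", "negative")
    else:
        trait_table["selected"] = pd.Series(dtype=bool)
        trait_table["sign"] = pd.Series(dtype=str)
    eigengenes = pd.DataFrame(eig_rows, index=em.samples.sample_ids).T
    eigengenes.index.name = "module"
    return ModuleSet(labels=labels, eigengenes=eigengenes, trait_table=trait_table)


def select_modules(
    trait_table: pd.DataFrame, r_min: float = 0.5, alpha: float = 0.05
) -> tuple[list[int], list[int]]:
    """(positively, negatively) trait-correlated module ids."""
    pos = trait_table.loc[(trait_table["r"] > r_min) & (trait_table["p"] < alpha), "module"]
    neg = trait_table.loc[(trait_table["r"] < -r_min) & (trait_table["p"] < alpha), "module"]
    return pos.tolist(), neg.tolist()


def module_refine_degs(degs: set[str], module_set: ModuleSet) -> set[str]:
    """M_DEG = DEG ∩ genes of the selected modules (grey genes excluded)."""
    universe = set(module_set.labels.index)
    orphans = degs - universe
    if degs and not (degs & universe):
        raise CoexpressionError(
            f"DEG set and module universe are disjoint (e.g. {sorted(orphans)[:3]})"
        )
    selected_genes = module_set.genes_of(module_set.selected_modules)
    return degs & selected_genes
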