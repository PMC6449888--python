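"""Paired differential expression with empirical-Bayes variance moderation.

For balanced paired data the pair-blocked linear model reduces to the
within-patient differences D_gi = expr(g, i, 12W) − expr(g, i, 0W):

    b_g  = mean_i D_gi            (log2 fold change)
    s2_g = var_i D_gi             (residual variance, d_g = n − 1 df)

Gene-wise variances are shrunk toward a common prior fitted by the method
of moments on log variances (the scaled-F model s2_g ~ s2_0 · F(d, d_0)):

    s2_post = (d_0·s2_0 + d·s2_g) / (d_0 + d)
    t_mod   = b_g / sqrt(s2_post / n),  reference t with d_0 + d df
             (d_0 = ∞ ⇒ s2_post = s2_0 and a normal reference).

DEG calls require BH-adjusted p < alpha AND |b_g| ≥ log2(fc).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .io_formats import ExpressionMatrix


class DiffExprError(ValueError):
    pass


@dataclass(frozen=True)
class ModerationPrior:
    """Inverse-chi-square prior on gene variances: d0 prior df, s2_0 scale."""

    d0: float
    s2_0: float

    def __post_init__(self) -> None:
        if self.d0 < 0:
            raise DiffExprError(f"prior df must be >= 0, got {self.d0}")
        if self.s2_0 <= 0:
            raise DiffExprError(f"prior variance must be > 0, got {self.s2_0}")


def paired_differences(em: ExpressionMatrix) -> pd.DataFrame:
    """Gene × patient matrix of within-patient 12W − 0W differences."""
    pairs = em.samples.pairs()
    if len(pairs) < 2:
        raise DiffExprError(f"paired analysis requires >= 2 patients, got {len(pairs)}")
    cols = {patient: em.values[s12].to_numpy() - em.values[s0].to_numpy()
            for patient, s0, s12 in pairs}
    return pd.DataFrame(cols, index=em.values.index)


def paired_effects(em: ExpressionMatrix) -> pd.DataFrame:
    """Per-gene paired effect size, residual variance, and residual df."""
    diffs = paired_differences(em)
    n = diffs.shape[1]
    b = diffs.mean(axis=1)
    s2 = diffs.var(axis=1, ddof=1)
    out = pd.DataFrame({"logFC": b, "s2": s2})
    out["df"] = float(n - 1)
    out.attrs["n_patients"] = n
    return out


def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return math.inf
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if -dif / x < 1e-10:
            break
    return float(x)


def estimate_prior(s2: np.ndarray | pd.Series, df: float) -> ModerationPrior:
    """Method-of-moments fit of (d0, s2_0) on log variances.

    Matches mean and spread of log s2_g to the scaled-F model via
    digamma/trigamma identities.  If the observed spread does not exceed
    the chi-square sampling floor, d0 = ∞ and s2_0 is the geometric mean
    of the positive variances.
    """
    s2 = np.asarray(s2, dtype=float)
    pos = s2[s2 > 0]
    if pos.size == 0:
        raise DiffExprError("cannot estimate a variance prior: all gene variances are zero")
    if pos.size < 10:
        raise DiffExprError(f"prior estimation requires >= 10 genes with s2 > 0, got {pos.size}")
    z = np.log(pos)
    # center each log-variance by its chi-square sampling bias
    e = z - special.digamma(df / 2.0) + math.log(df / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar <= 0:
        return ModerationPrior(d0=math.inf, s2_0=float(np.exp(z.mean())))
    d0 = 2.0 * trigamma_inverse(evar)
    s2_0 = float(np.exp(emean + special.digamma(d0 / 2.0) - math.log(d0 / 2.0)))
    return ModerationPrior(d0=d0, s2_0=s2_0)


def moderated_t(
    b: np.ndarray | pd.Series,
    s2: np.ndarray | pd.Series,
    df: float,
    prior: ModerationPrior,
    n: int,
) -> pd.DataFrame:
    """Moderated t statistics and two-sided p-values.

    d0 = 0 reduces to the ordinary paired t-test; d0 = ∞ uses the prior
    variance for every gene with a normal reference.  Genes with
    s2_post = 0 get t = ±inf, p = 0 and a ``degenerate`` flag.
    """
    b = np.asarray(b, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    if math.isinf(prior.d0):
        s2_post = np.full_like(s2, prior.s2_0)
        df_total = math.inf
    else:
        s2_post = (prior.d0 * prior.s2_0 + df * s2) / (prior.d0 + df)
        df_total = prior.d0 + df
    se = np.sqrt(s2_post / n)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, b / np.where(se > 0, se, 1.0), np.sign(b) * np.inf)
        t = np.where((se == 0) & (b == 0), 0.0, t)
    if math.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.where(np.isinf(t), 0.0, p)
    p = np.where((se == 0) & (b == 0), 1.0, p)
    return pd.DataFrame({
        "s2_post": s2_post,
        "t": t,
        "df_total": df_total,
        "p": p,
        "degenerate": se == 0,
    })


def bh_adjust(p: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        bad = np.argwhere(~((p >= 0) & (p <= 1)))[0][0]
        raise DiffExprError(f"p-value outside [0, 1] at position {bad}: {p[bad]}")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def call_degs(table: pd.DataFrame, alpha: float = 0.05, fc: float = 1.55) -> pd.DataFrame:
    """Flag DEGs: q < alpha AND |logFC| >= log2(fc); direction by sign."""
    if fc < 1:
        raise DiffExprError(f"fold-change threshold must be >= 1, got {fc}")
    if "q" not in table.columns:
        raise DiffExprError("call_degs requires a 'q' column (run bh_adjust first)")
    lfc_min = math.log2(fc)
    out = table.copy()
    out["is_deg"] = (out["q"] < alpha) & (out["logFC"].abs() >= lfc_min)
    out["direction"] = np.where(out["logFC"] > 0, "up", "down")
    out.attrs["n_deg"] = int(out["is_deg"].sum())
    out.attrs["n_up"] = int((out["is_deg"] & (out["direction"] == "up")).sum())
    out.attrs["n_down"] = int((out["is_deg"] & (out["direction"] == "down")).sum())
    return out


def differential_expression(
    em: ExpressionMatrix,
    alpha: float = 0.05,
    fc: float = 1.55,
) -> pd.DataFrame:
    """Full paired moderated-t pipeline: effects → prior → t → BH → calls."""
    eff = paired_effects(em)
    n = eff.attrs["n_patients"]
    df = float(eff["df"].iloc[0])
    prior = estimate_prior(eff["s2"].to_numpy(), df)
    mod = moderated_t(eff["logFC"].to_numpy(), eff["s2"].to_numpy(), df, prior, n)
    table = pd.concat([eff.reset_index(drop=True), mod], axis=1)
    table.index = eff.index
    table.index.name = "gene"
    table["q"] = bh_adjust(table["p"].to_numpy())
    table = call_degs(table, alpha=alpha, fc=fc)
    table.attrs["prior_d0"] = prior.d0
    table.attrs["prior_s2_0"] = prior.s2_0
    table.attrs["n_patients"] = n
    return table


def deg_set(table: pd.DataFrame) -> set[str]:
    return set(table.index[table["is_deg"]])
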