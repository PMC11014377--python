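"""Two-group (24m vs 6m) differential expression with the study's
significance classification.

The engine is a self-contained Welch t-test on log2(x+1) behind a pluggable
contract: any callable producing per-feature (log2FC, p) can replace it, and
every downstream statistic consumes only the resulting table.  Features are
labeled ``up`` when padj <= alpha and log2FC >= tau, ``down`` when
padj <= alpha and log2FC <= -tau, else ``ns`` — both thresholds inclusive.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import AGED, YOUNG, CountMatrix

DEFAULT_ALPHA = 0.05
DEFAULT_TAU = 0.58

DEEngine = Callable[[np.ndarray, np.ndarray], tuple[np.ndarray, np.ndarray]]


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    n = p.size
    if n == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def welch_log_engine(young: np.ndarray, aged: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Reference DE engine: log2FC from pseudocounted group means and a
    two-sided Welch t on log2(x+1).

    Degenerate features (both groups constant) get p = 1 when the means are
    equal and p = 0 when they differ exactly — the latter cannot arise from
    continuous data and is kept deterministic.
    """
    ly, la = np.log2(young + 1.0), np.log2(aged + 1.0)
    log2fc = np.log2(aged.mean(axis=1) + 1.0) - np.log2(young.mean(axis=1) + 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(la, ly, axis=1, equal_var=False)
    p = np.asarray(p, dtype=float)
    degenerate = ~np.isfinite(p)
    if degenerate.any():
        eq = np.isclose(la.mean(axis=1), ly.mean(axis=1))
        p[degenerate & eq] = 1.0
        p[degenerate & ~eq] = 0.0
    return log2fc, p


def moderated_t_engine(young: np.ndarray, aged: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Default DE engine: t-test on log2(x+1) with empirical-Bayes variance
    moderation across features.

    Per-feature residual variances are squeezed toward the common variance
    s0^2 with prior weight d0 estimated by method of moments from the
    spread of the observed variances; small designs (n = 4 per group)
    borrow strength across features the way count-model DE packages do.
    Swapping the group labels negates every log2FC and leaves every p
    unchanged.
    """
    ly, la = np.log2(young + 1.0), np.log2(aged + 1.0)
    n1, n2 = ly.shape[1], la.shape[1]
    d = n1 + n2 - 2
    diff = la.mean(axis=1) - ly.mean(axis=1)
    log2fc = np.log2(aged.mean(axis=1) + 1.0) - np.log2(young.mean(axis=1) + 1.0)
    s2 = (ly.var(axis=1, ddof=1) * (n1 - 1) + la.var(axis=1, ddof=1) * (n2 - 1)) / d
    s0 = float(s2.mean())
    var_s2 = float(s2.var(ddof=1)) if s2.size > 1 else 0.0
    if s0 > 0 and var_s2 > 2 * s0**2 / d:
        d0 = 2.0 / (var_s2 / s0**2 - 2.0 / d)
    else:
        d0 = 100.0
    d0 = float(np.clip(d0, 1.0, 100.0))
    s2_mod = (d0 * s0 + d * s2) / (d0 + d)
    se = np.sqrt(s2_mod * (1.0 / n1 + 1.0 / n2))
    with np.errstate(invalid="ignore", divide="ignore"):
        t = diff / se
    p = 2.0 * stats.t.sf(np.abs(t), df=d + d0)
    degenerate = ~np.isfinite(p)
    if degenerate.any():
        eq = np.isclose(diff, 0)
        p[degenerate & eq] = 1.0
        p[degenerate & ~eq] = 0.0
    return log2fc, p


def differential_expression(
    matrix: CountMatrix,
    alpha: float = DEFAULT_ALPHA,
    tau: float = DEFAULT_TAU,
    engine: DEEngine = moderated_t_engine,
) -> pd.DataFrame:
    """Per-feature DE table with columns log2FC, p, padj, direction.

    log2FC is 24m over 6m with pseudocount 1; BH adjustment is applied
    across all tested features of the matrix (genes and isoforms are
    analyzed in separate calls, so each level gets its own adjustment).
    """
    young_cols = matrix.group_samples(YOUNG)
    aged_cols = matrix.group_samples(AGED)
    if len(young_cols) < 2 or len(aged_cols) < 2:
        raise ValueError("differential expression requires >=2 samples per group")
    young = matrix.values[young_cols].to_numpy(float)
    aged = matrix.values[aged_cols].to_numpy(float)
    log2fc, p = engine(young, aged)
    padj = bh_adjust(p)
    direction = np.where(
        (padj <= alpha) & (log2fc >= tau),
        "up",
        np.where((padj <= alpha) & (log2fc <= -tau), "down", "ns"),
    )
    return pd.DataFrame(
        {"log2FC": log2fc, "p": p, "padj": padj, "direction": direction},
        index=matrix.feature_ids.rename("feature_id"),
    )


def cross_platform_correlation(
    de_a: pd.DataFrame, de_b: pd.DataFrame
) -> tuple[float, float, int]:
    """Spearman rank correlation of log2FC over the shared features of two
    DE tables (e.g. short-read vs long-read platforms)."""
    shared = de_a.index.intersection(de_b.index)
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared features; need >=3")
    rho, p = stats.spearmanr(de_a.loc[shared, "log2FC"], de_b.loc[shared, "log2FC"])
    return float(rho), float(p), int(len(shared))


def gene_set_shift_test(
    matrix: CountMatrix, gene_set: Sequence[str]
) -> tuple[float, float, int]:
    """Paired t-test across genes of a set, pairing each gene's young-group
    mean with its aged-group mean (used e.g. for X/Y-chromosome gene sets)."""
    usable = [g for g in dict.fromkeys(gene_set) if g in matrix.feature_ids]
    if len(usable) < 3:
        raise ValueError(f"only {len(usable)} genes of the set are in the matrix; need >=3")
    means = matrix.group_means().loc[usable]
    diffs = means[AGED].to_numpy(float) - means[YOUNG].to_numpy(float)
    if np.allclose(diffs, 0):
        return 0.0, 1.0, len(usable)
    t, p = stats.ttest_rel(means[AGED], means[YOUNG])
    return float(t), float(p), len(usable)


def write_de_table(de: pd.DataFrame, path) -> None:
    de.to_csv(path, sep="\t", index_label="feature_id")
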