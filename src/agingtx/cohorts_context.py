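"""Marker-assignment and enrichment rules used to contextualize bulk
changes with cell-type, region, and gene-set information.

All rules use strict inequalities; the cell-type fold-change rule applies a
pseudocount of 1 to the comparison cell type to avoid zero division.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import AGED, YOUNG
from .diffexpr import bh_adjust


def celltype_specific_genes(
    mean_expr: pd.DataFrame, threshold: float = 4.0
) -> dict[str, list[str]]:
    """Gene g is specific to cell type c iff
    expr(g, c) > threshold * (expr(g, c') + 1) for every other cell type c'.

    At most one cell type can satisfy this per gene (threshold > 1), so the
    resulting lists are mutually exclusive.  The stricter variant used for
    denser marker sets raises the threshold to 5.
    """
    if mean_expr.shape[1] < 2:
        raise ValueError("need at least two cell types")
    if threshold <= 1:
        raise ValueError("threshold must be > 1")
    out: dict[str, list[str]] = {c: [] for c in mean_expr.columns}
    vals = mean_expr.to_numpy(float)
    for i, gene in enumerate(mean_expr.index):
        for j, ct in enumerate(mean_expr.columns):
            others = np.delete(vals[i], j)
            if np.all(vals[i, j] > threshold * (others + 1.0)):
                out[ct].append(str(gene))
                break
    return out


def region_assignment(counts: pd.DataFrame) -> pd.Series:
    """Assign each gene to the single region whose count exceeds the median
    of that gene's counts in the other regions; genes beating the
    out-region median in multiple regions (or none) stay unassigned.

    Requires >=3 regions so the out-region median is informative.  The rule
    is invariant to region column order and to any monotone rescaling
    applied uniformly to all regions of a gene.
    """
    if counts.shape[1] < 3:
        raise ValueError("need at least three regions")
    assigned = {}
    vals = counts.to_numpy(float)
    for i, gene in enumerate(counts.index):
        winners = [
            r
            for j, r in enumerate(counts.columns)
            if vals[i, j] > np.median(np.delete(vals[i], j))
        ]
        assigned[str(gene)] = winners[0] if len(winners) == 1 else None
    return pd.Series(assigned, name="region")


def composition_change(
    cell_counts: pd.DataFrame, sample_ages: pd.Series
) -> pd.DataFrame:
    """Per-sample cell-type percentages (summing to 100) and a per-type
    Welch t-test of the percentage across ages, BH across types.  Samples
    with zero total cells are excluded and counted."""
    totals = cell_counts.sum(axis=1)
    excluded = list(cell_counts.index[totals <= 0])
    keep = cell_counts.loc[totals > 0]
    pct = keep.div(keep.sum(axis=1), axis=0) * 100.0
    ages = sample_ages.loc[pct.index]
    rows = []
    for ct in pct.columns:
        y = pct.loc[ages == YOUNG, ct].to_numpy(float)
        a = pct.loc[ages == AGED, ct].to_numpy(float)
        if len(y) < 2 or len(a) < 2:
            continue
        if np.isclose(y.std(), 0) and np.isclose(a.std(), 0):
            t, p = (0.0, 1.0) if np.isclose(y.mean(), a.mean()) else (np.inf, 0.0)
        else:
            t, p = stats.ttest_ind(a, y, equal_var=False)
        rows.append({"cell_type": ct, "mean_pct_young": float(y.mean()),
                     "mean_pct_aged": float(a.mean()),
                     "diff_pct": float(a.mean() - y.mean()),
                     "t": float(t), "p": float(p)})
    out = pd.DataFrame(rows).set_index("cell_type")
    out["padj"] = bh_adjust(out["p"].to_numpy())
    out.attrs["excluded_samples"] = excluded
    return out


def ora_test(
    hits: list[str],
    background: list[str],
    gene_sets: dict[str, list[str]],
) -> pd.DataFrame:
    """Over-representation of a hit list in named gene sets within a
    caller-declared background: one-sided hypergeometric tail p per set,
    BH across sets.  Hits outside the background are dropped and counted;
    sets disjoint from the background are skipped."""
    bg = set(background)
    if not bg:
        raise ValueError("empty background")
    hit_set = set(hits)
    dropped = len(hit_set - bg)
    hit_set &= bg
    rows = []
    n_bg, n_hits = len(bg), len(hit_set)
    for name, genes in gene_sets.items():
        in_bg = set(genes) & bg
        if not in_bg:
            rows.append({"set": name, "set_size": 0, "overlap": 0, "p": np.nan})
            continue
        k = len(hit_set & in_bg)
        # P(X >= k) for X ~ Hypergeom(N=n_bg, K=len(in_bg), n=n_hits)
        p = float(stats.hypergeom.sf(k - 1, n_bg, len(in_bg), n_hits))
        rows.append({"set": name, "set_size": len(in_bg), "overlap": k, "p": p})
    out = pd.DataFrame(rows).set_index("set")
    mask = out["p"].notna()
    out["padj"] = np.nan
    out.loc[mask, "padj"] = bh_adjust(out.loc[mask, "p"].to_numpy())
    out.attrs["hits_dropped"] = dropped
    return out


def read_gmt(path) -> dict[str, list[str]]:
    """Gene sets in GMT format (set name, description, genes...)."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = [g for g in parts[2:] if g]
    return sets
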