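"""Signed co-expression network modules from soft-thresholded correlation
and topological overlap.

The adjacency is a_ij = ((1 + cor_ij)/2)^beta (signed network), the
clustering dissimilarity is 1 - TOM, and modules come from average-linkage
hierarchical clustering with a static cut.  Full-study defaults are
beta = 18, min_size = 300, cut_height = 0.85; a desk-scale preset
(beta = 6, min_size = 20) is provided for small simulated designs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform

from .core_io import AGED, YOUNG, CountMatrix
from .diffexpr import bh_adjust

UNASSIGNED = "M0"


@dataclass
class ModuleConfig:
    beta: float = 18.0
    min_size: int = 300
    cut_height: float = 0.85

    def __post_init__(self) -> None:
        if self.beta < 1:
            raise ValueError("beta must be >= 1")
        if self.min_size < 2:
            raise ValueError("min_size must be >= 2")
        if not (0 < self.cut_height <= 1):
            raise ValueError("cut_height must be in (0, 1]")

    @classmethod
    def desk_scale(cls) -> "ModuleConfig":
        """Small-design preset used throughout the simulated test suites."""
        return cls(beta=6.0, min_size=20, cut_height=0.85)


@dataclass
class ModuleAssignment:
    """gene -> module labels (M0 unassigned; M1..Mk by decreasing size),
    module eigengenes (module x sample) and per-module age-direction tests."""

    labels: pd.Series
    eigengenes: pd.DataFrame
    direction: pd.DataFrame = field(default_factory=pd.DataFrame)

    def members(self, module: str) -> list[str]:
        return list(self.labels.index[self.labels == module])

    def module_names(self) -> list[str]:
        return [m for m in self.eigengenes.index]


def signed_adjacency(expr: CountMatrix, beta: float) -> pd.DataFrame:
    """a_ij = ((1 + pearson_ij)/2)^beta over gene pairs.

    Genes with zero variance across samples cannot be correlated and raise,
    naming the first offender; callers should drop them beforehand.
    """
    vals = expr.values.to_numpy(float)
    sd = vals.std(axis=1)
    if (sd == 0).any():
        bad = expr.feature_ids[np.argmax(sd == 0)]
        raise ValueError(f"zero-variance gene reached adjacency: {bad}")
    cor = np.corrcoef(vals)
    adj = ((1.0 + cor) / 2.0) ** beta
    np.fill_diagonal(adj, 1.0)
    adj = np.clip((adj + adj.T) / 2.0, 0.0, 1.0)
    return pd.DataFrame(adj, index=expr.feature_ids, columns=expr.feature_ids)


def topological_overlap(adjacency: pd.DataFrame) -> pd.DataFrame:
    """TOM_ij = (sum_{u not in {i,j}} a_iu a_uj + a_ij) /
    (min(k_i, k_j) + 1 - a_ij), with connectivity k_i = sum_{u != i} a_iu."""
    a = adjacency.to_numpy(float)
    if not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    if not np.allclose(np.diag(a), 1.0):
        raise ValueError("adjacency must have a unit diagonal")
    n = a.shape[0]
    prod = a @ a
    # remove u = i and u = j terms from the shared-neighbor sum
    shared = prod - 2.0 * a  # a_ii * a_ij + a_ij * a_jj = 2 a_ij when diag = 1
    k = a.sum(axis=1) - 1.0
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (shared + a) / denom
    tom[~np.isfinite(tom)] = 1.0
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    return pd.DataFrame(tom, index=adjacency.index, columns=adjacency.columns)


def _eigengene(member_vals: np.ndarray) -> np.ndarray:
    """First principal component of standardized module expression, unit
    variance across samples, sign-aligned with the module mean profile."""
    z = (member_vals - member_vals.mean(axis=1, keepdims=True))
    sd = z.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = z / sd
    # samples x genes SVD; first right-singular direction over samples
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    pc = vt[0]
    if np.corrcoef(pc, z.mean(axis=0))[0, 1] < 0:
        pc = -pc
    sd_pc = pc.std()
    return pc / (sd_pc if sd_pc > 0 else 1.0)


def detect_modules(
    tom: pd.DataFrame, config: ModuleConfig, expr: CountMatrix
) -> ModuleAssignment:
    """Average-linkage clustering on 1-TOM with a static cut at
    ``cut_height``; clusters below ``min_size`` fall into M0.  Surviving
    modules are labeled M1..Mk by decreasing size (ties broken by smallest
    member index for determinism).  Each module gets an eigengene and a
    paired-t age-direction test (gene young means vs aged means), BH across
    modules."""
    genes = list(tom.index)
    n = len(genes)
    if n < config.min_size:
        import warnings

        warnings.warn("fewer genes than min_size; all genes unassigned")
        labels = pd.Series(UNASSIGNED, index=pd.Index(genes, name="gene_id"))
        return ModuleAssignment(labels, pd.DataFrame(columns=expr.sample_ids))
    dist = 1.0 - tom.to_numpy(float)
    np.fill_diagonal(dist, 0.0)
    link = average(squareform(dist, checks=False))
    raw = fcluster(link, t=config.cut_height, criterion="distance")
    sizes: dict[int, int] = {}
    for c in raw:
        sizes[c] = sizes.get(c, 0) + 1
    surviving = [c for c, sz in sizes.items() if sz >= config.min_size]
    surviving.sort(key=lambda c: (-sizes[c], int(np.argmax(raw == c))))
    name_of = {c: f"M{i + 1}" for i, c in enumerate(surviving)}
    labels = pd.Series(
        [name_of.get(c, UNASSIGNED) for c in raw],
        index=pd.Index(genes, name="gene_id"),
        name="module",
    )

    vals = expr.values.loc[genes]
    eg_rows = {}
    t_rows = []
    young_cols = expr.group_samples(YOUNG)
    aged_cols = expr.group_samples(AGED)
    for c in surviving:
        name = name_of[c]
        members = labels.index[labels == name]
        member_vals = vals.loc[members].to_numpy(float)
        eg_rows[name] = _eigengene(member_vals)
        ym = vals.loc[members, young_cols].mean(axis=1).to_numpy(float)
        am = vals.loc[members, aged_cols].mean(axis=1).to_numpy(float)
        if np.allclose(am, ym):
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_rel(am, ym)
        t_rows.append({"module": name, "t": float(t), "p": float(p),
                       "mean_shift": float((am - ym).mean())})
    eigengenes = pd.DataFrame(eg_rows, index=expr.sample_ids).T
    eigengenes.index.name = "module"
    direction = pd.DataFrame(t_rows)
    if not direction.empty:
        direction["padj"] = bh_adjust(direction["p"].to_numpy())
        direction["direction"] = np.where(direction["mean_shift"] > 0, "up", "down")
        direction = direction.set_index("module")
    return ModuleAssignment(labels, eigengenes, direction)


def run_wgcna_like(
    expr: CountMatrix, config: ModuleConfig | None = None
) -> ModuleAssignment:
    """Convenience: adjacency -> TOM -> modules in one call."""
    config = config or ModuleConfig()
    adj = signed_adjacency(expr, config.beta)
    tom = topological_overlap(adj)
    return detect_modules(tom, config, expr)


def module_overlap(
    assignment: ModuleAssignment,
    gene_lists: dict[str, list[str]],
    universe: list[str],
) -> pd.DataFrame:
    """Fisher exact overlap of each module with each named gene list inside
    a declared universe; overlap ratio = |module & list| / |list & universe|.
    Lists disjoint from the universe are reported with a missing ratio."""
    if not gene_lists or not universe:
        raise ValueError("gene lists and universe must be non-empty")
    uni = set(universe)
    rows = []
    for module in assignment.module_names():
        mod = set(assignment.members(module)) & uni
        for name, lst in gene_lists.items():
            lset = set(lst) & uni
            inter = len(mod & lset)
            if not lset:
                rows.append({"module": module, "list": name, "overlap": 0,
                             "ratio": np.nan, "p": np.nan})
                continue
            table = [
                [inter, len(mod) - inter],
                [len(lset) - inter, len(uni) - len(mod) - len(lset) + inter],
            ]
            _, p = stats.fisher_exact(table, alternative="greater")
            rows.append({"module": module, "list": name, "overlap": inter,
                         "ratio": inter / len(lset), "p": float(p)})
    out = pd.DataFrame(rows)
    ok = out["p"].notna()
    out["padj"] = np.nan
    out.loc[ok, "padj"] = bh_adjust(out.loc[ok, "p"].to_numpy())
    return out
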