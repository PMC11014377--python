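"""Gene-wise sequence-feature contrasts between up- and down-regulated
isoforms of the same gene.

A gene is "bidirectional" when it has at least one significantly
upregulated and one significantly downregulated isoform in the aged brain.
For such genes the contrast statistics compare a sequence feature (region
length, GC%, GC3%) between the two isoform groups in a normalized form:
with group means m_up and m_dn and anchor a = (m_up + m_dn)/2,

    ratio_up = m_up / a,  ratio_down = m_dn / a,  delta = (m_up - m_dn) / a

so equality gives ratios of 1 and delta of 0, and the statistic does not
depend on expression magnitudes — only on direction labels and sequence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import TranscriptCatalog

REGIONS = ("cDNA", "CDS", "5UTR", "3UTR")


def gc_content(seq: str) -> float:
    """GC fraction of a sequence in percent (N excluded from denominator)."""
    seq = seq.upper()
    acgt = sum(seq.count(b) for b in "ACGT")
    if acgt == 0:
        return float("nan")
    return 100.0 * (seq.count("G") + seq.count("C")) / acgt


def gc3_content(cds_seq: str) -> float:
    """Percent of complete codons whose third (wobble) base is G or C.

    Trailing incomplete codons are ignored; the stop codon counts as a
    codon.  AU3 is the complement (100 - GC3).
    """
    cds_seq = cds_seq.upper()
    n_codons = len(cds_seq) // 3
    if n_codons == 0:
        return float("nan")
    third = cds_seq[2 : 3 * n_codons : 3]
    return 100.0 * sum(1 for b in third if b in "GC") / n_codons


def transcript_region_features(
    catalog: TranscriptCatalog, sequences: dict[str, str]
) -> pd.DataFrame:
    """Per-isoform table of region lengths and GC%, plus GC3/AU3 for the CDS.

    ``sequences`` maps transcript id -> cDNA (sense strand).  A sequence
    whose length disagrees with the catalog raises, naming the isoform.
    Isoforms without a CDS get missing CDS/UTR/GC3 entries.
    """
    rows = []
    for tx in catalog:
        seq = sequences.get(tx.transcript_id)
        if seq is None:
            raise ValueError(f"no sequence for isoform {tx.transcript_id}")
        if len(seq) != tx.cdna_length:
            raise ValueError(
                f"sequence/catalog length mismatch for {tx.transcript_id}: "
                f"{len(seq)} vs {tx.cdna_length}"
            )
        row: dict[str, object] = {
            "transcript_id": tx.transcript_id,
            "gene_id": tx.gene_id,
        }
        regions = tx.region_tx_intervals()
        for region in REGIONS:
            if region in regions:
                a, b = regions[region]
                sub = seq[a:b]
                row[f"len_{region}"] = b - a
                row[f"gc_{region}"] = gc_content(sub) if b > a else np.nan
            else:
                row[f"len_{region}"] = np.nan
                row[f"gc_{region}"] = np.nan
        if "CDS" in regions:
            a, b = regions["CDS"]
            cds_seq = seq[a:b]
            if len(cds_seq) % 3:
                cds_seq = cds_seq[: len(cds_seq) - len(cds_seq) % 3]
            row["gc3"] = gc3_content(cds_seq)
            row["au3"] = 100.0 - row["gc3"] if np.isfinite(row["gc3"]) else np.nan
        else:
            row["gc3"] = np.nan
            row["au3"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("transcript_id")


@dataclass
class GeneIsoformContrast:
    gene_id: str
    up_isoforms: list[str]
    down_isoforms: list[str]


def find_bidirectional_genes(
    iso_de: pd.DataFrame, catalog: TranscriptCatalog
) -> list[GeneIsoformContrast]:
    """Genes with >=1 isoform labeled up AND >=1 labeled down; ns isoforms
    belong to neither set."""
    gene_of = {tx.transcript_id: tx.gene_id for tx in catalog}
    ups: dict[str, list[str]] = {}
    downs: dict[str, list[str]] = {}
    for tid, row in iso_de.iterrows():
        gid = gene_of.get(str(tid))
        if gid is None:
            continue
        if row["direction"] == "up":
            ups.setdefault(gid, []).append(str(tid))
        elif row["direction"] == "down":
            downs.setdefault(gid, []).append(str(tid))
    out = [
        GeneIsoformContrast(g, sorted(ups[g]), sorted(downs[g]))
        for g in sorted(set(ups) & set(downs))
    ]
    return out


def genewise_normalized_contrast(
    contrasts: list[GeneIsoformContrast],
    features: pd.DataFrame,
    feature_col: str,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-gene normalized contrast of one feature column between up- and
    down-isoform groups, plus a paired t-test across genes pairing ratio_up
    with ratio_down.

    Isoform means within a gene are unweighted.  Genes whose anchor
    (m_up + m_dn)/2 is zero or whose feature values are all missing are
    skipped and flagged in the returned test dict (``n_skipped``).
    """
    rows = []
    n_skipped = 0
    for c in contrasts:
        up_vals = features.loc[
            [t for t in c.up_isoforms if t in features.index], feature_col
        ].dropna()
        dn_vals = features.loc[
            [t for t in c.down_isoforms if t in features.index], feature_col
        ].dropna()
        if up_vals.empty or dn_vals.empty:
            n_skipped += 1
            continue
        m_up, m_dn = float(up_vals.mean()), float(dn_vals.mean())
        anchor = (m_up + m_dn) / 2.0
        if anchor == 0:
            n_skipped += 1
            continue
        rows.append(
            {
                "gene_id": c.gene_id,
                "mean_up": m_up,
                "mean_down": m_dn,
                "ratio_up": m_up / anchor,
                "ratio_down": m_dn / anchor,
                "delta": (m_up - m_dn) / anchor,
            }
        )
    table = pd.DataFrame(rows)
    test: dict[str, float] = {"n_genes": float(len(rows)), "n_skipped": float(n_skipped)}
    if len(rows) >= 2:
        diffs = table["ratio_up"].to_numpy() - table["ratio_down"].to_numpy()
        if np.allclose(diffs, 0):
            test["t"], test["p"] = 0.0, 1.0
        else:
            t, p = stats.ttest_rel(table["ratio_up"], table["ratio_down"])
            test["t"], test["p"] = float(t), float(p)
    return table, test


def contrast_all_regions(
    contrasts: list[GeneIsoformContrast],
    features: pd.DataFrame,
    kind: str = "len",
) -> pd.DataFrame:
    """Run the normalized contrast for every mRNA region of one feature kind
    (``len`` or ``gc``), with a Tukey HSD comparing delta across regions."""
    frames = []
    for region in REGIONS:
        col = f"{kind}_{region}" if kind in ("len", "gc") else kind
        if col not in features.columns:
            continue
        table, test = genewise_normalized_contrast(contrasts, features, col)
        if table.empty:
            continue
        table = table.assign(region=region, p_paired=test.get("p", np.nan))
        frames.append(table)
    if not frames:
        return pd.DataFrame()
    out = pd.concat(frames, ignore_index=True)
    if out["region"].nunique() > 1:
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        tk = pairwise_tukeyhsd(out["delta"].to_numpy(), out["region"].to_numpy())
        out.attrs["tukey"] = pd.DataFrame(
            tk.summary().data[1:], columns=tk.summary().data[0]
        )
    return out


def length_expression_correlation(
    de: pd.DataFrame,
    lengths: pd.Series,
    assignment=None,
) -> pd.DataFrame:
    """Spearman correlation of log2FC against feature length, overall and
    per co-expression module (modules with <3 usable genes are skipped)."""
    shared = de.index.intersection(lengths.dropna().index)
    if len(shared) < 3:
        raise ValueError("need >=3 features with both log2FC and length")
    rows = []

    def _corr(ids, label):
        if len(ids) < 3:
            return
        rho, p = stats.spearmanr(de.loc[ids, "log2FC"], lengths.loc[ids])
        rows.append({"scope": label, "rho": float(rho), "p": float(p), "n": len(ids)})

    _corr(shared, "overall")
    if assignment is not None:
        for module in assignment.module_names():
            ids = [g for g in assignment.members(module) if g in shared]
            _corr(pd.Index(ids), module)
    return pd.DataFrame(rows)
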