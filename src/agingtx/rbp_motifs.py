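"""RNA-binding-protein / splicing-factor motif scoring on transcript
regions.

Motifs are IUPAC consensus strings (U treated as T).  The binding
probability of a protein on a region is the number of (overlapping) motif
occurrences per region length, scaled per 10,000 bp, summed over the
protein's motifs.  Scanning is single-strand: transcript sequences are
already sense-strand, and N in a sequence matches nothing.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust

SCALE_BP = 10_000

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def parse_motif_table(path: str | Path) -> dict[str, list[str]]:
    """Read a TSV with columns protein, motif; validate IUPAC characters,
    map U to T, and collapse duplicate (protein, motif) rows."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    if table.shape[1] < 2:
        raise ValueError(f"{path}: expected columns protein, motif")
    table = table.rename(columns=dict(zip(table.columns[:2], ["protein", "motif"])))
    out: dict[str, list[str]] = {}
    for i, row in table.iterrows():
        protein, motif = str(row["protein"]), str(row["motif"]).upper().replace("U", "T")
        if not motif:
            raise ValueError(f"{path} row {i}: empty motif for {protein}")
        bad = [ch for ch in motif if ch not in IUPAC]
        if bad:
            raise ValueError(
                f"{path} row {i}: invalid IUPAC character {bad[0]!r} in motif "
                f"{motif!r} for {protein}"
            )
        if motif not in out.setdefault(protein, []):
            out[protein].append(motif)
    return out


def _motif_regex(motif: str) -> re.Pattern:
    motif = motif.upper().replace("U", "T")
    return re.compile("(?=" + "".join(f"[{IUPAC[c]}]" for c in motif) + ")")


def count_motif_occurrences(sequence: str, motif: str) -> int:
    """Overlapping occurrences of an IUPAC motif in a sequence; a motif
    longer than the sequence yields 0, and N in the sequence never
    matches."""
    bad = [ch for ch in motif.upper().replace("U", "T") if ch not in IUPAC]
    if bad:
        raise ValueError(f"invalid IUPAC character {bad[0]!r} in motif {motif!r}")
    return len(_motif_regex(motif).findall(sequence.upper()))


def binding_probability(sequence: str, motifs: list[str]) -> float:
    """B = sum over the protein's motifs of occurrences / length x 10,000."""
    if len(sequence) == 0:
        raise ValueError("binding probability undefined for a zero-length region")
    total = sum(count_motif_occurrences(sequence, m) for m in motifs)
    return total / len(sequence) * SCALE_BP


def binding_profiles(
    region_sequences: dict[str, str], motif_table: dict[str, list[str]]
) -> pd.DataFrame:
    """Binding probability per transcript x protein for one region; entries
    with zero-length regions are missing."""
    rows = {}
    for tid, seq in region_sequences.items():
        if not seq:
            rows[tid] = {p: np.nan for p in motif_table}
            continue
        rows[tid] = {p: binding_probability(seq, ms) for p, ms in motif_table.items()}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "transcript_id"
    return out


def group_contrast(
    profiles: pd.DataFrame,
    de: pd.DataFrame,
    min_group: int = 3,
) -> pd.DataFrame:
    """Contrast binding probability between transcripts grouped by their DE
    direction (down / up / ns): per protein a one-way ANOVA across the
    three groups, Tukey HSD pairwise adjusted p-values, and log2 fold
    changes of the group means over the ns group (pseudocount = smallest
    positive B observed for the protein)."""
    shared = profiles.index.intersection(de.index)
    direction = de.loc[shared, "direction"]
    groups = {g: list(direction.index[direction == g]) for g in ("down", "up", "ns")}
    rows = []
    for protein in profiles.columns:
        b = profiles.loc[shared, protein]
        samples = {g: b.loc[ids].dropna() for g, ids in groups.items()}
        if any(len(v) < min_group for v in samples.values()):
            rows.append({"protein": protein, "skipped": True})
            continue
        f, p = stats.f_oneway(*[v.to_numpy(float) for v in samples.values()])
        pos = b[b > 0]
        pseudo = float(pos.min()) if len(pos) else 1.0
        log2fc_up = float(np.log2((samples["up"].mean() + pseudo)
                                  / (samples["ns"].mean() + pseudo)))
        log2fc_down = float(np.log2((samples["down"].mean() + pseudo)
                                    / (samples["ns"].mean() + pseudo)))
        row = {"protein": protein, "skipped": False, "anova_F": float(f),
               "anova_p": float(p), "log2fc_up_vs_ns": log2fc_up,
               "log2fc_down_vs_ns": log2fc_down}
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        vals = np.concatenate([samples[g].to_numpy(float) for g in ("down", "up", "ns")])
        labs = np.concatenate([[g] * len(samples[g]) for g in ("down", "up", "ns")])
        tk = pairwise_tukeyhsd(vals, labs)
        summary = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
        for _, trow in summary.iterrows():
            row[f"tukey_p_{trow['group1']}_vs_{trow['group2']}"] = float(trow["p-adj"])
        rows.append(row)
    out = pd.DataFrame(rows).set_index("protein")
    ok = out.get("anova_p")
    if ok is not None and ok.notna().any():
        out["anova_padj"] = np.nan
        mask = ok.notna()
        out.loc[mask, "anova_padj"] = bh_adjust(ok[mask].to_numpy())
    return out
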