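"""Differential transcript usage, splicing-event classification between
switching isoforms, event-asymmetry statistics, and functional consequences
(ORF, NMD by the 50-nt rule, coding potential, peptide similarity).

Event taxonomy (strand-aware):

ATSS  alternative transcription start site (5' end differs beyond a
      tolerance; default 10 nt absorbs sequencing-end noise)
ATTS  alternative transcription termination site (3' end differs)
A5    alternative 5' splice site (donor shifted at a shared intron)
A3    alternative 3' splice site (acceptor shifted)
ES    one internal exon skipped with both flanking junctions shared
MES   two or more consecutive internal exons skipped
MEE   mutually exclusive exons: one exclusive internal exon per isoform
      inside the same inter-junction window
IR    intron retention: one isoform's exon spans the other's intron with
      both flanking exon boundaries matched

Each event records the isoform that "carries" it: the skipping isoform for
ES/MES, the retaining isoform for IR, the isoform whose splice site falls
inside the other's intron for A5/A3, the isoform with the shorter
(more internal) transcript end for ATSS/ATTS, and for MEE the isoform
owning the 5'-most exclusive exon (a positional convention, since MEE is
intrinsically mutual).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import AGED, YOUNG, CountMatrix, Transcript, TranscriptCatalog
from .diffexpr import bh_adjust

EVENT_TYPES = ("ATSS", "ATTS", "A5", "A3", "ES", "MES", "MEE", "IR")

STOP_CODONS = {"TAA", "TAG", "TGA"}
NMD_BOUNDARY_NT = 50
CODING_MIN_ORF_NT = 300
TSS_TOLERANCE_NT = 10


# ---------------------------------------------------------------------------
# Isoform fractions and the usage test
# ---------------------------------------------------------------------------

@dataclass
class IsoformFractionTable:
    """Isoform fractions (isoform count / gene count) per sample after the
    expression filters, plus the boundary-shrinkage epsilon used by the
    logit transform."""

    fractions: pd.DataFrame          # isoforms x samples
    gene_of: dict[str, str]
    samples: pd.DataFrame
    epsilon: float
    n_genes_removed: int = 0
    n_isoforms_removed: int = 0

    def group_samples(self, age_group: str) -> list[str]:
        sheet = self.samples.loc[self.fractions.columns]
        return list(sheet.index[sheet["age_group"] == age_group])


def compute_isoform_fractions(
    gene_matrix: CountMatrix,
    isoform_matrix: CountMatrix,
    catalog: TranscriptCatalog,
    gene_cutoff: float = 5.0,
    iso_cutoff: float = 3.0,
) -> IsoformFractionTable:
    """Filter as the usage analysis prescribes, then renormalize isoform
    fractions over the retained isoforms of each gene.

    Genes with mean expression below ``gene_cutoff`` are dropped, isoforms
    with mean expression below ``iso_cutoff`` are dropped, and genes left
    with fewer than two isoforms are removed entirely (single-isoform genes
    carry no usage signal).
    """
    gene_of = {}
    for tid in isoform_matrix.feature_ids:
        try:
            gene_of[tid] = catalog.gene_of(str(tid))
        except KeyError as exc:
            raise ValueError(f"isoform {tid} has no gene in the catalog") from exc
    gene_means = gene_matrix.values.mean(axis=1)
    ok_genes = set(gene_means.index[gene_means >= gene_cutoff])
    iso_means = isoform_matrix.values.mean(axis=1)
    keep = [
        tid
        for tid in isoform_matrix.feature_ids
        if gene_of[tid] in ok_genes and iso_means[tid] >= iso_cutoff
    ]
    per_gene: dict[str, list[str]] = {}
    for tid in keep:
        per_gene.setdefault(gene_of[tid], []).append(tid)
    multi = {g for g, tids in per_gene.items() if len(tids) >= 2}
    retained = [tid for tid in keep if gene_of[tid] in multi]

    vals = isoform_matrix.values.loc[retained]
    gene_index = pd.Index([gene_of[t] for t in retained])
    totals = vals.groupby(gene_index).transform("sum")
    with np.errstate(invalid="ignore", divide="ignore"):
        fractions = vals / totals
    med = float(np.median(gene_matrix.values.loc[sorted(multi)].to_numpy())) if multi else 1.0
    epsilon = 1.0 / (2.0 * max(med, 1.0))
    return IsoformFractionTable(
        fractions=fractions,
        gene_of={t: gene_of[t] for t in retained},
        samples=isoform_matrix.samples,
        epsilon=epsilon,
        n_genes_removed=len(set(gene_of.values())) - len(multi),
        n_isoforms_removed=len(gene_of) - len(retained),
    )


def dtu_test(ift: IsoformFractionTable, alpha: float = 0.05) -> pd.DataFrame:
    """Per-isoform usage test: t on logit-transformed fractions with
    boundary shrinkage and empirical-Bayes variance moderation across
    isoforms, dIF = mean IF(24m) - mean IF(6m), BH across isoforms.
    Fractions constant at 0 or 1 across all samples are degenerate and
    get p = 1 (flagged)."""
    young_cols = ift.group_samples(YOUNG)
    aged_cols = ift.group_samples(AGED)
    if len(young_cols) < 2 or len(aged_cols) < 2:
        raise ValueError("usage test requires >=2 samples per group")
    fr = ift.fractions
    eps = ift.epsilon
    stats_rows = []
    for tid, row in fr.iterrows():
        y = row[young_cols].to_numpy(float)
        a = row[aged_cols].to_numpy(float)
        y, a = y[np.isfinite(y)], a[np.isfinite(a)]
        if len(y) < 2 or len(a) < 2:
            continue
        dif = float(a.mean() - y.mean())
        allv = np.concatenate([y, a])
        degenerate = bool(np.allclose(allv, 0) or np.allclose(allv, 1))
        ly = _logit(np.clip(y, eps, 1 - eps))
        la = _logit(np.clip(a, eps, 1 - eps))
        d = len(y) + len(a) - 2
        s2 = (ly.var(ddof=1) * (len(y) - 1) + la.var(ddof=1) * (len(a) - 1)) / d
        stats_rows.append({
            "transcript_id": tid, "gene_id": ift.gene_of[tid], "dIF": dif,
            "degenerate": degenerate, "diff_logit": float(la.mean() - ly.mean()),
            "s2": float(s2), "inv_n": 1.0 / len(y) + 1.0 / len(a), "df": d,
        })
    rows = []
    if stats_rows:
        s2_all = np.array([r["s2"] for r in stats_rows if not r["degenerate"]])
        d = stats_rows[0]["df"]
        s0 = float(s2_all.mean()) if s2_all.size else 0.0
        var_s2 = float(s2_all.var(ddof=1)) if s2_all.size > 1 else 0.0
        if s0 > 0 and var_s2 > 2 * s0**2 / d:
            d0 = float(np.clip(2.0 / (var_s2 / s0**2 - 2.0 / d), 1.0, 100.0))
        else:
            d0 = 100.0
        for r in stats_rows:
            if r["degenerate"]:
                rows.append({"transcript_id": r["transcript_id"],
                             "gene_id": r["gene_id"], "dIF": r["dIF"],
                             "p": 1.0, "degenerate": True})
                continue
            s2_mod = (d0 * s0 + r["df"] * r["s2"]) / (d0 + r["df"])
            se = np.sqrt(s2_mod * r["inv_n"])
            if se == 0:
                p = 1.0 if np.isclose(r["diff_logit"], 0) else 0.0
            else:
                t = r["diff_logit"] / se
                p = float(2.0 * stats.t.sf(abs(t), df=r["df"] + d0))
            rows.append({"transcript_id": r["transcript_id"],
                         "gene_id": r["gene_id"], "dIF": r["dIF"],
                         "p": p, "degenerate": False})
    if not rows:
        return pd.DataFrame(
            columns=["gene_id", "dIF", "p", "degenerate", "padj", "significant"],
            index=pd.Index([], name="transcript_id"),
        )
    out = pd.DataFrame(rows).set_index("transcript_id")
    out["padj"] = bh_adjust(out["p"].to_numpy())
    out["significant"] = out["padj"] <= alpha
    return out


def _logit(x: np.ndarray) -> np.ndarray:
    return np.log(x / (1.0 - x))


@dataclass(frozen=True)
class SwitchPair:
    """An isoform switch: within one gene, the aged-up and aged-down member."""

    gene_id: str
    up: str
    down: str


def find_switch_pairs(dtu: pd.DataFrame, alpha: float = 0.05) -> list[SwitchPair]:
    """Isoform pairs within a gene with significant, opposite-signed dIF.
    The most extreme up and down isoforms per gene form the reported pair."""
    sig = dtu[dtu["padj"] <= alpha]
    pairs = []
    for gid, sub in sig.groupby("gene_id"):
        ups = sub[sub["dIF"] > 0].sort_values("dIF", ascending=False)
        downs = sub[sub["dIF"] < 0].sort_values("dIF")
        if len(ups) and len(downs):
            pairs.append(SwitchPair(str(gid), str(ups.index[0]), str(downs.index[0])))
    return sorted(pairs, key=lambda p: p.gene_id)


# ---------------------------------------------------------------------------
# Splicing-event classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplicingEvent:
    gene_id: str
    event_type: str
    carrier: str               # transcript id of the isoform carrying the event
    pair: tuple[str, str]


def classify_splicing_events(
    iso_a: Transcript,
    iso_b: Transcript,
    tss_tolerance: int = TSS_TOLERANCE_NT,
) -> set[SplicingEvent]:
    """Classify every splicing difference between two isoforms of one gene.

    Coordinates are genomic 0-based half-open; donor/acceptor labels are
    assigned strand-aware.  A pair may carry several events.
    """
    if iso_a.gene_id != iso_b.gene_id:
        raise ValueError("isoforms belong to different genes")
    if iso_a.strand != iso_b.strand:
        raise ValueError("isoforms on different strands")
    strand = iso_a.strand
    gene = iso_a.gene_id
    pair = (iso_a.transcript_id, iso_b.transcript_id)
    events: set[SplicingEvent] = set()

    def emit(ev_type: str, carrier: Transcript) -> None:
        events.add(SplicingEvent(gene, ev_type, carrier.transcript_id, pair))

    # --- transcript ends (ATSS / ATTS) ------------------------------------
    left_a, right_a = iso_a.start, iso_a.end
    left_b, right_b = iso_b.start, iso_b.end
    if strand == "+":
        if abs(left_a - left_b) > tss_tolerance:
            emit("ATSS", iso_a if left_a > left_b else iso_b)
        if abs(right_a - right_b) > tss_tolerance:
            emit("ATTS", iso_a if right_a < right_b else iso_b)
    else:
        if abs(right_a - right_b) > tss_tolerance:
            emit("ATSS", iso_a if right_a < right_b else iso_b)
        if abs(left_a - left_b) > tss_tolerance:
            emit("ATTS", iso_a if left_a > left_b else iso_b)

    ex = {iso_a.transcript_id: iso_a.exons, iso_b.transcript_id: iso_b.exons}
    ends = {t: {e for _, e in x} for t, x in ex.items()}
    starts = {t: {s for s, _ in x} for t, x in ex.items()}

    # --- exon skipping (ES / MES) ------------------------------------------
    for skipper, other in ((iso_a, iso_b), (iso_b, iso_a)):
        for s, e in skipper.introns():
            if s in ends[other.transcript_id] and e in starts[other.transcript_id]:
                inside = [x for x in other.exons if s <= x[0] and x[1] <= e]
                if len(inside) == 1:
                    emit("ES", skipper)
                elif len(inside) >= 2:
                    emit("MES", skipper)

    # --- alternative donors / acceptors (A5 / A3) ---------------------------
    for ia in iso_a.introns():
        for ib in iso_b.introns():
            if ia == ib or ia[1] <= ib[0] or ib[1] <= ia[0]:
                continue
            if ia[0] == ib[0] and ia[1] != ib[1]:
                # shared left boundary; right (acceptor on +) shifted
                down_a = _exon_starting_at(iso_a, ia[1])
                down_b = _exon_starting_at(iso_b, ib[1])
                if down_a and down_b and _overlap(down_a, down_b):
                    carrier = iso_a if ia[1] < ib[1] else iso_b
                    emit("A3" if strand == "+" else "A5", carrier)
            elif ia[1] == ib[1] and ia[0] != ib[0]:
                up_a = _exon_ending_at(iso_a, ia[0])
                up_b = _exon_ending_at(iso_b, ib[0])
                if up_a and up_b and _overlap(up_a, up_b):
                    carrier = iso_a if ia[0] > ib[0] else iso_b
                    emit("A5" if strand == "+" else "A3", carrier)

    # --- intron retention ---------------------------------------------------
    for retainer, other in ((iso_a, iso_b), (iso_b, iso_a)):
        other_exons = set(map(tuple, other.exons))
        for gs, ge in retainer.exons:
            for s, e in other.introns():
                if (gs, s) in other_exons and (e, ge) in other_exons:
                    emit("IR", retainer)

    # --- mutually exclusive exons ------------------------------------------
    common_donors = ends[iso_a.transcript_id] & ends[iso_b.transcript_id]
    common_acceptors = starts[iso_a.transcript_id] & starts[iso_b.transcript_id]
    for y1 in sorted(common_donors):
        for x2 in sorted(common_acceptors):
            if x2 <= y1:
                continue
            in_a = [x for x in iso_a.exons if y1 <= x[0] and x[1] <= x2]
            in_b = [x for x in iso_b.exons if y1 <= x[0] and x[1] <= x2]
            if len(in_a) == 1 and len(in_b) == 1 and not _overlap(in_a[0], in_b[0]):
                ea, eb = in_a[0], in_b[0]
                if strand == "+":
                    carrier = iso_a if ea[0] < eb[0] else iso_b
                else:
                    carrier = iso_a if ea[0] > eb[0] else iso_b
                emit("MEE", carrier)
    return events


def _exon_starting_at(tx: Transcript, pos: int) -> tuple[int, int] | None:
    for s, e in tx.exons:
        if s == pos:
            return (s, e)
    return None


def _exon_ending_at(tx: Transcript, pos: int) -> tuple[int, int] | None:
    for s, e in tx.exons:
        if e == pos:
            return (s, e)
    return None


def _overlap(x: tuple[int, int], y: tuple[int, int]) -> bool:
    return x[0] < y[1] and y[0] < x[1]


def classify_switch_events(
    switches: list[SwitchPair], catalog: TranscriptCatalog,
    tss_tolerance: int = TSS_TOLERANCE_NT,
) -> dict[SwitchPair, set[SplicingEvent]]:
    return {
        sp: classify_splicing_events(catalog[sp.up], catalog[sp.down], tss_tolerance)
        for sp in switches
    }


# ---------------------------------------------------------------------------
# Event-fraction asymmetry test
# ---------------------------------------------------------------------------

def event_fraction_test(
    events_by_pair: dict[SwitchPair, set[SplicingEvent]]
) -> pd.DataFrame:
    """Per event type, the fraction of informative switch pairs where the
    aged-up isoform carries the event, with a two-sided exact binomial test
    against 0.5 and BH adjustment across event types.

    A pair is informative for a type when exactly one member carries it
    (f = 0.5 signifies no asymmetry between up- and down-isoforms).
    Types with zero informative pairs are omitted.
    """
    rows = []
    for ev_type in EVENT_TYPES:
        n_up = n_info = 0
        for sp, events in events_by_pair.items():
            carriers = {e.carrier for e in events if e.event_type == ev_type}
            hit_up, hit_down = sp.up in carriers, sp.down in carriers
            if hit_up != hit_down:
                n_info += 1
                n_up += int(hit_up)
        if n_info == 0:
            continue
        p = stats.binomtest(n_up, n_info, 0.5, alternative="two-sided").pvalue
        rows.append({"event_type": ev_type, "n": n_info,
                     "fraction_up": n_up / n_info, "p": float(p)})
    out = pd.DataFrame(rows)
    if not out.empty:
        out["padj"] = bh_adjust(out["p"].to_numpy())
        out = out.set_index("event_type")
    return out


# ---------------------------------------------------------------------------
# Module-relative isoform ratio
# ---------------------------------------------------------------------------

def module_relative_isoform_ratio(
    iso_de: pd.DataFrame,
    events_by_pair: dict[SwitchPair, set[SplicingEvent]],
    assignment,
) -> tuple[pd.DataFrame, pd.DataFrame, int]:
    """Label each switching isoform "similar" when its DE direction matches
    the age-direction of its gene's module (else "opposite"); per gene and
    event type the isoform ratio is similar/(similar+opposite).  Gene-level
    ratios are pooled into up-module vs down-module groups and compared per
    event type by an unpaired t-test, with a Tukey HSD across event-type x
    module-direction cells.

    Genes in M0 are excluded; their number is returned.
    """
    if assignment.direction.empty:
        raise ValueError("module assignment has no direction test results")
    mod_dir = assignment.direction["direction"].to_dict()
    labels = assignment.labels
    rows = []
    n_unassigned = 0
    for sp, events in events_by_pair.items():
        module = labels.get(sp.gene_id, "M0")
        if module == "M0" or module not in mod_dir:
            n_unassigned += 1
            continue
        for ev_type in {e.event_type for e in events}:
            n_similar = n_total = 0
            for tid in (sp.up, sp.down):
                if tid not in iso_de.index:
                    continue
                d = iso_de.loc[tid, "direction"]
                if d == "ns":
                    continue
                n_total += 1
                n_similar += int(d == mod_dir[module])
            if n_total:
                rows.append({
                    "gene_id": sp.gene_id, "event_type": ev_type,
                    "module": module, "module_direction": mod_dir[module],
                    "ratio": n_similar / n_total,
                })
    per_gene = pd.DataFrame(rows)
    tests = []
    if not per_gene.empty:
        for ev_type, sub in per_gene.groupby("event_type"):
            up = sub.loc[sub["module_direction"] == "up", "ratio"]
            down = sub.loc[sub["module_direction"] == "down", "ratio"]
            if len(up) >= 2 and len(down) >= 2:
                t, p = stats.ttest_ind(up, down, equal_var=False)
                tests.append({"event_type": ev_type, "mean_up_modules": up.mean(),
                              "mean_down_modules": down.mean(),
                              "t": float(t), "p": float(p)})
    test_df = pd.DataFrame(tests)
    if len(per_gene) and per_gene.groupby(["event_type", "module_direction"]).ngroups > 1:
        cells = (per_gene["event_type"] + ":" + per_gene["module_direction"]).to_numpy()
        if len(np.unique(cells)) > 1 and all(
            np.sum(cells == c) >= 2 for c in np.unique(cells)
        ):
            from statsmodels.stats.multicomp import pairwise_tukeyhsd

            tk = pairwise_tukeyhsd(per_gene["ratio"].to_numpy(), cells)
            test_df.attrs["tukey"] = pd.DataFrame(
                tk.summary().data[1:], columns=tk.summary().data[0]
            )
    return per_gene, test_df, n_unassigned


# ---------------------------------------------------------------------------
# ORF prediction and functional consequences
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Orf:
    start: int      # 0-based position of the A of the ATG
    end: int        # half-open end just past the stop codon
    frame: int

    @property
    def length(self) -> int:
        return self.end - self.start


def predict_orf(cdna: str) -> Orf | None:
    """Longest ATG-to-stop open reading frame; ties broken by the 5'-most
    start.  N never matches; absence is returned, never raised."""
    seq = cdna.upper()
    best: Orf | None = None
    for start in _find_all(seq, "ATG"):
        for pos in range(start + 3, len(seq) - 2, 3):
            codon = seq[pos : pos + 3]
            if codon in STOP_CODONS:
                cand = Orf(start=start, end=pos + 3, frame=start % 3)
                if best is None or cand.length > best.length or (
                    cand.length == best.length and cand.start < best.start
                ):
                    best = cand
                break
    return best


def _find_all(seq: str, sub: str):
    i = seq.find(sub)
    while i != -1:
        yield i
        i = seq.find(sub, i + 1)


def nmd_sensitive(
    tx: Transcript, orf: Orf | None, boundary: int = NMD_BOUNDARY_NT
) -> bool | None:
    """The 50-nt rule: a transcript is NMD-sensitive when its ORF stop lies
    strictly more than ``boundary`` nt upstream of the last exon-exon
    junction in transcript coordinates.  Single-exon transcripts (no
    junction) and ORF-less transcripts return None ("not applicable")."""
    if orf is None:
        return None
    last_junction = tx.last_junction_tx()
    if last_junction is None:
        return None
    return (last_junction - orf.end) > boundary


def orf_similarity(orf_seq_a: str, orf_seq_b: str) -> float:
    """Global-alignment identity of two predicted peptides: match +1,
    mismatch 0, linear gap -1; identity = matches / alignment length."""
    from Bio.Align import PairwiseAligner
    from Bio.Seq import Seq

    pep_a = str(Seq(orf_seq_a).translate(to_stop=True))
    pep_b = str(Seq(orf_seq_b).translate(to_stop=True))
    if not pep_a or not pep_b:
        return 0.0
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = 0
    aligner.open_gap_score = -1
    aligner.extend_gap_score = -1
    aln = aligner.align(pep_a, pep_b)[0]
    a_row, b_row = str(aln[0]), str(aln[1])
    matches = sum(1 for x, y in zip(a_row, b_row) if x == y and x != "-")
    return matches / len(a_row)


CONSEQUENCES = ("NMD_status", "coding_potential", "intron_retention")


def assess_consequences(
    switches: list[SwitchPair],
    catalog: TranscriptCatalog,
    sequences: dict[str, str],
    events_by_pair: dict[SwitchPair, set[SplicingEvent]] | None = None,
    nmd_boundary: int = NMD_BOUNDARY_NT,
    coding_min_len: int = CODING_MIN_ORF_NT,
) -> pd.DataFrame:
    """Per switch pair: NMD status, coding potential (ORF >= 300 nt
    heuristic), peptide similarity of the two ORFs, and an intron-retention
    flag from the event classification."""
    rows = []
    for sp in switches:
        tx_up, tx_down = catalog[sp.up], catalog[sp.down]
        seq_up, seq_down = sequences[sp.up], sequences[sp.down]
        orf_up, orf_down = predict_orf(seq_up), predict_orf(seq_down)
        events = (
            events_by_pair.get(sp, set())
            if events_by_pair is not None
            else classify_splicing_events(tx_up, tx_down)
        )
        ir_carriers = {e.carrier for e in events if e.event_type == "IR"}
        sim = np.nan
        if orf_up and orf_down:
            sim = orf_similarity(
                seq_up[orf_up.start : orf_up.end], seq_down[orf_down.start : orf_down.end]
            )
        rows.append({
            "gene_id": sp.gene_id, "up": sp.up, "down": sp.down,
            "NMD_status_up": nmd_sensitive(tx_up, orf_up, nmd_boundary),
            "NMD_status_down": nmd_sensitive(tx_down, orf_down, nmd_boundary),
            "coding_potential_up": bool(orf_up and orf_up.length >= coding_min_len),
            "coding_potential_down": bool(orf_down and orf_down.length >= coding_min_len),
            "intron_retention_up": sp.up in ir_carriers,
            "intron_retention_down": sp.down in ir_carriers,
            "ORF_seq_similarity": sim,
        })
    return pd.DataFrame(rows)


def consequence_summary(assessed: pd.DataFrame) -> pd.DataFrame:
    """Gain/loss asymmetry per consequence: "gain" when the aged-up isoform
    has the consequence and the aged-down does not; exact binomial test of
    the gain fraction against 0.5, BH across consequences."""
    if assessed.empty:
        return pd.DataFrame(columns=["n", "gain_fraction", "p", "padj"])
    rows = []
    for cons in CONSEQUENCES:
        up = assessed[f"{cons}_up"]
        down = assessed[f"{cons}_down"]
        usable = up.notna() & down.notna()
        gains = int(((up == True) & (down == False) & usable).sum())  # noqa: E712
        losses = int(((up == False) & (down == True) & usable).sum())  # noqa: E712
        n = gains + losses
        if n == 0:
            continue
        p = stats.binomtest(gains, n, 0.5, alternative="two-sided").pvalue
        rows.append({"consequence": cons, "n": n,
                     "gain_fraction": gains / n, "p": float(p)})
    out = pd.DataFrame(rows)
    if not out.empty:
        out["padj"] = bh_adjust(out["p"].to_numpy())
        out = out.set_index("consequence")
    return out
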