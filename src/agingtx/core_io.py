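"""Count-matrix and transcript-catalog containers, file formats, and the
normalization chain applied to bulk RNA-seq counts.

The normalization order is fixed by the pipeline: low-count filtering, then
quantile normalization, then row-wise median centering.  All genomic
coordinates are 0-based half-open internally; GTF conversion happens only on
read/write.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

YOUNG = "6m"
AGED = "24m"
AGE_GROUPS = (YOUNG, AGED)


class ParseError(ValueError):
    """Malformed input file (duplicate ids, missing samples, bad cells)."""


# ---------------------------------------------------------------------------
# CountMatrix
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    """Features x samples abundance matrix with an age-group sample sheet.

    Parameters
    ----------
    values
        DataFrame, rows are feature ids, columns are sample ids.
    samples
        DataFrame indexed by sample id with columns ``age_group``
        (``"6m"`` or ``"24m"``) and ``cohort``.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise ParseError(f"duplicate feature ids: {list(dupes)[:5]}")
        missing = [s for s in self.values.columns if s not in self.samples.index]
        if missing:
            raise ParseError(f"samples absent from sample sheet: {missing}")
        if "age_group" not in self.samples.columns:
            raise ParseError("sample sheet lacks an 'age_group' column")
        bad = set(self.samples["age_group"]) - set(AGE_GROUPS)
        if bad:
            raise ParseError(f"unknown age groups: {sorted(bad)}")
        arr = self.values.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)) or (arr < 0).any():
            raise ParseError("count values must be finite and >= 0")

    # -- convenience -------------------------------------------------------

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def group_samples(self, age_group: str) -> list[str]:
        sheet = self.samples.loc[self.values.columns]
        return list(sheet.index[sheet["age_group"] == age_group])

    def group_means(self) -> pd.DataFrame:
        """Per-feature mean within each age group (columns 6m, 24m)."""
        return pd.DataFrame(
            {g: self.values[self.group_samples(g)].mean(axis=1) for g in AGE_GROUPS}
        )

    def with_values(self, values: pd.DataFrame) -> "CountMatrix":
        return CountMatrix(values=values, samples=self.samples)


def read_counts(path: str | Path, sample_sheet_path: str | Path) -> CountMatrix:
    """Read a tab-separated counts file (first column feature ids) plus a
    sample sheet TSV with columns sample_id, age_group[, cohort]."""
    try:
        values = pd.read_csv(path, sep="\t", index_col=0)
    except ValueError as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"{path}: {exc}") from exc
    for col in values.columns:
        coerced = pd.to_numeric(values[col], errors="coerce")
        bad = coerced.isna() & values[col].notna()
        if bad.any():
            row = values.index[bad.argmax()]
            raise ParseError(f"{path}: non-numeric cell at row {row!r}, column {col!r}")
        values[col] = coerced
    samples = read_sample_sheet(sample_sheet_path)
    return CountMatrix(values=values.astype(float), samples=samples)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", dtype=str)
    if sheet.shape[1] < 2:
        raise ParseError(f"{path}: expected columns sample_id, age_group[, cohort]")
    sheet = sheet.rename(
        columns=dict(zip(sheet.columns[:3], ["sample_id", "age_group", "cohort"]))
    )
    if "cohort" not in sheet.columns:
        sheet["cohort"] = "c1"
    return sheet.set_index("sample_id")


def write_counts(matrix: CountMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="feature_id")


def write_sample_sheet(samples: pd.DataFrame, path: str | Path) -> None:
    samples.to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# Normalization chain
# ---------------------------------------------------------------------------

def filter_low_counts(
    matrix: CountMatrix, threshold: float = 5.0, agg: str = "mean"
) -> tuple[CountMatrix, int]:
    """Drop features whose aggregate raw count is <= ``threshold``.

    The aggregation across samples is configurable (``mean`` default,
    ``max`` or ``total``); removal is inclusive at the threshold.
    Returns the filtered matrix and the number of features removed.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if agg == "mean":
        stat = matrix.values.mean(axis=1)
    elif agg == "max":
        stat = matrix.values.max(axis=1)
    elif agg == "total":
        stat = matrix.values.sum(axis=1)
    else:
        raise ValueError(f"unknown aggregation {agg!r}")
    keep = stat > threshold
    return matrix.with_values(matrix.values.loc[keep]), int((~keep).sum())


def quantile_normalize(matrix: CountMatrix) -> CountMatrix:
    """Quantile-normalize samples so every column shares the same empirical
    distribution.  Ties within a sample receive the mean of the rank-means
    they span."""
    vals = matrix.values.to_numpy(dtype=float)
    n_feat, n_samp = vals.shape
    if n_samp < 2:
        warnings.warn("quantile_normalize: single sample, returning input unchanged")
        return matrix
    if n_feat == 0:
        return matrix
    rank_means = np.sort(vals, axis=0).mean(axis=1)
    csum = np.concatenate([[0.0], np.cumsum(rank_means)])
    out = np.empty_like(vals)
    from scipy.stats import rankdata

    for j in range(n_samp):
        lo = rankdata(vals[:, j], method="min").astype(int)
        hi = rankdata(vals[:, j], method="max").astype(int)
        # mean of rank_means over the tie span [lo, hi]
        out[:, j] = (csum[hi] - csum[lo - 1]) / (hi - lo + 1)
    return matrix.with_values(
        pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    )


def row_median_center(matrix: CountMatrix) -> tuple[CountMatrix, list[str]]:
    """Divide each row by its own median.  Rows whose median is zero are
    divided by their smallest positive value instead and flagged; all-zero
    rows are left untouched and flagged."""
    vals = matrix.values.to_numpy(dtype=float).copy()
    flagged: list[str] = []
    med = np.median(vals, axis=1)
    for i in range(vals.shape[0]):
        d = med[i]
        if d == 0:
            pos = vals[i][vals[i] > 0]
            flagged.append(str(matrix.values.index[i]))
            if pos.size == 0:
                continue
            d = pos.min()
        vals[i] /= d
    return (
        matrix.with_values(
            pd.DataFrame(vals, index=matrix.values.index, columns=matrix.values.columns)
        ),
        flagged,
    )


def normalize_pipeline(
    matrix: CountMatrix, threshold: float = 5.0, agg: str = "mean"
) -> CountMatrix:
    """The fixed chain: filter -> quantile -> row-median."""
    filtered, _ = filter_low_counts(matrix, threshold=threshold, agg=agg)
    qn = quantile_normalize(filtered)
    centered, _ = row_median_center(qn)
    return centered


def count_isoforms_detected(
    isoform_matrix: CountMatrix, cutoff: float = 2.0
) -> dict[str, float]:
    """Count isoforms whose within-age-group mean normalized value is
    strictly above ``cutoff``, per group, and the percent difference
    100*(aged-young)/young."""
    means = isoform_matrix.group_means()
    for g in AGE_GROUPS:
        if not isoform_matrix.group_samples(g):
            raise ValueError(f"no samples in age group {g}")
    n_young = int((means[YOUNG] > cutoff).sum())
    n_aged = int((means[AGED] > cutoff).sum())
    pct = 100.0 * (n_aged - n_young) / n_young if n_young else float("nan")
    return {"n_young": n_young, "n_aged": n_aged, "percent_difference": pct}


# ---------------------------------------------------------------------------
# TranscriptCatalog
# ---------------------------------------------------------------------------

@dataclass
class Transcript:
    """One isoform: sorted non-overlapping exons, optional CDS, genomic
    0-based half-open coordinates."""

    transcript_id: str
    gene_id: str
    strand: str
    exons: list[tuple[int, int]]
    cds: tuple[int, int] | None = None
    chrom: str = "chr1"

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.transcript_id}: strand must be + or -")
        ex = sorted(self.exons)
        for (s0, e0), (s1, e1) in zip(ex, ex[1:]):
            if e0 > s1:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
        for s, e in ex:
            if e <= s:
                raise ValueError(f"{self.transcript_id}: empty exon ({s},{e})")
        self.exons = ex
        if self.cds is not None:
            cs, ce = self.cds
            if not (self.exons[0][0] <= cs < ce <= self.exons[-1][1]):
                raise ValueError(f"{self.transcript_id}: CDS outside exon span")

    # -- geometry ----------------------------------------------------------

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def cdna_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def introns(self) -> list[tuple[int, int]]:
        return [(e0, s1) for (_, e0), (s1, _) in zip(self.exons, self.exons[1:])]

    def genomic_to_tx(self, pos: int) -> int:
        """Map a genomic position lying on an exon to transcript coordinates
        (0-based, 5'->3' along the transcript)."""
        fwd = self._tx_start_offset(pos)
        if self.strand == "+":
            return fwd
        return self.cdna_length - 1 - fwd

    def cds_tx_interval(self) -> tuple[int, int] | None:
        """CDS as a half-open interval in transcript coordinates."""
        if self.cds is None:
            return None
        cs, ce = self.cds
        if self.strand == "+":
            a = self.genomic_to_tx(cs)
            b = self._tx_of_end(ce)
        else:
            a = self.genomic_to_tx(ce - 1)
            b = self._tx_of_end_minus(cs)
        return (a, b)

    def _tx_of_end(self, pos: int) -> int:
        # map a half-open genomic end to a half-open tx end (+ strand)
        offset = 0
        for s, e in self.exons:
            if s < pos <= e:
                return offset + (pos - s)
            offset += e - s
        raise ValueError(f"{self.transcript_id}: end {pos} not exonic")

    def _tx_of_end_minus(self, pos: int) -> int:
        # CDS genomic start maps to the tx end on the - strand
        return self.cdna_length - self._tx_start_offset(pos)

    def _tx_start_offset(self, pos: int) -> int:
        offset = 0
        for s, e in self.exons:
            if s <= pos < e:
                return offset + (pos - s)
            offset += e - s
        raise ValueError(f"{self.transcript_id}: position {pos} not exonic")

    def region_tx_intervals(self) -> dict[str, tuple[int, int]]:
        """Half-open transcript-coordinate intervals for cDNA/5'UTR/CDS/3'UTR."""
        out = {"cDNA": (0, self.cdna_length)}
        cds = self.cds_tx_interval()
        if cds is not None:
            out["5UTR"] = (0, cds[0])
            out["CDS"] = cds
            out["3UTR"] = (cds[1], self.cdna_length)
        return out

    def last_junction_tx(self) -> int | None:
        """Transcript coordinate of the last exon-exon junction (None for
        single-exon transcripts)."""
        if len(self.exons) == 1:
            return None
        lengths = [e - s for s, e in self.exons]
        if self.strand == "-":
            lengths = lengths[::-1]
        return sum(lengths[:-1])


@dataclass
class TranscriptCatalog:
    """gene -> isoform structure collection."""

    transcripts: dict[str, Transcript] = field(default_factory=dict)

    def add(self, tx: Transcript) -> None:
        if tx.transcript_id in self.transcripts:
            raise ParseError(f"duplicate transcript id {tx.transcript_id}")
        self.transcripts[tx.transcript_id] = tx

    def __iter__(self):
        return iter(self.transcripts.values())

    def __len__(self) -> int:
        return len(self.transcripts)

    def __getitem__(self, transcript_id: str) -> Transcript:
        return self.transcripts[transcript_id]

    def genes(self) -> dict[str, list[Transcript]]:
        out: dict[str, list[Transcript]] = {}
        for tx in self.transcripts.values():
            out.setdefault(tx.gene_id, []).append(tx)
        return out

    def gene_of(self, transcript_id: str) -> str:
        return self.transcripts[transcript_id].gene_id


def write_gtf(catalog: TranscriptCatalog, path: str | Path) -> None:
    """Write exon and CDS features, converting to GTF's 1-based inclusive
    coordinates."""
    with open(path, "w") as fh:
        for tx in catalog:
            attrs = f'gene_id "{tx.gene_id}"; transcript_id "{tx.transcript_id}";'
            for s, e in tx.exons:
                fh.write(
                    f"{tx.chrom}\tagingtx\texon\t{s + 1}\t{e}\t.\t{tx.strand}\t.\t{attrs}\n"
                )
            if tx.cds is not None:
                cs, ce = tx.cds
                fh.write(
                    f"{tx.chrom}\tagingtx\tCDS\t{cs + 1}\t{ce}\t.\t{tx.strand}\t.\t{attrs}\n"
                )


def read_gtf(path: str | Path) -> TranscriptCatalog:
    """Read a GTF with exon/CDS features carrying gene_id and transcript_id
    attributes; coordinates are converted to 0-based half-open."""
    import gffutils

    try:
        db = gffutils.create_db(
            str(path), ":memory:", keep_order=True,
            disable_infer_genes=True, disable_infer_transcripts=True,
        )
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str, str]] = {}
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS"):
            continue
        tids = feat.attributes.get("transcript_id")
        gids = feat.attributes.get("gene_id")
        if not tids or not gids:
            raise ParseError(f"{path}: {feat.featuretype} feature missing "
                             "gene_id/transcript_id")
        tid = tids[0]
        iv = (feat.start - 1, feat.end)
        meta.setdefault(tid, (gids[0], feat.strand, feat.seqid))
        (exons if feat.featuretype == "exon" else cds).setdefault(tid, []).append(iv)
    catalog = TranscriptCatalog()
    for tid, (gid, strand, chrom) in meta.items():
        cds_iv = None
        if tid in cds:
            segs = sorted(cds[tid])
            cds_iv = (segs[0][0], segs[-1][1])
        catalog.add(
            Transcript(
                transcript_id=tid,
                gene_id=gid,
                strand=strand,
                exons=sorted(exons.get(tid, [])),
                cds=cds_iv,
                chrom=chrom,
            )
        )
    return catalog


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")
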