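"""Synthetic inputs with known ground truth for every pipeline stage.

The generator emulates the study design: two age groups (6m young adult,
24m aged) with four replicates each, negative-binomial gene/isoform counts
with correlated module blocks and planted age effects, bidirectional
isoform switches, transcript models differing from their gene's reference
isoform by exactly one labeled splicing event, cDNA sequences with
controlled GC/GC3 and planted motifs, and steady-state premature/mature
count pairs with planted stability shifts.

Counts follow NB(mean mu, dispersion phi) with variance mu + phi*mu^2; one
latent factor per module, shared by the module's genes and drawn per
sample, generates the block correlation the network stage must recover.
All coordinates are 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import AGED, YOUNG, CountMatrix, Transcript, TranscriptCatalog
from .splicing import EVENT_TYPES, STOP_CODONS


class GenerationError(ValueError):
    """Requested synthetic geometry or density cannot be realized."""


@dataclass
class SimConfig:
    """Study-condition knobs for the synthetic bundle.

    Defaults mirror the emulated design: 4 replicates per age group, five
    correlated modules, moderate NB dispersion, and a planted |log2FC| of
    1 for isoform switches.
    """

    n_genes: int = 500
    isoforms_per_gene: tuple[int, int] = (1, 4)
    n_samples_per_group: int = 4
    n_modules: int = 5
    module_size: int = 40
    module_effect: float = 0.75       # log2-scale age effect on module genes
    module_loading: float = 1.0       # latent-factor loading
    switch_fraction: float = 0.3      # fraction of multi-isoform genes switched
    switch_lfc: float = 1.0           # planted |log2FC| per switching isoform
    de_fraction: float = 0.2          # fraction of module-free genes with age DE
    de_lfc: float = 2.0               # planted |log2FC| for those genes
    nb_dispersion: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_genes, self.n_samples_per_group, self.n_modules,
               self.module_size, self.isoforms_per_gene[0]) < 1:
            raise ValueError("all counts must be >= 1")
        if not (0 <= self.switch_fraction <= 1):
            raise ValueError("switch_fraction must be in [0, 1]")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if self.isoforms_per_gene[0] > self.isoforms_per_gene[1]:
            raise ValueError("isoforms_per_gene range inverted")

    def rng(self, salt: int = 0) -> np.random.Generator:
        return np.random.default_rng((self.seed * 1_000_003 + salt) % 2**31)


# ---------------------------------------------------------------------------
# Transcript catalog with planted splicing events
# ---------------------------------------------------------------------------

_EXON_LEN = (120, 180)
_INTRON_LEN = (400, 600)
_N_EXONS = 6
_END_SHIFT = 60          # ATSS/ATTS shift, well past the 10-nt call tolerance
_SITE_SHIFT = 80         # A5/A3 splice-site shift


def _plant_event(exons: list[list[int]], event: str, strand: str,
                 gene_id: str) -> list[list[int]]:
    ex = [list(e) for e in exons]
    n = len(ex)
    if event in ("MES",) and n < 5:
        raise GenerationError(f"{gene_id}: MES needs >=5 exons, got {n}")
    if n < 4:
        raise GenerationError(f"{gene_id}: event {event} needs >=4 exons, got {n}")
    if event == "ATSS":
        if strand == "+":
            ex[0][0] += _END_SHIFT
        else:
            ex[-1][1] -= _END_SHIFT
    elif event == "ATTS":
        if strand == "+":
            ex[-1][1] -= _END_SHIFT
        else:
            ex[0][0] += _END_SHIFT
    elif event == "A5":
        if strand == "+":
            ex[1][1] += _SITE_SHIFT       # donor pushed into the intron
        else:
            ex[2][0] -= _SITE_SHIFT
    elif event == "A3":
        if strand == "+":
            ex[2][0] -= _SITE_SHIFT       # acceptor pulled into the intron
        else:
            ex[1][1] += _SITE_SHIFT
    elif event == "ES":
        del ex[2]
    elif event == "MES":
        del ex[2:4]
    elif event == "MEE":
        x, y = ex[2]
        ex[2] = [y + 40, y + 130]
        if ex[2][1] >= ex[3][0] - 20:
            raise GenerationError(f"{gene_id}: intron too short for MEE geometry")
    elif event == "IR":
        ex[2] = [ex[2][0], ex[3][1]]
        del ex[3]
    else:
        raise GenerationError(f"{gene_id}: unknown event type {event}")
    return ex


def _assign_cds(exons: list[tuple[int, int]], strand: str) -> tuple[int, int]:
    """CDS covering roughly the middle half of the transcript, with a length
    divisible by 3 (leaves UTRs long enough to host motifs)."""
    positions: list[int] = []
    for s, e in exons:
        positions.extend(range(s, e))
    if strand == "-":
        positions = positions[::-1]
    L = len(positions)
    a = max(3, round(0.25 * L))
    cds_len = ((round(0.5 * L)) // 3) * 3
    cds_len = max(cds_len, 6)
    b = min(a + cds_len, L)
    b = a + ((b - a) // 3) * 3
    span = positions[a:b]
    return (min(span), max(span) + 1)


def generate_transcript_catalog(
    config: SimConfig, events: list[str] | None = None
) -> tuple[TranscriptCatalog, pd.DataFrame]:
    """Build one reference isoform per gene plus alternative isoforms, each
    differing from the reference by exactly one planted splicing event.

    ``events`` optionally restricts/forces the planted types (cycled);
    by default all eight types are cycled in order.  Returns the catalog
    and a ground-truth table (gene_id, transcript_id, event).
    """
    rng = config.rng(salt=11)
    plan = list(events) if events else list(EVENT_TYPES)
    catalog = TranscriptCatalog()
    truth = []
    ev_idx = 0
    for gi in range(config.n_genes):
        gene_id = f"G{gi:05d}"
        strand = "+" if gi % 2 == 0 else "-"
        pos = 0
        exons = []
        for _ in range(_N_EXONS):
            elen = int(rng.integers(*_EXON_LEN))
            exons.append((pos, pos + elen))
            pos += elen + int(rng.integers(*_INTRON_LEN))
        n_iso = int(rng.integers(config.isoforms_per_gene[0],
                                 config.isoforms_per_gene[1] + 1))
        ref_id = f"{gene_id}.t1"
        catalog.add(Transcript(ref_id, gene_id, strand, list(exons),
                               cds=_assign_cds(exons, strand), chrom=gene_id))
        truth.append({"gene_id": gene_id, "transcript_id": ref_id, "event": "reference"})
        for k in range(2, n_iso + 1):
            event = plan[ev_idx % len(plan)]
            ev_idx += 1
            alt = [tuple(e) for e in _plant_event(exons, event, strand, gene_id)]
            tid = f"{gene_id}.t{k}"
            catalog.add(Transcript(tid, gene_id, strand, list(alt),
                                   cds=_assign_cds(alt, strand), chrom=gene_id))
            truth.append({"gene_id": gene_id, "transcript_id": tid, "event": event})
    return catalog, pd.DataFrame(truth)


# ---------------------------------------------------------------------------
# Count matrices
# ---------------------------------------------------------------------------

def _nb_sample(rng: np.random.Generator, mu: np.ndarray, phi: float) -> np.ndarray:
    """NB with variance mu + phi mu^2 via gamma-Poisson mixing."""
    shape = 1.0 / phi
    lam = rng.gamma(shape, mu * phi)
    return rng.poisson(lam)


def sample_sheet(config: SimConfig) -> pd.DataFrame:
    names = [f"y{i + 1}" for i in range(config.n_samples_per_group)] + [
        f"a{i + 1}" for i in range(config.n_samples_per_group)
    ]
    ages = [YOUNG] * config.n_samples_per_group + [AGED] * config.n_samples_per_group
    return pd.DataFrame({"age_group": ages, "cohort": "c1"},
                        index=pd.Index(names, name="sample_id"))


def simulate_count_matrices(
    catalog: TranscriptCatalog, config: SimConfig
) -> tuple[CountMatrix, CountMatrix, pd.DataFrame, pd.DataFrame]:
    """NB isoform counts around mu = baseline * 2^(loading*z + age + switch);
    gene counts are the sums of their isoforms' counts.

    Returns (gene matrix, isoform matrix, gene truth, switch truth).  Gene
    truth lists module membership and planted DE direction; switch truth
    lists the planted up/down isoform of each switching gene.
    """
    rng = config.rng(salt=23)
    sheet = sample_sheet(config)
    genes = catalog.genes()
    gene_ids = sorted(genes)
    n_mod_genes = config.n_modules * config.module_size
    if n_mod_genes > len(gene_ids):
        raise GenerationError("module plan exceeds the number of genes")
    module_of = {}
    age_lfc = {}
    for i, g in enumerate(gene_ids):
        if i < n_mod_genes:
            m = i // config.module_size + 1
            module_of[g] = f"M{m}"
            age_lfc[g] = config.module_effect * (1 if m % 2 == 1 else -1)
        else:
            module_of[g] = "M0"
            age_lfc[g] = 0.0

    multi = [g for g in gene_ids if len(genes[g]) >= 2]
    n_switch = int(round(config.switch_fraction * len(multi)))
    switch_genes = list(rng.choice(multi, size=n_switch, replace=False)) if n_switch else []
    switch_of: dict[str, tuple[str, str]] = {}
    for g in switch_genes:
        tids = sorted(t.transcript_id for t in genes[g])
        switch_of[g] = (tids[0], tids[1])  # planted aged-up, aged-down

    # whole-gene age effects on module-free, non-switching genes (the
    # bulk DE signal the expression stage is meant to recover)
    free = [g for g in gene_ids
            if module_of[g] == "M0" and g not in switch_of]
    n_de = int(round(config.de_fraction * len(free)))
    for i, g in enumerate(free[:n_de]):
        age_lfc[g] = config.de_lfc * (1 if i % 2 == 0 else -1)

    iso_ids = sorted(t.transcript_id for t in catalog)
    baseline = pd.Series(2 ** rng.normal(6.5, 0.8, size=len(iso_ids)), index=iso_ids)
    for g, (up, down) in switch_of.items():
        base = float(baseline[[up, down]].mean())
        baseline[up] = baseline[down] = base  # equal baselines: gene log2FC ~ 0

    is_aged = sheet["age_group"].eq(AGED).to_numpy()
    n_samples = len(sheet)
    # Module latent factors: orthogonalized across modules (so planted
    # blocks stay mutually uncorrelated at small sample counts) and against
    # the age contrast (latents model age-independent covariation; the age
    # effect enters only through the planted shifts).
    z = rng.normal(size=(config.n_modules + 1, n_samples))  # row 0 unused (M0)
    if config.n_modules + 1 < n_samples:
        age_vec = is_aged.astype(float) - is_aged.mean()
        basis = np.vstack([age_vec, z[1:] - z[1:].mean(axis=1, keepdims=True)])
        q, _ = np.linalg.qr(basis.T)
        z[1:] = q.T[1 : config.n_modules + 1] * np.sqrt(n_samples)
    z = z / z.std(axis=1, keepdims=True)

    iso_rows = []
    for tid in iso_ids:
        g = catalog.gene_of(tid)
        m = module_of[g]
        m_idx = int(m[1:]) if m != "M0" else 0
        log2mu = np.log2(baseline[tid]) * np.ones(n_samples)
        if m_idx:
            log2mu = log2mu + config.module_loading * z[m_idx]
        log2mu = log2mu + age_lfc[g] * is_aged
        if g in switch_of:
            up, down = switch_of[g]
            if tid == up:
                log2mu = log2mu + config.switch_lfc * is_aged
            elif tid == down:
                log2mu = log2mu - config.switch_lfc * is_aged
        iso_rows.append(_nb_sample(rng, 2.0 ** log2mu, config.nb_dispersion))
    iso_vals = pd.DataFrame(np.vstack(iso_rows), index=pd.Index(iso_ids, name="feature_id"),
                            columns=sheet.index)
    gene_index = pd.Index([catalog.gene_of(t) for t in iso_ids])
    gene_vals = iso_vals.groupby(gene_index).sum()
    gene_vals.index.name = "feature_id"

    gene_truth = pd.DataFrame({
        "gene_id": gene_ids,
        "module": [module_of[g] for g in gene_ids],
        "age_lfc": [age_lfc[g] for g in gene_ids],
        "de_direction": ["up" if age_lfc[g] > 0 else "down" if age_lfc[g] < 0 else "ns"
                         for g in gene_ids],
    }).set_index("gene_id")
    switch_truth = pd.DataFrame(
        [{"gene_id": g, "iso_up": u, "iso_down": d} for g, (u, d) in switch_of.items()]
    )
    return (
        CountMatrix(gene_vals.astype(float), sheet),
        CountMatrix(iso_vals.astype(float), sheet),
        gene_truth,
        switch_truth,
    )


# ---------------------------------------------------------------------------
# Premature / mature steady-state counts
# ---------------------------------------------------------------------------

def make_rate_table(
    n_genes: int,
    pt_fraction: float = 0.05,
    k3_factor: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-gene synthesis (k1), processing (k2) and degradation (k3) rates,
    with the aged-group k3 scaled by ``k3_factor`` for a planted fraction
    of PT-regulated genes (halving k3 doubles the aged PT ratio).

    Synthesis rates span ~1.5 decades; processing and degradation rates are
    lognormal with a modest spread, so the premature-mature relation across
    genes is tight enough for the population-calibrated null model to have
    useful resolution.
    """
    rng = np.random.default_rng(seed)
    k1 = 10 ** rng.uniform(0.5, 2.0, n_genes)
    k2 = 10 ** rng.normal(0.2, 0.055, n_genes)
    k3 = 10 ** rng.normal(-0.2, 0.055, n_genes)
    planted = np.zeros(n_genes, dtype=bool)
    planted[: int(round(pt_fraction * n_genes))] = True
    table = pd.DataFrame({
        "k1": k1, "k2": k2, "k3_young": k3,
        "k3_aged": np.where(planted, k3 * k3_factor, k3),
        "pt_regulated": planted,
    }, index=pd.Index([f"G{i:05d}" for i in range(n_genes)], name="gene_id"))
    if (table[["k1", "k2", "k3_young", "k3_aged"]] <= 0).any().any():
        raise GenerationError("all rates must be positive")
    return table


def simulate_premature_mature(
    rates: pd.DataFrame, depth: float, config: SimConfig
) -> tuple[CountMatrix, CountMatrix]:
    """Steady-state counts: premature ~ Poisson(depth * k1/k2), mature ~
    Poisson(depth * k1/k3) per sample, with the age-specific k3."""
    if depth <= 0:
        raise GenerationError("depth must be > 0")
    rng = config.rng(salt=37)
    sheet = sample_sheet(config)
    prem = {}
    mat = {}
    for sample, row in sheet.iterrows():
        k3 = rates["k3_aged"] if row["age_group"] == AGED else rates["k3_young"]
        prem[sample] = rng.poisson(depth * rates["k1"] / rates["k2"])
        mat[sample] = rng.poisson(depth * rates["k1"] / k3)
    prem_df = pd.DataFrame(prem, index=rates.index)
    mat_df = pd.DataFrame(mat, index=rates.index)
    return CountMatrix(prem_df.astype(float), sheet), CountMatrix(mat_df.astype(float), sheet)


# ---------------------------------------------------------------------------
# Sequences: controlled GC / GC3 and planted motifs
# ---------------------------------------------------------------------------

_IUPAC_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def random_sequence(length: int, gc_target: float, rng: np.random.Generator) -> str:
    """Per-base i.i.d. sequence, then deterministic flips to bring realized
    GC within +/-0.5% of the target."""
    gc = rng.random(length) < gc_target
    bases = np.where(gc, rng.choice(list("GC"), length), rng.choice(list("AT"), length))
    want = int(round(gc_target * length))
    have = int(gc.sum())
    idx = np.arange(length)
    if have > want:
        flip = rng.choice(idx[gc], size=have - want, replace=False)
        bases[flip] = rng.choice(list("AT"), size=len(flip))
    elif want > have:
        flip = rng.choice(idx[~gc], size=want - have, replace=False)
        bases[flip] = rng.choice(list("GC"), size=len(flip))
    return "".join(bases)


def _codon_block(n_codons: int, gc_target: float, gc3_target: float,
                 rng: np.random.Generator) -> str:
    """Internal codons (no start/stop) with controlled wobble GC."""
    out = []
    n_gc3 = int(round(gc3_target * n_codons))
    third_gc = np.zeros(n_codons, dtype=bool)
    third_gc[:n_gc3] = True
    rng.shuffle(third_gc)
    for i in range(n_codons):
        while True:
            b1 = rng.choice(list("GC")) if rng.random() < gc_target else rng.choice(list("AT"))
            b2 = rng.choice(list("GC")) if rng.random() < gc_target else rng.choice(list("AT"))
            b3 = rng.choice(list("GC")) if third_gc[i] else rng.choice(list("AT"))
            codon = b1 + b2 + b3
            if codon not in STOP_CODONS and codon != "ATG":
                out.append(codon)
                break
    return "".join(out)


def _adjust_gc(seq: str, positions: list[int], want_total: int,
               rng: np.random.Generator) -> str:
    """Flip bases at the given positions until the sequence's total GC count
    equals ``want_total`` (or the flippable positions are exhausted)."""
    chars = list(seq)
    have = sum(1 for c in chars if c in "GC")
    if have > want_total:
        pool = [i for i in positions if chars[i] in "GC"]
        rng.shuffle(pool)
        for i in pool[: have - want_total]:
            chars[i] = str(rng.choice(list("AT")))
    elif want_total > have:
        pool = [i for i in positions if chars[i] in "AT"]
        rng.shuffle(pool)
        for i in pool[: want_total - have]:
            chars[i] = str(rng.choice(list("GC")))
    return "".join(chars)


def _realize_motif(motif: str, rng: np.random.Generator) -> str:
    motif = motif.upper().replace("U", "T")
    return "".join(rng.choice(list(_IUPAC_SETS[c])) for c in motif)


def plant_motifs(
    sequence: str,
    motif: str,
    per_10kb: float,
    rng: np.random.Generator,
    max_tries: int = 200,
) -> tuple[str, int]:
    """Plant non-overlapping realizations of an IUPAC motif at the requested
    per-10-kb density and scrub chance occurrences elsewhere, so the
    realized count equals the planted count exactly.

    Raises when the density cannot be placed without overlap.
    """
    from .rbp_motifs import _motif_regex

    n = int(round(len(sequence) * per_10kb / 10_000))
    L, m = len(sequence), len(motif)
    if n * m > L:
        raise GenerationError(
            f"cannot place {n} non-overlapping {m}-mers in {L} nt"
        )
    seq = list(sequence)
    placed: list[int] = []
    for _ in range(n):
        for _try in range(max_tries):
            pos = int(rng.integers(0, L - m + 1))
            if all(pos + m <= q or q + m <= pos for q in placed):
                placed.append(pos)
                real = _realize_motif(motif, rng)
                seq[pos : pos + m] = list(real)
                break
        else:
            raise GenerationError("could not place motifs without overlap")
    pattern = _motif_regex(motif)
    protected = set()
    for q in placed:
        protected.update(range(q, q + m))
    for _pass in range(50):
        text = "".join(seq)
        extras = [mm.start() for mm in pattern.finditer(text) if mm.start() not in placed]
        if not extras:
            break
        for pos in extras:
            for off in range(m):
                j = pos + off
                if j in protected:
                    continue
                allowed = [b for b in "ACGT" if b not in _IUPAC_SETS[motif[off].upper()]]
                if allowed:
                    seq[j] = str(rng.choice(allowed))
                    break
    else:
        raise GenerationError("motif scrubbing did not converge")
    return "".join(seq), len(placed)


def synthesize_sequences(
    catalog: TranscriptCatalog,
    gc_target: float = 0.5,
    gc3_target: float = 0.5,
    motif_plan: dict[str, tuple[str, float]] | None = None,
    config: SimConfig | None = None,
    motif_region: str = "3UTR",
) -> tuple[dict[str, str], pd.DataFrame]:
    """Per-isoform cDNA honoring the catalog geometry: UTR bases at the GC
    target, CDS codons with wobble positions at the GC3 target (ATG start,
    stop chosen to respect GC3), and motifs planted in the 3'UTR (or the
    whole cDNA when no CDS exists) at the planned per-10-kb densities.

    Returns the sequences and a ground-truth table of planted motif counts
    and realized GC/GC3 per isoform.
    """
    if not (0 < gc_target < 1) or not (0 <= gc3_target <= 1):
        raise GenerationError("GC targets must lie in (0,1) / [0,1]")
    config = config or SimConfig()
    rng = config.rng(salt=53)
    sequences: dict[str, str] = {}
    rows = []
    for tx in sorted(catalog, key=lambda t: t.transcript_id):
        regions = tx.region_tx_intervals()
        L = tx.cdna_length
        if "CDS" in regions:
            a, b = regions["CDS"]
            n_codons = (b - a) // 3
            stop = ("TAG" if rng.random() < gc3_target else "TAA")
            body = _codon_block(max(n_codons - 2, 0), gc_target, gc3_target, rng)
            cds = ("ATG" + body + stop)[: b - a]
            utr5 = random_sequence(a, gc_target, rng)
            utr3 = random_sequence(L - b, gc_target, rng)
            seq = utr5 + cds + utr3
            # wobble bases follow gc3_target, so rebalance UTR bases to keep
            # the whole-cDNA GC on target
            utr_pos = list(range(a)) + list(range(b, L))
            seq = _adjust_gc(seq, utr_pos, int(round(gc_target * L)), rng)
        else:
            a = b = None
            seq = random_sequence(L, gc_target, rng)
        planted: dict[str, int] = {}
        if motif_plan:
            if motif_region == "3UTR" and b is not None:
                sub = seq[b:]
                for protein, (motif, dens) in motif_plan.items():
                    sub, n = plant_motifs(sub, motif, dens, rng)
                    planted[protein] = n
                seq = seq[:b] + sub
            else:
                for protein, (motif, dens) in motif_plan.items():
                    seq, n = plant_motifs(seq, motif, dens, rng)
                    planted[protein] = n
        sequences[tx.transcript_id] = seq
        from .isoform_features import gc3_content, gc_content

        row = {"transcript_id": tx.transcript_id,
               "realized_gc": gc_content(seq) / 100.0}
        if "CDS" in regions:
            row["realized_gc3"] = gc3_content(seq[a:b]) / 100.0
        for protein, n in planted.items():
            row[f"planted_{protein}"] = n
        rows.append(row)
    return sequences, pd.DataFrame(rows).set_index("transcript_id")
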