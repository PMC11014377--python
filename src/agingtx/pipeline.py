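"""Orchestration of the analysis graph on a file bundle.

Stage order: normalize -> de -> modules -> isoforms -> splicing -> motifs
-> dynamics -> context.  Every stage writes TSVs into its own directory
under the run's output directory and nothing mutates another stage's
outputs; a JSON manifest records the seed, thresholds, package version and
checksums of all written files, so a rerun with the same configuration and
inputs is reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core_io import (
    AGED,
    YOUNG,
    CountMatrix,
    normalize_pipeline,
    count_isoforms_detected,
    read_counts,
    read_fasta,
    read_gtf,
    write_counts,
    write_fasta,
    write_gtf,
    write_sample_sheet,
)
from .coexpr import ModuleConfig, module_overlap, run_wgcna_like
from .diffexpr import differential_expression, gene_set_shift_test
from .isoform_features import (
    contrast_all_regions,
    find_bidirectional_genes,
    length_expression_correlation,
    transcript_region_features,
)
from .rbp_motifs import binding_profiles, group_contrast, parse_motif_table
from .rna_dynamics import compare_pt_distributions, compute_pt, fit_null_and_call
from .splicing import (
    assess_consequences,
    classify_switch_events,
    compute_isoform_fractions,
    consequence_summary,
    dtu_test,
    event_fraction_test,
    find_switch_pairs,
    module_relative_isoform_ratio,
)
from .synthetic_data import (
    SimConfig,
    generate_transcript_catalog,
    make_rate_table,
    simulate_count_matrices,
    simulate_premature_mature,
    synthesize_sequences,
)

log = logging.getLogger("agingtx")

STAGES = ("normalize", "de", "modules", "isoforms", "splicing", "motifs",
          "dynamics", "context")
DEPENDENCIES = {
    "normalize": (),
    "de": ("normalize",),
    "modules": ("normalize",),
    "isoforms": ("de",),
    "splicing": ("de", "modules"),
    "motifs": ("de",),
    "dynamics": (),
    "context": ("de",),
}

DEFAULT_MOTIF_PLAN = {"RBP1": ("TGCATG", 2.0), "RBP2": ("YGCY", 3.0)}


class ConfigError(ValueError):
    pass


class DataError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """Paths, stage toggles, thresholds and the seed for one run."""

    outdir: str = "agingtx_run"
    bundle_dir: str | None = None      # existing input bundle; None -> simulate
    stages: dict[str, bool] = field(default_factory=lambda: {s: True for s in STAGES})
    # thresholds
    alpha: float = 0.05
    tau: float = 0.58
    low_count_threshold: float = 5.0
    isoform_detect_cutoff: float = 2.0
    gene_cutoff: float = 5.0
    iso_cutoff: float = 3.0
    beta: float = 6.0                  # desk-scale network preset
    min_module_size: int = 20
    cut_height: float = 0.85
    seed: int = 0
    sim: SimConfig = field(default_factory=SimConfig)

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ConfigError(f"unknown stages: {sorted(unknown)}")
        for s in STAGES:
            self.stages.setdefault(s, True)
        for s, on in self.stages.items():
            if on:
                missing = [d for d in DEPENDENCIES[s] if not self.stages.get(d)]
                if missing:
                    raise ConfigError(
                        f"stage {s!r} requires disabled stage(s) {missing}"
                    )


BUNDLE_FILES = {
    "gene_counts": "gene_counts.tsv",
    "isoform_counts": "isoform_counts.tsv",
    "sample_sheet": "sample_sheet.tsv",
    "catalog": "catalog.gtf",
    "sequences": "sequences.fa",
    "motifs": "motifs.tsv",
    "premature": "premature_counts.tsv",
    "mature": "mature_counts.tsv",
}


def simulate_bundle(config: PipelineConfig, outdir: Path) -> Path:
    """Generate the full synthetic input bundle and write it as plain-text
    files (TSV counts, GTF catalog, FASTA sequences, TSV motif table)."""
    outdir.mkdir(parents=True, exist_ok=True)
    sim = config.sim
    catalog, event_truth = generate_transcript_catalog(sim)
    gene_m, iso_m, gene_truth, switch_truth = simulate_count_matrices(catalog, sim)
    sequences, seq_truth = synthesize_sequences(
        catalog, motif_plan=DEFAULT_MOTIF_PLAN, config=sim
    )
    rates = make_rate_table(sim.n_genes, seed=sim.seed)
    prem, mat = simulate_premature_mature(rates, depth=1e4, config=sim)

    write_counts(gene_m, outdir / BUNDLE_FILES["gene_counts"])
    write_counts(iso_m, outdir / BUNDLE_FILES["isoform_counts"])
    write_sample_sheet(gene_m.samples, outdir / BUNDLE_FILES["sample_sheet"])
    write_gtf(catalog, outdir / BUNDLE_FILES["catalog"])
    write_fasta(sequences, outdir / BUNDLE_FILES["sequences"])
    pd.DataFrame(
        [(p, m) for p, (m, _d) in DEFAULT_MOTIF_PLAN.items()],
        columns=["protein", "motif"],
    ).to_csv(outdir / BUNDLE_FILES["motifs"], sep="\t", index=False)
    write_counts(prem, outdir / BUNDLE_FILES["premature"])
    write_counts(mat, outdir / BUNDLE_FILES["mature"])
    event_truth.to_csv(outdir / "truth_events.tsv", sep="\t", index=False)
    gene_truth.to_csv(outdir / "truth_genes.tsv", sep="\t")
    switch_truth.to_csv(outdir / "truth_switches.tsv", sep="\t", index=False)
    rates.to_csv(outdir / "truth_rates.tsv", sep="\t")
    return outdir


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in dependency order and return a result
    bundle (in-memory objects keyed by stage) alongside the written files."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if config.bundle_dir is None:
        bundle = simulate_bundle(config, outdir / "bundle")
    else:
        bundle = Path(config.bundle_dir)
        missing = [f for f in BUNDLE_FILES.values() if not (bundle / f).exists()]
        if missing:
            raise DataError(f"bundle {bundle} is missing {missing}")

    sheet_path = bundle / BUNDLE_FILES["sample_sheet"]
    gene_raw = read_counts(bundle / BUNDLE_FILES["gene_counts"], sheet_path)
    iso_raw = read_counts(bundle / BUNDLE_FILES["isoform_counts"], sheet_path)
    catalog = read_gtf(bundle / BUNDLE_FILES["catalog"])
    sequences = read_fasta(bundle / BUNDLE_FILES["sequences"])

    results: dict = {"bundle_dir": str(bundle)}
    written: list[Path] = []

    def emit(stage: str, name: str, df: pd.DataFrame, index=True) -> None:
        d = outdir / stage
        d.mkdir(exist_ok=True)
        p = d / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=index)
        written.append(p)

    # --- normalize ---------------------------------------------------------
    if config.stages["normalize"]:
        log.info("normalize: low-count filter <=%s, quantile, row-median",
                 config.low_count_threshold)
        from .core_io import filter_low_counts, quantile_normalize, row_median_center

        gene_qn = quantile_normalize(
            filter_low_counts(gene_raw, threshold=config.low_count_threshold)[0]
        )
        iso_qn = quantile_normalize(
            filter_low_counts(iso_raw, threshold=config.low_count_threshold)[0]
        )
        # row-median centering rescales each gene to its own median: the
        # right input for the network stage, while expression-scale stages
        # (DE, usage filters) consume the quantile-normalized matrix
        gene_centered, _ = row_median_center(gene_qn)
        iso_centered, _ = row_median_center(iso_qn)
        detect = count_isoforms_detected(iso_qn, cutoff=config.isoform_detect_cutoff)
        results["normalize"] = {"gene": gene_qn, "isoform": iso_qn,
                                "gene_centered": gene_centered,
                                "isoform_centered": iso_centered,
                                "isoforms_detected": detect}
        emit("normalize", "gene_normalized", gene_centered.values)
        emit("normalize", "isoform_normalized", iso_centered.values)
        emit("normalize", "isoforms_detected",
             pd.DataFrame([detect]), index=False)

    # --- differential expression ------------------------------------------
    if config.stages["de"]:
        gene_norm = results["normalize"]["gene"]
        iso_norm = results["normalize"]["isoform"]
        log.info("de: alpha=%s tau=%s", config.alpha, config.tau)
        de_gene = differential_expression(gene_norm, config.alpha, config.tau)
        de_iso = differential_expression(iso_norm, config.alpha, config.tau)
        results["de"] = {"gene": de_gene, "isoform": de_iso}
        emit("de", "de_genes", de_gene)
        emit("de", "de_isoforms", de_iso)

    # --- co-expression modules --------------------------------------------
    if config.stages["modules"]:
        gene_centered = results["normalize"]["gene_centered"]
        mc = ModuleConfig(beta=config.beta, min_size=config.min_module_size,
                          cut_height=config.cut_height)
        log.info("modules: beta=%s min_size=%s cut_height=%s",
                 mc.beta, mc.min_size, mc.cut_height)
        logged = gene_centered.with_values(np.log2(gene_centered.values + 1.0))
        sd = logged.values.std(axis=1)
        logged = logged.with_values(logged.values.loc[sd > 0])
        assignment = run_wgcna_like(logged, mc)
        results["modules"] = assignment
        emit("modules", "module_labels", assignment.labels.to_frame())
        emit("modules", "eigengenes", assignment.eigengenes)
        if not assignment.direction.empty:
            emit("modules", "module_direction", assignment.direction)

    # --- isoform sequence features ----------------------------------------
    if config.stages["isoforms"]:
        de_iso = results["de"]["isoform"]
        features = transcript_region_features(catalog, sequences)
        contrasts = find_bidirectional_genes(de_iso, catalog)
        results["isoforms"] = {"features": features, "bidirectional": contrasts}
        emit("isoforms", "region_features", features)
        for kind in ("len", "gc"):
            table = contrast_all_regions(contrasts, features, kind)
            if not table.empty:
                emit("isoforms", f"contrast_{kind}", table, index=False)
                results["isoforms"][f"contrast_{kind}"] = table
        lengths = features["len_cDNA"].groupby(features["gene_id"]).mean()
        de_gene = results["de"]["gene"]
        assignment = results.get("modules")
        corr = length_expression_correlation(de_gene, lengths, assignment)
        results["isoforms"]["length_expression"] = corr
        emit("isoforms", "length_expression_correlation", corr, index=False)

    # --- splicing -----------------------------------------------------------
    if config.stages["splicing"]:
        # usage cutoffs are expression-scale rules, so they act on raw counts
        ift = compute_isoform_fractions(
            gene_raw, iso_raw, catalog,
            gene_cutoff=config.gene_cutoff, iso_cutoff=config.iso_cutoff,
        )
        dtu = dtu_test(ift, alpha=config.alpha)
        switches = find_switch_pairs(dtu, alpha=config.alpha)
        events = classify_switch_events(switches, catalog)
        fractions = event_fraction_test(events)
        assessed = assess_consequences(switches, catalog, sequences, events)
        cons = consequence_summary(assessed)
        results["splicing"] = {
            "ift": ift, "dtu": dtu, "switches": switches, "events": events,
            "event_fractions": fractions, "consequences": assessed,
            "consequence_summary": cons,
        }
        emit("splicing", "dtu", dtu)
        if not fractions.empty:
            emit("splicing", "event_fractions", fractions)
        if not assessed.empty:
            emit("splicing", "consequences", assessed, index=False)
        if not cons.empty:
            emit("splicing", "consequence_summary", cons)
        assignment = results.get("modules")
        if assignment is not None and not assignment.direction.empty and events:
            per_gene, tests, n_excl = module_relative_isoform_ratio(
                results["de"]["isoform"], events, assignment
            )
            results["splicing"]["module_ratio"] = per_gene
            if not per_gene.empty:
                emit("splicing", "module_relative_ratio", per_gene, index=False)

    # --- RBP motifs ---------------------------------------------------------
    if config.stages["motifs"]:
        motif_table = parse_motif_table(bundle / BUNDLE_FILES["motifs"])
        utr3 = {}
        for tx in catalog:
            regions = tx.region_tx_intervals()
            if "3UTR" in regions:
                a, b = regions["3UTR"]
                utr3[tx.transcript_id] = sequences[tx.transcript_id][a:b]
        profiles = binding_profiles(utr3, motif_table)
        contrast = group_contrast(profiles, results["de"]["isoform"])
        results["motifs"] = {"profiles": profiles, "contrast": contrast}
        emit("motifs", "binding_profiles", profiles)
        emit("motifs", "group_contrast", contrast)

    # --- RNA dynamics -------------------------------------------------------
    if config.stages["dynamics"]:
        prem = read_counts(bundle / BUNDLE_FILES["premature"], sheet_path)
        mat = read_counts(bundle / BUNDLE_FILES["mature"], sheet_path)
        pt = compute_pt(prem, mat)
        comparison = compare_pt_distributions(pt)
        fit, calls = fit_null_and_call(pt, alpha=config.alpha)
        results["dynamics"] = {"pt": pt, "comparison": comparison,
                               "fit": fit, "calls": calls}
        emit("dynamics", "pt_ratio", pt.pt)
        emit("dynamics", "pt_comparison", pd.DataFrame([comparison]), index=False)
        emit("dynamics", "pt_calls", calls)

    # --- cohort context -----------------------------------------------------
    if config.stages["context"]:
        de_gene = results["de"]["gene"]
        sig = list(de_gene.index[de_gene["direction"] != "ns"])
        up = list(de_gene.index[de_gene["direction"] == "up"])
        from .cohorts_context import ora_test

        sets = {"upregulated": up,
                "downregulated": list(de_gene.index[de_gene["direction"] == "down"])}
        ora = ora_test(sig, list(de_gene.index), sets) if sig else pd.DataFrame()
        results["context"] = {"ora": ora}
        if not ora.empty:
            emit("context", "ora", ora)

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "thresholds": {
            k: v for k, v in asdict(config).items()
            if isinstance(v, (int, float, str)) and k not in ("outdir", "bundle_dir")
        },
        "stages": {s: bool(config.stages[s]) for s in STAGES},
        "inputs": {k: _sha256(bundle / f) for k, f in BUNDLE_FILES.items()
                   if (bundle / f).exists()},
        "outputs": {str(p.relative_to(outdir)): _sha256(p) for p in written},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    results["manifest"] = manifest
    return results
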