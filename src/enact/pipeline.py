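"""End-to-end pipeline orchestration with a validated config and manifest.

Stages run in dependency order::

    simulate -> call-enhancers -> quantify -> diffactivity
             -> fragqc -> motifdev -> aggregate

Each stage writes its outputs into the run directory; a provenance
manifest records the package version, the normalized parameters, the
seed and SHA-256 checksums of every stage output, so a rerun with an
identical config is byte-identical and verifiably so.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from . import __version__
from .core_io import (
    GenomicInterval,
    read_cell_labels,
    read_fragments,
    write_bedgraph,
    write_cell_labels,
    write_count_matrix,
    write_fragments,
    write_gene_table,
    write_intervals,
    CountMatrix,
)
from . import synthetic
from .enhancer_calling import call_enhancers
from .activity_stats import (
    filter_low_expression,
    kmeans_profiles,
    lrt_any_change,
    nbql_test,
    quantify_regions,
    rle_size_factors,
)
from .fragment_qc import metrics_frame, per_cell_metrics, qc_filter
from .motif_activity import (
    build_peak_matrix,
    cluster_specific_motifs,
    motif_deviation_scores,
)
from .aggregate_signal import (
    average_profile,
    pseudobulk_insertion_coverage,
    signal_matrix,
    state_specific_regions,
)

logger = logging.getLogger("enact")

# ---------------------------------------------------------------------------
# config schema: {key: (type, default)}; nested dicts are stage blocks
# ---------------------------------------------------------------------------

CONFIG_SCHEMA: dict[str, Any] = {
    "seed": (int, 7),
    "log_level": (str, "INFO"),
    "simulate": {
        "n_chroms": (int, 2),
        "chrom_length": (int, 2_000_000),
        "n_genes": (int, 60),
        "n_enhancers": (int, 120),
        "n_peaks": (int, 80),
        "n_replicates": (int, 3),
        "depth": (float, 1.0),
        "n_cells_per_cluster": (int, 60),
        "fragments_per_cell": (int, 3000),
    },
    "inputs": {
        # optional explicit inputs; empty string means "use simulated data"
        "fragments": (str, ""),
        "labels": (str, ""),
    },
    "enhancers": {
        "flank": (int, 500),
        "min_cpm": (float, 1.0),
        "cluster_gap": (int, 500),
        "max_peak_width": (int, 7500),
        "dip_threshold": (float, 0.5),
        "smooth_bw": (int, 50),
    },
    "quantify": {
        "gene_cap": (int, 3),
    },
    "diffactivity": {
        "enhancer_cutoff": (float, 5.0),
        "enhancer_min_samples": (int, 2),
        "enhancer_fdr": (float, 0.1),
        "gene_cutoff": (float, 0.5),
        "gene_min_samples": (int, 2),
        "gene_fdr": (float, 0.001),
        "kmeans_k": (int, 6),
    },
    "fragqc": {
        "min_fragments_in_peaks": (float, 1000.0),
        "max_fragments_in_peaks": (float, 100_000.0),
        "min_pct_reads_in_peaks": (float, 15.0),
        "max_blacklist_ratio": (float, 0.05),
        "max_nucleosome_signal": (float, 10.0),
        "min_tss_enrichment": (float, 2.0),
    },
    "motifdev": {
        "B": (int, 50),
        "effect_threshold": (float, 1.5),
        "fdr": (float, 1e-4),
    },
    "aggregate": {
        "min_fc": (float, 0.1),
        "fdr": (float, 0.1),
        "top_n": (int, 200),
        "flank": (int, 1000),
        "bin_size": (int, 25),
    },
}


class ConfigError(ValueError):
    """Raised with an exhaustive list of config problems."""


def validate_config(source: str | Path | Mapping[str, Any] | None) -> dict[str, Any]:
    """Normalize a YAML config file (or mapping) against the schema.

    Unknown keys are rejected and type mismatches are reported all at
    once; missing keys receive defaults.  An empty file yields the
    all-defaults config.
    """
    if source is None:
        raw: dict[str, Any] = {}
    elif isinstance(source, (str, Path)):
        text = Path(source).read_text()
        raw = yaml.safe_load(text) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    else:
        raw = dict(source)

    errors: list[str] = []

    def walk(schema: Mapping[str, Any], given: Mapping[str, Any], prefix: str) -> dict:
        out: dict[str, Any] = {}
        for key in given:
            if key not in schema:
                errors.append(f"unknown key {prefix}{key}")
        for key, spec in schema.items():
            path = f"{prefix}{key}"
            if isinstance(spec, dict):
                sub = given.get(key, {})
                if not isinstance(sub, Mapping):
                    errors.append(f"{path}: expected a mapping")
                    sub = {}
                out[key] = walk(spec, sub, path + ".")
            else:
                typ, default = spec
                if key in given:
                    val = given[key]
                    if typ is float and isinstance(val, int) and not isinstance(val, bool):
                        val = float(val)
                    if not isinstance(val, typ) or isinstance(val, bool):
                        errors.append(
                            f"{path}: expected {typ.__name__}, got {type(val).__name__}"
                        )
                        val = default
                    out[key] = val
                else:
                    out[key] = default
        return out

    cfg = walk(CONFIG_SCHEMA, raw, "")
    if errors:
        raise ConfigError("; ".join(errors))
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def run_pipeline(config: Mapping[str, Any] | str | Path | None, out_dir: str | Path) -> Path:
    """Run all stages on synthetic (or supplied) data; returns the run dir."""
    cfg = validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=cfg["log_level"])
    seed = cfg["seed"]
    manifest: dict[str, Any] = {
        "package": "enact",
        "version": __version__,
        "config": copy.deepcopy(cfg),
        "outputs": {},
    }
    (out / "config.normalized.yaml").write_text(yaml.safe_dump(cfg, sort_keys=True))

    def record(name: str, path: Path) -> None:
        manifest["outputs"][name] = {
            "path": path.name,
            "sha256": _sha256(path),
        }

    # ------------------------------------------------------------------ simulate
    logger.info("[simulate] generating locus set and assays")
    sim = cfg["simulate"]
    truth = synthetic.simulate_locus_set(
        seed=seed,
        n_chroms=sim["n_chroms"],
        chrom_length=sim["chrom_length"],
        n_genes=sim["n_genes"],
        n_enhancers=sim["n_enhancers"],
        n_peaks=sim["n_peaks"],
    )
    write_intervals(truth.peaks, out / "peaks.bed")
    write_intervals(truth.histone_peaks, out / "histone_peaks.bed")
    write_intervals(truth.blacklist, out / "blacklist.bed")
    write_intervals(synthetic.motif_sites(truth), out / "motif_sites.bed")
    write_gene_table([g.model for g in truth.genes], out / "genes.tsv")

    samples: list[str] = []
    design: list[str] = []
    coverages = {}
    for cond in truth.conditions:
        for rep in range(sim["n_replicates"]):
            name = f"{cond}_{rep + 1}"
            cov = synthetic.simulate_nascent_coverage(
                truth, cond, depth=sim["depth"],
                seed=seed + 1000 + 100 * len(samples),
            )
            coverages[name] = cov
            samples.append(name)
            design.append(cond)
            write_bedgraph(cov.plus, out / f"coverage_{name}_plus.bedgraph")
            write_bedgraph(cov.minus, out / f"coverage_{name}_minus.bedgraph")
    histone_signal = synthetic.simulate_histone_coverage(truth, seed=seed + 5)
    write_bedgraph(histone_signal, out / "histone_signal.bedgraph")

    if cfg["inputs"]["fragments"]:
        frag_path = Path(cfg["inputs"]["fragments"])
        if not frag_path.exists():
            raise StageError("fragqc", f"fragments file not found: {frag_path}")
        fragments = list(read_fragments(frag_path))
        labels = read_cell_labels(cfg["inputs"]["labels"])
    else:
        fragments, labels = synthetic.simulate_fragments(
            truth,
            n_cells_per_cluster=sim["n_cells_per_cluster"],
            fragments_per_cell=sim["fragments_per_cell"],
            seed=seed + 9,
        )
        write_fragments(fragments, out / "fragments.tsv")
        write_cell_labels(labels, out / "labels.tsv")
    truth.to_json(out / "truth.json")
    for f in ("peaks.bed", "histone_peaks.bed", "blacklist.bed", "motif_sites.bed",
              "genes.tsv", "truth.json"):
        record(f, out / f)

    # ------------------------------------------------------- call-enhancers
    logger.info("[call-enhancers] defining and filtering candidates")
    enh_cfg = cfg["enhancers"]
    pooled = synthetic.StrandedCoverage(
        plus={
            c: np.sum([coverages[s].plus[c] for s in samples], axis=0)
            for c in truth.chrom_lengths
        },
        minus={
            c: np.sum([coverages[s].minus[c] for s in samples], axis=0)
            for c in truth.chrom_lengths
        },
        chrom_lengths=dict(truth.chrom_lengths),
    )
    genes = [g.model for g in truth.genes]
    candidates, dips = call_enhancers(
        truth.peaks,
        genes,
        pooled,
        histone_peaks=truth.histone_peaks,
        histone_signal=histone_signal,
        flank=enh_cfg["flank"],
        min_cpm=enh_cfg["min_cpm"],
        cluster_gap=enh_cfg["cluster_gap"],
        max_peak_width=enh_cfg["max_peak_width"],
        dip_threshold=enh_cfg["dip_threshold"],
        smooth_bw=enh_cfg["smooth_bw"],
    )
    import pandas as pd

    cand_df = pd.DataFrame(
        {
            "id": [c.id for c in candidates],
            "chrom": [c.chrom for c in candidates],
            "start": [c.region.start for c in candidates],
            "end": [c.region.end for c in candidates],
            "plus_count": [c.plus_count for c in candidates],
            "minus_count": [c.minus_count for c in candidates],
            "balance_ratio": [c.balance_ratio for c in candidates],
            "effective_count": [c.effective_count for c in candidates],
            "passed_cpm": [c.evidence["passed_cpm"] for c in candidates],
            "histone_overlap": [c.evidence["histone_overlap"] for c in candidates],
            "status": [c.status for c in candidates],
        }
    )
    cand_df.to_csv(out / "enhancers.tsv", sep="\t", index=False)
    kept = [c for c in candidates if c.kept]
    write_intervals([c.region for c in kept], out / "enhancers_kept.bed")
    record("enhancers.tsv", out / "enhancers.tsv")
    record("enhancers_kept.bed", out / "enhancers_kept.bed")
    if not kept:
        raise StageError("call-enhancers", "no enhancers kept")

    # ------------------------------------------------------------- quantify
    logger.info("[quantify] counting enhancer and gene signal per sample")
    enh_regions = [c.region for c in kept]
    enh_counts = np.column_stack(
        [
            quantify_regions(coverages[s], enh_regions, strand_mode="effective")
            for s in samples
        ]
    )
    enh_matrix = CountMatrix(
        feature_ids=[c.id for c in kept],
        sample_ids=samples,
        counts=np.rint(enh_counts),
        feature_lengths=np.array([r.width for r in enh_regions], dtype=float),
    )
    exon_mask = {g.model.body.name: list(g.model.exons) for g in truth.genes}
    gene_counts = np.column_stack(
        [
            quantify_regions(
                coverages[s],
                [g.model.body for g in truth.genes],
                per_position_cap=cfg["quantify"]["gene_cap"],
                exon_mask=exon_mask,
                strand_mode="sense",
            )
            for s in samples
        ]
    )
    gene_matrix = CountMatrix(
        feature_ids=[g.model.body.name for g in truth.genes],
        sample_ids=samples,
        counts=np.rint(gene_counts),
    )
    write_count_matrix(enh_matrix, out / "enhancer_counts.tsv")
    write_count_matrix(gene_matrix, out / "gene_counts.tsv")
    record("enhancer_counts.tsv", out / "enhancer_counts.tsv")
    record("gene_counts.tsv", out / "gene_counts.tsv")

    # --------------------------------------------------------- diffactivity
    logger.info("[diffactivity] differential enhancer and gene activity")
    da = cfg["diffactivity"]
    enh_f = filter_low_expression(
        enh_matrix, da["enhancer_cutoff"], da["enhancer_min_samples"], unit="raw"
    )
    sf = rle_size_factors(enh_f)
    enh_res = nbql_test(enh_f, design, size_factors=sf)
    enh_res.to_csv(out / "diff_enhancers.tsv", sep="\t", index=False)
    gene_f = filter_low_expression(
        gene_matrix, da["gene_cutoff"], da["gene_min_samples"], unit="cpm"
    )
    gene_res = lrt_any_change(gene_f, design, size_factors=rle_size_factors(gene_f))
    sig = gene_res[gene_res["qvalue"] < da["gene_fdr"]]
    cpm = gene_f.cpm()
    sig_idx = [gene_f.feature_ids.index(f) for f in sig["feature"]]
    if sig_idx:
        profiles = np.log1p(cpm[sig_idx])
        z = (profiles - profiles.mean(axis=1, keepdims=True)) / np.maximum(
            profiles.std(axis=1, keepdims=True), 1e-9
        )
        k = min(da["kmeans_k"], len(sig_idx))
        clusters = kmeans_profiles(z, k=k, seed=seed)
        sig = sig.assign(cluster=clusters)
    sig.to_csv(out / "diff_genes_significant.tsv", sep="\t", index=False)
    gene_res.to_csv(out / "diff_genes.tsv", sep="\t", index=False)
    record("diff_enhancers.tsv", out / "diff_enhancers.tsv")
    record("diff_genes.tsv", out / "diff_genes.tsv")

    # --------------------------------------------------------------- fragqc
    logger.info("[fragqc] per-cell fragment QC")
    tss = [(g.model.body.chrom, g.model.tss) for g in truth.genes]
    metrics = per_cell_metrics(fragments, truth.peaks, truth.blacklist, tss)
    mdf = metrics_frame(metrics)
    mdf.to_csv(out / "cell_metrics.tsv", sep="\t", index=False)
    kept_cells = qc_filter(metrics, cfg["fragqc"])
    (out / "cells_kept.txt").write_text("\n".join(kept_cells) + "\n")
    record("cell_metrics.tsv", out / "cell_metrics.tsv")
    record("cells_kept.txt", out / "cells_kept.txt")
    if not kept_cells:
        raise StageError("fragqc", "no cells passed QC")

    # -------------------------------------------------------------- motifdev
    logger.info("[motifdev] per-cell motif deviations")
    md = cfg["motifdev"]
    pcm = build_peak_matrix(fragments, truth.peaks, kept_cells)
    motif_map = {
        m: [nm for nm in names if nm in set(pcm.peak_names)]
        for m, names in truth.motif_assignments.items()
    }
    motif_map = {m: v for m, v in motif_map.items() if v}
    dev = motif_deviation_scores(pcm, motif_map, B=md["B"], seed=seed + 21)
    dev.to_frame().to_csv(out / "motif_deviations.tsv", sep="\t", index_label="motif")
    cluster_motifs = cluster_specific_motifs(
        dev,
        {bc: labels.labels[bc] for bc in dev.barcodes if bc in labels.labels},
        effect_threshold=md["effect_threshold"],
        fdr=md["fdr"],
    )
    cluster_motifs.to_csv(out / "cluster_motifs.tsv", sep="\t", index=False)
    record("motif_deviations.tsv", out / "motif_deviations.tsv")
    record("cluster_motifs.tsv", out / "cluster_motifs.tsv")

    # -------------------------------------------------------------- aggregate
    logger.info("[aggregate] state-specific regions and signal matrices")
    ag = cfg["aggregate"]
    kept_set = set(kept_cells)
    lab_kept = {bc: labels.labels[bc] for bc in kept_cells if bc in labels.labels}
    region_counts = _region_cell_counts(fragments, enh_regions, kept_cells)
    states = state_specific_regions(
        region_counts,
        [r.name for r in enh_regions],
        [lab_kept[bc] for bc in kept_cells],
        min_fc=ag["min_fc"],
        fdr=ag["fdr"],
        top_n=ag["top_n"],
    )
    states.to_csv(out / "state_specific_regions.tsv", sep="\t", index=False)
    pseudo = pseudobulk_insertion_coverage(fragments, lab_kept, truth.chrom_lengths)
    top = states[states["top_hit"]]
    top_regions = [r for r in enh_regions if r.name in set(top["region"])]
    profiles = {}
    for state, track in sorted(pseudo.items()):
        mat = signal_matrix(
            track,
            top_regions or enh_regions,
            flank=ag["flank"],
            bin_size=ag["bin_size"],
        )
        mat.to_frame().to_csv(out / f"signal_matrix_{state}.tsv", sep="\t")
        prof = average_profile(mat)
        if prof:
            profiles[state] = prof["all"]
    pd.DataFrame(profiles).to_csv(out / "average_profiles.tsv", sep="\t", index=False)
    record("state_specific_regions.tsv", out / "state_specific_regions.tsv")
    record("average_profiles.tsv", out / "average_profiles.tsv")

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    logger.info("pipeline complete: %s", out)
    return out


def _region_cell_counts(
    fragments, regions: list[GenomicInterval], barcodes: list[str]
) -> np.ndarray:
    """Insertion counts per region per barcode (regions x cells)."""
    from intervaltree import IntervalTree

    bc_index = {bc: i for i, bc in enumerate(barcodes)}
    trees: dict[str, IntervalTree] = {}
    for i, r in enumerate(regions):
        trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end, i)
    counts = np.zeros((len(regions), len(barcodes)))
    for frag in fragments:
        ci = bc_index.get(frag.barcode)
        if ci is None:
            continue
        tree = trees.get(frag.chrom)
        if tree is None:
            continue
        for insertion in (frag.start, frag.end - 1):
            for hit in tree.at(insertion):
                counts[hit.data, ci] += frag.count
    return counts
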