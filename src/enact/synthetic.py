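"""Seeded synthetic-data generators with planted ground truth.

The generators emulate the statistical structure of the assays the
pipeline consumes:

* a toy genome with genes (stranded, exon structure), intergenic
  enhancers, accessibility peaks (real + decoy), broad histone peaks with
  a central nucleosome-free dip, and blacklist regions;
* strand-specific nascent-transcription coverage in which genes transcribe
  on their sense strand, enhancers emit short bidirectional eRNA
  (balanced ~50/50, with a configurable minority of strongly imbalanced
  loci), and condition-specific fold changes are planted;
* per-cell fragment files whose length distribution is a two-component
  mixture (sub-nucleosomal vs mononucleosomal) with a per-cell mixture
  weight, so that condensed, mitotic-like cells carry an elevated
  nucleosome signal; accessibility in motif-bearing peaks is scaled by a
  per-cell motif-activity multiplier.

Every generator takes an explicit seed and is deterministic for a given
seed.  Defaults are sized so that the full toy data set generates in
seconds: 2 chromosomes x 2 Mb, 60 genes, 120 enhancers, 80 decoy peaks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .core_io import (
    CellLabelTable,
    FragmentRecord,
    GeneModel,
    GenomicInterval,
    StrandedCoverage,
)

CONDITIONS = ("DMSO", "AZD")

#: fragment-length mixture: sub-nucleosomal vs mononucleosomal component
SUBNUC_MEAN, SUBNUC_SD = 75.0, 25.0
MONO_MEAN, MONO_SD = 200.0, 30.0
SUBNUC_RANGE = (10, 146)   # truncated below the 147 bp nucleosome bound
MONO_RANGE = (147, 294)    # the mononucleosome bin


@dataclass
class EnhancerTruth:
    id: str
    chrom: str
    center: int
    rates: dict[str, float]          # condition -> expected eRNA counts (depth 1)
    balanced: bool
    plus_fraction: float             # share of eRNA on the plus strand
    has_histone: bool
    histone_width: int


@dataclass
class GeneTruth:
    model: GeneModel
    rates: dict[str, float]          # condition -> expected per-bp sense rate


@dataclass
class SyntheticTruth:
    """Planted ground truth for one simulated locus set."""

    chrom_lengths: dict[str, int]
    conditions: tuple[str, ...]
    enhancers: list[EnhancerTruth]
    genes: list[GeneTruth]
    peaks: list[GenomicInterval]             # accessibility peaks; score = GC
    blacklist: list[GenomicInterval]
    histone_peaks: list[GenomicInterval]
    differential_features: dict[str, float]  # feature id -> fold change (AZD/DMSO)
    motif_assignments: dict[str, list[str]]  # motif id -> peak names
    active_motif: str
    cluster_templates: dict[str, tuple[float, float]]  # cluster -> (mono_frac, motif_mult)
    cell_phenotypes: dict[str, tuple[str, float, float]] = field(default_factory=dict)

    @property
    def enhancer_peak_names(self) -> set[str]:
        return {p.name for p in self.peaks if p.name.startswith("enh_")}

    @property
    def decoy_peak_names(self) -> set[str]:
        return {p.name for p in self.peaks if p.name.startswith("decoy_")}

    def balanced_enhancer_names(self) -> set[str]:
        return {e.id for e in self.enhancers if e.balanced}

    def to_json(self, path: str | Path) -> None:
        doc = {
            "chrom_lengths": self.chrom_lengths,
            "conditions": list(self.conditions),
            "enhancers": [asdict(e) for e in self.enhancers],
            "genes": [
                {
                    "name": g.model.body.name,
                    "chrom": g.model.body.chrom,
                    "start": g.model.body.start,
                    "end": g.model.body.end,
                    "strand": g.model.body.strand,
                    "rates": g.rates,
                }
                for g in self.genes
            ],
            "differential_features": self.differential_features,
            "motif_assignments": self.motif_assignments,
            "active_motif": self.active_motif,
            "cluster_templates": self.cluster_templates,
            "cell_phenotypes": self.cell_phenotypes,
        }
        Path(path).write_text(json.dumps(doc, indent=1))


# ---------------------------------------------------------------------------
# locus-set generation
# ---------------------------------------------------------------------------

#: default cluster templates: (mononucleosome fraction, motif multiplier).
#: c_base emulates normal interphase cells, c_motif a cluster with elevated
#: accessibility at the active motif's peaks, c_condensed a mitotic-like
#: condensed-chromatin state with high nucleosome signal.
DEFAULT_CLUSTERS: dict[str, tuple[float, float]] = {
    "c_base": (0.3, 1.0),
    "c_motif": (0.3, 2.0),
    "c_condensed": (0.8, 1.0),
}


def simulate_locus_set(
    seed: int,
    n_chroms: int = 2,
    chrom_length: int = 2_000_000,
    n_genes: int = 60,
    n_enhancers: int = 120,
    n_peaks: int = 80,
    imbalanced_fraction: float = 0.1,
    histone_fraction: float = 0.6,
    diff_up_fraction: float = 0.2,
    diff_down_fraction: float = 0.1,
    n_motifs: int = 8,
    peaks_per_motif: int = 20,
    peak_width: int = 400,
    min_gap: int = 2600,
    conditions: Sequence[str] = CONDITIONS,
) -> SyntheticTruth:
    """Place genes, enhancers, peaks, histone peaks and blacklist on a toy genome.

    Features are laid out left to right per chromosome with random gaps of
    at least ``min_gap`` bp, which keeps enhancers intergenic (>= 2 kb from
    any gene) and keeps 1 kb candidate windows of neighbouring features
    disjoint.  Raises ``ValueError`` when the requested features cannot be
    packed into the genome.
    """
    if n_chroms < 1 or chrom_length < 10_000:
        raise ValueError("need at least one chromosome of >= 10 kb")
    rng = np.random.default_rng(seed)
    chroms = [f"chr{i + 1}" for i in range(n_chroms)]
    chrom_lengths = {c: int(chrom_length) for c in chroms}

    # feature skeletons in random order, then distributed over chromosomes
    kinds = ["gene"] * n_genes + ["enh"] * n_enhancers + ["decoy"] * n_peaks
    rng.shuffle(kinds)
    per_chrom: dict[str, list[str]] = {c: [] for c in chroms}
    for i, kind in enumerate(kinds):
        per_chrom[chroms[i % n_chroms]].append(kind)

    genes: list[GeneTruth] = []
    enhancers: list[EnhancerTruth] = []
    peaks: list[GenomicInterval] = []
    gi = ei = di = 0
    for chrom in chroms:
        widths = [
            int(rng.integers(5000, 15001)) if kind == "gene" else peak_width
            for kind in per_chrom[chrom]
        ]
        n_feat = len(widths)
        # gaps: minimum spacing plus a random share of the leftover space
        leftover = chrom_length - sum(widths) - (n_feat + 1) * min_gap
        if leftover < 0:
            raise ValueError(
                f"infeasible packing on {chrom}: "
                f"{sum(widths)} bp of features + gaps exceed {chrom_length} bp"
            )
        shares = rng.dirichlet(np.ones(n_feat + 1)) * leftover if n_feat else []
        cursor = 0
        for kind, w, extra in zip(per_chrom[chrom], widths, shares):
            cursor += min_gap + int(extra)
            if kind == "gene":
                strand = "+" if rng.random() < 0.5 else "-"
                name = f"gene_{gi:04d}"
                n_ex = int(rng.integers(2, 6))
                bounds = np.sort(rng.choice(np.arange(cursor + 50, cursor + w - 50), size=2 * n_ex, replace=False))
                exons = tuple(
                    GenomicInterval(chrom, int(bounds[2 * k]), int(bounds[2 * k + 1]), strand)
                    for k in range(n_ex)
                )
                body = GenomicInterval(chrom, cursor, cursor + w, strand, name)
                base = float(np.exp(rng.uniform(np.log(0.02), np.log(0.2))))
                genes.append(GeneTruth(GeneModel(body, exons), {c: base for c in conditions}))
                gi += 1
            elif kind == "enh":
                center = cursor + w // 2
                name = f"enh_{ei:04d}"
                rate = float(np.exp(rng.uniform(np.log(150), np.log(400))))
                balanced = rng.random() >= imbalanced_fraction
                if balanced:
                    pf = float(rng.uniform(0.45, 0.55))
                else:
                    pf = float(rng.uniform(0.92, 0.97))
                    if rng.random() < 0.5:
                        pf = 1.0 - pf
                enhancers.append(
                    EnhancerTruth(
                        id=name,
                        chrom=chrom,
                        center=center,
                        rates={c: rate for c in conditions},
                        balanced=balanced,
                        plus_fraction=pf,
                        has_histone=rng.random() < histone_fraction,
                        histone_width=int(rng.integers(1000, 7001)),
                    )
                )
                peaks.append(
                    GenomicInterval(chrom, cursor, cursor + w, ".", name, float(rng.uniform(0.3, 0.7)))
                )
                ei += 1
            else:
                name = f"decoy_{di:04d}"
                peaks.append(
                    GenomicInterval(chrom, cursor, cursor + w, ".", name, float(rng.uniform(0.3, 0.7)))
                )
                di += 1
            cursor += w

    # condition-specific fold changes on a subset of enhancers and genes
    differential: dict[str, float] = {}
    if len(conditions) >= 2:
        treated = conditions[1]
        for coll, ids in (
            (enhancers, [e.id for e in enhancers]),
            (genes, [g.model.body.name for g in genes]),
        ):
            n = len(ids)
            order = rng.permutation(n)
            n_up = int(round(diff_up_fraction * n))
            n_down = int(round(diff_down_fraction * n))
            for j in order[:n_up]:
                fc = float(rng.uniform(2.0, 4.0))
                differential[ids[j]] = fc
                coll[j].rates[treated] = coll[j].rates[conditions[0]] * fc
            for j in order[n_up : n_up + n_down]:
                fc = float(1.0 / rng.uniform(2.0, 4.0))
                differential[ids[j]] = fc
                coll[j].rates[treated] = coll[j].rates[conditions[0]] * fc

    # histone peaks over a subset of enhancers, clipped to stay clear of
    # neighbouring candidate windows
    centers = sorted(
        [(p.chrom, p.center) for p in peaks]
        + [(g.model.body.chrom, g.model.body.start) for g in genes]
        + [(g.model.body.chrom, g.model.body.end) for g in genes]
    )
    histone_peaks: list[GenomicInterval] = []
    for e in enhancers:
        if not e.has_histone:
            continue
        half = e.histone_width // 2
        for chrom, c in centers:
            if chrom == e.chrom and c != e.center:
                d = abs(c - e.center)
                if d - 1100 < half:
                    half = max(500, d - 1100)
        histone_peaks.append(
            GenomicInterval(e.chrom, e.center - half, e.center + half, ".", f"hist_{e.id}")
        )

    # blacklist over a subset of decoy peaks
    decoys = [p for p in peaks if p.name.startswith("decoy_")]
    n_bl = max(1, len(decoys) // 8) if decoys else 0
    bl_idx = rng.choice(len(decoys), size=n_bl, replace=False) if n_bl else []
    blacklist = [
        GenomicInterval(decoys[i].chrom, decoys[i].start, decoys[i].end, ".", f"bl_{k:03d}")
        for k, i in enumerate(sorted(bl_idx))
    ]

    # motif -> peak assignments; the first motif is the planted "active" one
    motifs: dict[str, list[str]] = {}
    peak_names = [p.name for p in peaks]
    for m in range(n_motifs):
        k = min(peaks_per_motif, len(peak_names))
        chosen = rng.choice(len(peak_names), size=k, replace=False)
        motifs[f"M{m}"] = sorted(peak_names[i] for i in chosen)

    return SyntheticTruth(
        chrom_lengths=chrom_lengths,
        conditions=tuple(conditions),
        enhancers=enhancers,
        genes=genes,
        peaks=peaks,
        blacklist=blacklist,
        histone_peaks=histone_peaks,
        differential_features=differential,
        motif_assignments=motifs,
        active_motif="M0",
        cluster_templates=dict(DEFAULT_CLUSTERS),
    )


# ---------------------------------------------------------------------------
# nascent coverage
# ---------------------------------------------------------------------------


def simulate_nascent_coverage(
    truth: SyntheticTruth,
    condition: str,
    depth: float = 1.0,
    seed: int = 0,
    background_rate: float = 1e-4,
    enhancer_window: int = 300,
    dispersion: float = 0.1,
) -> StrandedCoverage:
    """Draw Poisson per-base nascent coverage for one condition/sample.

    Genes transcribe on their sense strand over the body; enhancers emit
    eRNA split across strands within ``center +/- enhancer_window``.  When
    ``dispersion`` > 0 each feature's rate is Gamma-mixed per call, so
    region-level counts across independent samples are negative binomial —
    the distribution the downstream differential test assumes.
    """
    if condition not in truth.conditions:
        raise ValueError(f"unknown condition {condition!r}")
    if depth < 0:
        raise ValueError("depth must be non-negative")
    rng = np.random.default_rng(seed)

    rate = {
        "+": {c: np.full(n, background_rate * depth) for c, n in truth.chrom_lengths.items()},
        "-": {c: np.full(n, background_rate * depth) for c, n in truth.chrom_lengths.items()},
    }

    def mix(x: float) -> float:
        if dispersion <= 0:
            return x
        return x * float(rng.gamma(1.0 / dispersion, dispersion))

    for g in truth.genes:
        body = g.model.body
        r = mix(g.rates[condition] * depth)
        rate[body.strand][body.chrom][body.start : body.end] += r

    for e in truth.enhancers:
        lo = max(0, e.center - enhancer_window)
        hi = min(truth.chrom_lengths[e.chrom], e.center + enhancer_window)
        total = mix(e.rates[condition] * depth)
        per_base = total / max(1, hi - lo)
        rate["+"][e.chrom][lo:hi] += per_base * e.plus_fraction
        rate["-"][e.chrom][lo:hi] += per_base * (1.0 - e.plus_fraction)

    plus = {c: rng.poisson(v).astype(float) for c, v in rate["+"].items()}
    minus = {c: rng.poisson(v).astype(float) for c, v in rate["-"].items()}
    return StrandedCoverage(plus=plus, minus=minus, chrom_lengths=dict(truth.chrom_lengths))


def simulate_histone_coverage(
    truth: SyntheticTruth,
    depth: float = 1.0,
    seed: int = 0,
    summit_rate: float = 60.0,
    valley_ratio: float = 0.2,
    background_rate: float = 0.2,
) -> dict[str, np.ndarray]:
    """Unstranded histone ChIP signal with a central dip at each histone peak.

    Each histone peak gets two Gaussian summits flanking the enhancer
    center, so the enhancer sits in a nucleosome-free valley whose floor is
    ``valley_ratio`` of the summit height.
    """
    rng = np.random.default_rng(seed)
    rate = {c: np.full(n, background_rate * depth) for c, n in truth.chrom_lengths.items()}
    hist_by_id = {h.name: h for h in truth.histone_peaks}
    for e in truth.enhancers:
        h = hist_by_id.get(f"hist_{e.id}")
        if h is None:
            continue
        offset = max(300, h.width // 5)
        sd = max(100.0, h.width / 14.0)
        pos = np.arange(h.start, h.end)
        bump = np.exp(-0.5 * ((pos - (e.center - offset)) / sd) ** 2)
        bump += np.exp(-0.5 * ((pos - (e.center + offset)) / sd) ** 2)
        floor = valley_ratio * bump.max()
        profile = np.maximum(bump, 0.0) + floor
        rate[h.chrom][h.start : h.end] += summit_rate * depth * profile / profile.max()
    return {c: rng.poisson(v).astype(float) for c, v in rate.items()}


# ---------------------------------------------------------------------------
# single-cell fragments
# ---------------------------------------------------------------------------


def simulate_fragments(
    truth: SyntheticTruth,
    n_cells_per_cluster: int = 60,
    fragments_per_cell: int = 3000,
    seed: int = 0,
    in_peak_fraction: float = 0.6,
    tss_fraction: float = 0.15,
    blacklist_weight: float = 0.2,
) -> tuple[list[FragmentRecord], CellLabelTable]:
    """Simulate per-cell accessibility fragments and a cell-label table.

    Each cell belongs to a cluster template from ``truth.cluster_templates``;
    its fragment lengths follow the two-component nucleosomal mixture with
    the template's mononucleosome fraction, and its fragments land in the
    active motif's peaks at a rate scaled by the template's motif
    multiplier.  Barcode phenotypes are recorded into
    ``truth.cell_phenotypes``.
    """
    if fragments_per_cell < 1:
        raise ValueError("fragments_per_cell must be >= 1")
    if not truth.cluster_templates:
        raise ValueError("need at least one cluster template")
    rng = np.random.default_rng(seed)

    peaks = truth.peaks
    motif_peaks = set(truth.motif_assignments.get(truth.active_motif, []))
    # blacklist intervals sit on decoy peaks: match by coordinates
    bl_coords = {(iv.chrom, iv.start, iv.end) for iv in truth.blacklist}
    base_w = np.array(
        [
            blacklist_weight if (p.chrom, p.start, p.end) in bl_coords else 1.0
            for p in peaks
        ]
    )
    motif_mask = np.array([p.name in motif_peaks for p in peaks])
    tss = [(g.model.body.chrom, g.model.tss) for g in truth.genes]
    chroms = list(truth.chrom_lengths)
    chrom_len = truth.chrom_lengths

    records: list[FragmentRecord] = []
    labels: dict[str, str] = {}
    for cluster, (mono_frac, mult) in truth.cluster_templates.items():
        w = base_w * np.where(motif_mask, mult, 1.0)
        w = w / w.sum()
        for j in range(n_cells_per_cluster):
            barcode = f"{cluster}_{j:04d}"
            labels[barcode] = cluster
            truth.cell_phenotypes[barcode] = (cluster, mono_frac, mult)

            n = fragments_per_cell
            lengths = np.where(
                rng.random(n) < mono_frac,
                np.clip(np.rint(rng.normal(MONO_MEAN, MONO_SD, n)), *MONO_RANGE),
                np.clip(np.rint(rng.normal(SUBNUC_MEAN, SUBNUC_SD, n)), *SUBNUC_RANGE),
            ).astype(int)

            u = rng.random(n)
            in_peak = u < in_peak_fraction
            at_tss = (~in_peak) & (u < in_peak_fraction + tss_fraction)
            centers = np.empty(n, dtype=int)
            frag_chrom = np.empty(n, dtype=object)

            idx = rng.choice(len(peaks), size=int(in_peak.sum()), p=w)
            frag_chrom[in_peak] = [peaks[i].chrom for i in idx]
            centers[in_peak] = [
                int(rng.integers(peaks[i].start, peaks[i].end)) for i in idx
            ]

            n_tss = int(at_tss.sum())
            if n_tss and tss:
                t_idx = rng.integers(0, len(tss), size=n_tss)
                frag_chrom[at_tss] = [tss[i][0] for i in t_idx]
                centers[at_tss] = [
                    int(tss[i][1] + rng.normal(0, 50)) for i in t_idx
                ]
            bg = ~(in_peak | at_tss)
            n_bg = int(bg.sum())
            bg_chrom_idx = rng.integers(0, len(chroms), size=n_bg)
            frag_chrom[bg] = [chroms[i] for i in bg_chrom_idx]
            centers[bg] = [
                int(rng.integers(0, chrom_len[chroms[i]])) for i in bg_chrom_idx
            ]

            starts = centers - lengths // 2
            for c, s, ln in zip(frag_chrom, starts, lengths):
                s = int(max(0, min(s, chrom_len[c] - ln - 1)))
                records.append(FragmentRecord(str(c), s, s + int(ln), barcode, 1))

    records.sort(key=lambda r: (r.chrom, r.start, r.end, r.barcode))
    return records, CellLabelTable(labels=labels)


# ---------------------------------------------------------------------------
# motif site export
# ---------------------------------------------------------------------------


def motif_sites(truth: SyntheticTruth) -> list[GenomicInterval]:
    """One motif site interval at the center of each assigned peak.

    The BED name column carries the motif id, so the sites file maps
    motifs to peaks after intersection.
    """
    by_name = {p.name: p for p in truth.peaks}
    sites: list[GenomicInterval] = []
    for motif, names in sorted(truth.motif_assignments.items()):
        for nm in names:
            p = by_name[nm]
            c = p.center
            sites.append(GenomicInterval(p.chrom, c - 5, c + 5, ".", motif))
    sites.sort(key=lambda iv: (iv.chrom, iv.start))
    return sites
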