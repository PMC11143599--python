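"""Per-cell QC from single-cell accessibility fragment files.

The central metric is the nucleosome signal: the ratio of
mononucleosome-sized fragments (147-294 bp) to sub-nucleosomal fragments
(< 147 bp).  Cells in a condensed, mitotic-like chromatin state shift
their fragment-length distribution toward the mononucleosomal mode and
show an elevated nucleosome signal.  The remaining metrics — fragment
totals, fraction of fragments in peaks, blacklist ratio, and TSS
enrichment — are the standard per-nucleus quality filters.

Duplicate multiplicity (the fifth fragments-file column) counts toward
every metric.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree

from .core_io import FragmentRecord, GenomicInterval

MONO_RANGE = (147, 294)
FREE_MAX = 147

#: QC thresholds: all comparisons are strict inequalities.
DEFAULT_QC_THRESHOLDS: dict[str, float] = {
    "min_fragments_in_peaks": 1000,
    "max_fragments_in_peaks": 100_000,
    "min_pct_reads_in_peaks": 15.0,
    "max_blacklist_ratio": 0.05,
    "max_nucleosome_signal": 10.0,
    "min_tss_enrichment": 2.0,
}


@dataclass
class CellMetrics:
    barcode: str
    n_fragments: int = 0
    n_in_peaks: int = 0
    blacklist_fragments: int = 0
    nucleosome_signal: float = math.nan
    tss_enrichment: float = math.nan

    @property
    def pct_reads_in_peaks(self) -> float:
        if self.n_fragments == 0:
            return 0.0
        return 100.0 * self.n_in_peaks / self.n_fragments

    @property
    def blacklist_ratio(self) -> float:
        if self.n_fragments == 0:
            return 0.0
        return self.blacklist_fragments / self.n_fragments


def nucleosome_signal(
    lengths: Sequence[int] | np.ndarray,
    counts: Sequence[int] | np.ndarray | None = None,
    mono_range: tuple[int, int] = MONO_RANGE,
    free_max: int = FREE_MAX,
) -> float:
    """Mononucleosomal / sub-nucleosomal fragment ratio for one cell.

    Returns ``+inf`` when there are mononucleosomal but no sub-nucleosomal
    fragments (fully condensed profile) and ``nan`` when both bins are
    empty.
    """
    lengths = np.asarray(lengths)
    if np.any(lengths < 1):
        raise ValueError("fragment lengths must be >= 1")
    counts = (
        np.ones(len(lengths)) if counts is None else np.asarray(counts, dtype=float)
    )
    mono = counts[(lengths >= mono_range[0]) & (lengths <= mono_range[1])].sum()
    free = counts[lengths < free_max].sum()
    if free == 0:
        return math.inf if mono > 0 else math.nan
    return float(mono / free)


def _build_tree(intervals: Sequence[GenomicInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for iv in intervals:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    return trees


def per_cell_metrics(
    fragments: Iterable[FragmentRecord],
    peaks: Sequence[GenomicInterval],
    blacklist: Sequence[GenomicInterval] = (),
    tss_positions: Sequence[tuple[str, int]] = (),
    tss_flank: int = 2000,
    chrom: str | None = None,
) -> list[CellMetrics]:
    """Compute fragment totals, peak/blacklist overlap, NS and TSS enrichment.

    A fragment is in-peak when either of its ends (Tn5 insertions at
    ``start`` and ``end - 1``) lies inside a peak; it counts toward the
    blacklist when it overlaps a blacklist region.  TSS enrichment is the
    mean insertion density over the central 101 bp of all TSS windows
    (``tss +/- tss_flank``) divided by the mean density over the two
    outermost 100 bp flanks; ``+inf`` when the flanks are empty but the
    center is not.  ``chrom`` optionally restricts the nucleosome-signal
    computation to one chromosome.
    """
    peak_trees = _build_tree(peaks)
    bl_trees = _build_tree(blacklist)
    tss_by_chrom: dict[str, np.ndarray] = {}
    for c, pos in tss_positions:
        tss_by_chrom.setdefault(c, [])
    for c, pos in tss_positions:
        tss_by_chrom[c].append(pos)
    tss_by_chrom = {c: np.sort(np.asarray(v)) for c, v in tss_by_chrom.items()}

    per_cell: dict[str, dict] = {}
    for frag in fragments:
        st = per_cell.setdefault(
            frag.barcode,
            {
                "n": 0,
                "in_peaks": 0,
                "bl": 0,
                "mono": 0.0,
                "free": 0.0,
                "tss_center": 0.0,
                "tss_flank": 0.0,
            },
        )
        w = frag.count
        st["n"] += w
        tree = peak_trees.get(frag.chrom)
        if tree is not None and (
            tree.overlaps_point(frag.start) or tree.overlaps_point(frag.end - 1)
        ):
            st["in_peaks"] += w
        bt = bl_trees.get(frag.chrom)
        if bt is not None and bt.overlap(frag.start, frag.end):
            st["bl"] += w
        if chrom is None or frag.chrom == chrom:
            ln = frag.length
            if MONO_RANGE[0] <= ln <= MONO_RANGE[1]:
                st["mono"] += w
            elif ln < FREE_MAX:
                st["free"] += w
        tss = tss_by_chrom.get(frag.chrom)
        if tss is not None and len(tss):
            for insertion in (frag.start, frag.end - 1):
                j = np.searchsorted(tss, insertion)
                for t in tss[max(0, j - 1) : j + 1]:
                    d = insertion - t
                    if -50 <= d <= 50:
                        st["tss_center"] += w
                    elif -tss_flank <= d < -tss_flank + 100 or tss_flank - 100 < d <= tss_flank:
                        st["tss_flank"] += w

    out: list[CellMetrics] = []
    for bc in sorted(per_cell):
        st = per_cell[bc]
        if st["free"] == 0:
            ns = math.inf if st["mono"] > 0 else math.nan
        else:
            ns = st["mono"] / st["free"]
        center_density = st["tss_center"] / 101.0
        flank_density = st["tss_flank"] / 200.0
        if flank_density == 0:
            tss_enr = math.inf if center_density > 0 else math.nan
        else:
            tss_enr = center_density / flank_density
        out.append(
            CellMetrics(
                barcode=bc,
                n_fragments=st["n"],
                n_in_peaks=st["in_peaks"],
                blacklist_fragments=st["bl"],
                nucleosome_signal=ns,
                tss_enrichment=tss_enr,
            )
        )
    return out


def qc_filter(
    metrics: Sequence[CellMetrics],
    thresholds: Mapping[str, float] | None = None,
) -> list[str]:
    """Barcodes passing all strict-inequality QC thresholds.

    A ``+inf`` nucleosome signal fails the upper bound; ``nan`` metrics
    fail their test (comparisons with nan are false).
    """
    th = dict(DEFAULT_QC_THRESHOLDS)
    if thresholds:
        unknown = set(thresholds) - set(th)
        if unknown:
            raise ValueError(f"unknown QC thresholds: {sorted(unknown)}")
        th.update(thresholds)
    kept: list[str] = []
    for m in metrics:
        if (
            m.n_in_peaks > th["min_fragments_in_peaks"]
            and m.n_in_peaks < th["max_fragments_in_peaks"]
            and m.pct_reads_in_peaks > th["min_pct_reads_in_peaks"]
            and m.blacklist_ratio < th["max_blacklist_ratio"]
            and m.nucleosome_signal < th["max_nucleosome_signal"]
            and m.tss_enrichment > th["min_tss_enrichment"]
        ):
            kept.append(m.barcode)
    return kept


def length_histogram(
    fragments: Iterable[FragmentRecord],
    groups: Mapping[str, str],
    max_len: int = 600,
) -> dict[str, np.ndarray]:
    """Per-group integer fragment-length histogram over [1, max_len].

    ``groups`` maps barcodes to group labels; fragments from unlabelled
    barcodes are ignored, as are lengths beyond ``max_len``.  Bin ``i`` of
    the returned vectors counts fragments of length ``i + 1``.
    """
    hists: dict[str, np.ndarray] = {g: np.zeros(max_len, dtype=int) for g in set(groups.values())}
    for frag in fragments:
        g = groups.get(frag.barcode)
        if g is None:
            continue
        ln = frag.length
        if 1 <= ln <= max_len:
            hists[g][ln - 1] += frag.count
    return hists


def metrics_frame(metrics: Sequence[CellMetrics]):
    """Per-barcode QC metrics as a pandas DataFrame (TSV-ready)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "barcode": [m.barcode for m in metrics],
            "n_fragments": [m.n_fragments for m in metrics],
            "n_in_peaks": [m.n_in_peaks for m in metrics],
            "pct_reads_in_peaks": [m.pct_reads_in_peaks for m in metrics],
            "blacklist_ratio": [m.blacklist_ratio for m in metrics],
            "nucleosome_signal": [m.nucleosome_signal for m in metrics],
            "tss_enrichment": [m.tss_enrichment for m in metrics],
        }
    )
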