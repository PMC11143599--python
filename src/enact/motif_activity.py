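"""Per-cell TF motif-deviation activity from peak x cell accessibility.

For each motif, the observed insertion count in its peaks per cell is
compared with the expectation under the aggregate accessibility profile:

    expected_mc = (sum of motif-peak totals / grand total) * cell_c total
    raw_mc      = (observed_mc - expected_mc) / expected_mc

Raw deviations are standardized against ``B`` background peak sets that
match each motif peak on GC content and mean accessibility (decile-grid
binning), giving a z-score per motif per cell — a proxy for TF activity
that is comparable across motifs of different peak-set sizes.

Cluster-specific motifs are called with a Wilcoxon rank-sum test of the
z-scores (cluster vs rest), thresholding the difference of mean z and
the BH-adjusted p-value.  Known-motif enrichment in a region set uses
Fisher's exact test against a background region set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .activity_stats import bh_fdr
from .core_io import FragmentRecord, GenomicInterval

MIN_PEAK_WIDTH = 10         # merged peaks narrower than this are discarded
MIN_CELL_FRACTION = 0.01    # peaks must be detected in > 1% of cells


@dataclass
class PeakCellMatrix:
    """Retained peaks x kept cells insertion-count matrix with per-peak GC."""

    peaks: list[GenomicInterval]
    gc: np.ndarray
    barcodes: list[str]
    counts: np.ndarray  # peaks x cells

    def __post_init__(self) -> None:
        self.gc = np.asarray(self.gc, dtype=float)
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.peaks), len(self.barcodes)):
            raise ValueError("counts shape inconsistent with peaks/barcodes")

    @property
    def peak_names(self) -> list[str]:
        return [p.name for p in self.peaks]


@dataclass
class DeviationMatrix:
    """Motifs x cells raw deviations and background-calibrated z-scores."""

    motif_ids: list[str]
    barcodes: list[str]
    raw: np.ndarray
    z: np.ndarray
    background_sets: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.z, index=self.motif_ids, columns=self.barcodes)


# ---------------------------------------------------------------------------
# peak x cell matrix
# ---------------------------------------------------------------------------


def build_peak_matrix(
    fragments: Iterable[FragmentRecord],
    peaks: Sequence[GenomicInterval],
    kept_barcodes: Sequence[str],
    min_peak_width: int = MIN_PEAK_WIDTH,
    min_cell_fraction: float = MIN_CELL_FRACTION,
) -> PeakCellMatrix:
    """Count Tn5 insertions (both fragment ends) per peak per kept cell.

    Peaks narrower than ``min_peak_width`` bp are discarded before
    counting; peaks detected in no more than ``min_cell_fraction`` of the
    kept cells are dropped afterwards.  Per-peak GC is carried in the
    peak score column.
    """
    kept = list(kept_barcodes)
    if not kept:
        raise ValueError("no kept barcodes")
    bc_index = {bc: i for i, bc in enumerate(kept)}
    wide = [p for p in peaks if p.width >= min_peak_width]
    trees: dict[str, IntervalTree] = {}
    for i, p in enumerate(wide):
        trees.setdefault(p.chrom, IntervalTree()).addi(p.start, p.end, i)

    counts = np.zeros((len(wide), len(kept)), dtype=np.int64)
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

    detected = (counts > 0).sum(axis=1) / len(kept)
    keep = detected > min_cell_fraction
    return PeakCellMatrix(
        peaks=[p for p, k in zip(wide, keep) if k],
        gc=np.array([p.score for p, k in zip(wide, keep) if k]),
        barcodes=kept,
        counts=counts[keep],
    )


# ---------------------------------------------------------------------------
# deviation scores
# ---------------------------------------------------------------------------


MIN_BIN_OCCUPANCY = 8  # background bins need enough peers to be informative


def _background_bins(
    matrix: PeakCellMatrix, gc_bins: int, access_bins: int
) -> np.ndarray:
    """Assign every peak to a (GC quantile x log-mean-access quantile) bin.

    The requested grid is coarsened so that the average bin holds at
    least ``MIN_BIN_OCCUPANCY`` peaks; with a decile x decile default
    grid this only matters for small (toy-scale) peak sets, where a full
    grid would let motif peaks match mostly themselves.
    """
    n = len(matrix.peaks)
    per_axis = max(1, int(np.sqrt(n / MIN_BIN_OCCUPANCY)))
    gc_k = min(gc_bins, per_axis)
    acc_k = min(access_bins, per_axis)

    def quantile_codes(values: np.ndarray, k: int) -> np.ndarray:
        qs = np.quantile(values, np.linspace(0, 1, k + 1)[1:-1])
        return np.searchsorted(qs, values, side="right")

    gc_code = quantile_codes(matrix.gc, gc_k)
    access = np.log1p(matrix.counts.mean(axis=1))
    acc_code = quantile_codes(access, acc_k)
    return gc_code * acc_k + acc_code


def motif_deviation_scores(
    matrix: PeakCellMatrix,
    motifs: Mapping[str, Sequence[str]],
    B: int = 50,
    gc_bins: int = 10,
    access_bins: int = 10,
    seed: int = 0,
) -> DeviationMatrix:
    """Raw and background-standardized motif deviations per cell.

    ``motifs`` maps motif ids to peak names (peaks absent from the
    retained matrix are ignored; motifs with no retained peak raise).
    Cells with zero total counts get NaN scores.
    """
    if B < 10:
        raise ValueError("B must be >= 10")
    rng = np.random.default_rng(seed)
    name_index = {nm: i for i, nm in enumerate(matrix.peak_names)}
    X = matrix.counts.astype(float)
    cell_tot = X.sum(axis=0)
    peak_tot = X.sum(axis=1)
    grand = X.sum()
    if grand <= 0:
        raise ValueError("empty count matrix")
    empty_cells = cell_tot == 0

    bins = _background_bins(matrix, gc_bins, access_bins)
    peers: dict[int, np.ndarray] = {
        b: np.flatnonzero(bins == b) for b in np.unique(bins)
    }

    def raw_for(idx: np.ndarray) -> np.ndarray:
        expected = peak_tot[idx].sum() / grand * cell_tot
        observed = X[idx].sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(expected > 0, (observed - expected) / expected, np.nan)

    motif_ids = sorted(motifs)
    raw = np.full((len(motif_ids), len(matrix.barcodes)), np.nan)
    z = np.full_like(raw, np.nan)
    for mi, motif in enumerate(motif_ids):
        idx = np.array(
            sorted(name_index[nm] for nm in motifs[motif] if nm in name_index),
            dtype=int,
        )
        if idx.size == 0:
            raise ValueError(f"motif {motif!r} overlaps no retained peak")
        raw[mi] = raw_for(idx)
        bg = np.empty((B, len(matrix.barcodes)))
        for b in range(B):
            sampled = np.array(
                [peers[bins[i]][rng.integers(len(peers[bins[i]]))] for i in idx]
            )
            bg[b] = raw_for(sampled)
        mu = bg.mean(axis=0)
        sd = bg.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            z[mi] = (raw[mi] - mu) / np.maximum(sd, 1e-12)
    raw[:, empty_cells] = np.nan
    z[:, empty_cells] = np.nan
    return DeviationMatrix(
        motif_ids=motif_ids,
        barcodes=list(matrix.barcodes),
        raw=raw,
        z=z,
        background_sets=B,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# cluster-specific motifs
# ---------------------------------------------------------------------------


def cluster_specific_motifs(
    deviations: DeviationMatrix,
    labels: Mapping[str, str],
    effect_threshold: float = 1.5,
    fdr: float = 1e-4,
) -> pd.DataFrame:
    """Wilcoxon rank-sum of z-scores, each cluster vs the rest.

    The effect is the difference of mean z (cluster minus rest), reported
    in the fold-change slot of the output; a motif is significant for a
    cluster when ``|effect| >= effect_threshold`` and BH q < ``fdr``.
    """
    lab = np.array([labels.get(bc, "") for bc in deviations.barcodes])
    clusters = sorted(c for c in set(lab) if c)
    if len(clusters) < 2:
        raise ValueError("need >= 2 clusters")
    rows = []
    for ci, cluster in enumerate(clusters):
        in_c = lab == cluster
        out_c = (lab != cluster) & (lab != "")
        if in_c.sum() < 3 or out_c.sum() < 3:
            raise ValueError(f"cluster {cluster!r} needs >= 3 cells on both sides")
        for mi, motif in enumerate(deviations.motif_ids):
            zi = deviations.z[mi]
            a, b = zi[in_c], zi[out_c]
            a, b = a[~np.isnan(a)], b[~np.isnan(b)]
            stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
            rows.append(
                {
                    "motif": motif,
                    "cluster": cluster,
                    "effect": float(a.mean() - b.mean()),
                    "pvalue": float(p),
                }
            )
    df = pd.DataFrame(rows)
    df["qvalue"] = bh_fdr(df["pvalue"].to_numpy())
    df["significant"] = (df["effect"].abs() >= effect_threshold) & (df["qvalue"] < fdr)
    return df


# ---------------------------------------------------------------------------
# known-motif enrichment in a region set
# ---------------------------------------------------------------------------


def motif_enrichment(
    target_regions: Sequence[GenomicInterval],
    background_regions: Sequence[GenomicInterval],
    motif_sites: Mapping[str, Sequence[GenomicInterval]],
) -> pd.DataFrame:
    """Fisher's exact enrichment of motif sites in targets vs background.

    Background regions that coincide with a target (same coordinates) are
    excluded.  The odds ratio uses a Haldane 0.5 correction when any
    margin of the 2x2 table is zero.
    """
    if not target_regions or not background_regions:
        raise ValueError("target and background region sets must be non-empty")
    target_keys = {(t.chrom, t.start, t.end) for t in target_regions}
    background = [
        b for b in background_regions if (b.chrom, b.start, b.end) not in target_keys
    ]
    if not background:
        raise ValueError("background is empty after excluding targets")

    def with_site(regions: Sequence[GenomicInterval], sites: Sequence[GenomicInterval]) -> int:
        trees: dict[str, IntervalTree] = {}
        for s in sites:
            trees.setdefault(s.chrom, IntervalTree()).addi(s.start, s.end)
        n = 0
        for r in regions:
            t = trees.get(r.chrom)
            if t is not None and t.overlap(r.start, r.end):
                n += 1
        return n

    rows = []
    for motif in sorted(motif_sites):
        sites = motif_sites[motif]
        a = with_site(target_regions, sites)
        b = len(target_regions) - a
        c = with_site(background, sites)
        d = len(background) - c
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        if min(a + b, c + d, a + c, b + d) == 0 or 0 in (a, b, c, d):
            odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
        else:
            odds = (a * d) / (b * c)
        rows.append({"motif": motif, "odds_ratio": float(odds), "pvalue": float(p)})
    df = pd.DataFrame(rows)
    df["qvalue"] = bh_fdr(df["pvalue"].to_numpy())
    return df
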