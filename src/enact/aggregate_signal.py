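"""Chromatin-state-specific enhancer selection and binned signal matrices.

``state_specific_regions`` reproduces the marker-style per-state test on
per-cell accessibility (Wilcoxon on log-normalized counts, fold-change
and FDR thresholds, top-N by effect size).  ``signal_matrix`` computes
the metagene-style regions x bins matrix (bin value = mean per-base
signal) used for heatmaps, and ``average_profile`` the per-group mean
histograms.  ``pseudobulk_insertion_coverage`` pools per-cell fragments
into one insertion-coverage track per chromatin state.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .activity_stats import bh_fdr
from .core_io import FragmentRecord, GenomicInterval


@dataclass
class SignalMatrix:
    """Regions x bins signal matrix centered on region midpoints.

    The region center falls on the boundary between the two middle bins;
    bin ``j`` covers ``[center - flank + j*bin_size, ... + bin_size)``.
    """

    region_ids: list[str]
    bin_size: int
    flank: int
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n_bins = 2 * self.flank // self.bin_size
        if self.values.shape != (len(self.region_ids), n_bins):
            raise ValueError("values shape inconsistent with regions/bins")

    @property
    def n_bins(self) -> int:
        return 2 * self.flank // self.bin_size

    def to_frame(self) -> pd.DataFrame:
        cols = [
            f"{-self.flank + j * self.bin_size}"
            for j in range(self.n_bins)
        ]
        return pd.DataFrame(self.values, index=self.region_ids, columns=cols)

    def row_max_normalized(self) -> "SignalMatrix":
        mx = np.maximum(self.values.max(axis=1, keepdims=True), 1e-12)
        return SignalMatrix(
            list(self.region_ids), self.bin_size, self.flank, self.values / mx
        )


# ---------------------------------------------------------------------------
# state-specific regions
# ---------------------------------------------------------------------------


def state_specific_regions(
    counts: np.ndarray,
    region_ids: Sequence[str],
    cell_labels: Sequence[str],
    min_fc: float = 0.1,
    fdr: float = 0.1,
    top_n: int = 200,
    scale: float = 1e4,
) -> pd.DataFrame:
    """Per-state up/down accessibility markers from a regions x cells matrix.

    Counts are depth-normalized per cell to ``scale`` and log1p
    transformed; each region is tested per state with a Wilcoxon rank-sum
    (state vs rest).  log2FC compares depth-normalized mean counts with a
    +1 pseudocount.  A region is significant when ``|log2FC| >= min_fc``
    and BH q (over all region x state tests) < ``fdr``; per state and
    direction only the ``top_n`` by |log2FC| are flagged as top hits.
    """
    counts = np.asarray(counts, dtype=float)
    labels = np.asarray(cell_labels)
    states = sorted(set(labels))
    if len(states) < 2:
        raise ValueError("need >= 2 states")
    if counts.shape != (len(region_ids), len(labels)):
        raise ValueError("counts shape inconsistent with regions/labels")

    depth = np.maximum(counts.sum(axis=0), 1.0)
    norm = counts / depth[None, :] * scale
    logn = np.log1p(norm)

    rows = []
    for state in states:
        in_s = labels == state
        out_s = ~in_s
        mean_in = norm[:, in_s].mean(axis=1)
        mean_out = norm[:, out_s].mean(axis=1)
        log2fc = np.log2(mean_in + 1.0) - np.log2(mean_out + 1.0)
        stat, p = stats.mannwhitneyu(
            logn[:, in_s], logn[:, out_s], axis=1, alternative="two-sided"
        )
        for i, rid in enumerate(region_ids):
            rows.append(
                {
                    "region": rid,
                    "state": state,
                    "log2FC": float(log2fc[i]),
                    "pvalue": float(p[i]),
                }
            )
    df = pd.DataFrame(rows)
    df["qvalue"] = bh_fdr(df["pvalue"].to_numpy())
    df["significant"] = (df["log2FC"].abs() >= min_fc) & (df["qvalue"] < fdr)

    df["top_hit"] = False
    for state in states:
        for direction in (1, -1):
            sub = df[
                (df["state"] == state)
                & df["significant"]
                & (np.sign(df["log2FC"]) == direction)
            ]
            chosen = sub.reindex(
                sub["log2FC"].abs().sort_values(ascending=False).index
            ).head(top_n).index
            df.loc[chosen, "top_hit"] = True
    return df


# ---------------------------------------------------------------------------
# binned signal matrices
# ---------------------------------------------------------------------------


def signal_matrix(
    track: Mapping[str, np.ndarray],
    centers: Sequence[tuple[str, int]] | Sequence[GenomicInterval],
    flank: int = 1000,
    bin_size: int = 25,
    region_ids: Sequence[str] | None = None,
) -> SignalMatrix:
    """Mean per-base signal in ``bin_size`` bp bins over ``center +/- flank``.

    ``centers`` may be (chrom, position) pairs or intervals (midpoints are
    used).  Regions extending past a chromosome edge are dropped with a
    warning-level omission (they do not appear in the output).
    """
    if flank % bin_size != 0:
        raise ValueError("flank must be divisible by bin_size")
    pts: list[tuple[str, int, str]] = []
    for i, c in enumerate(centers):
        if isinstance(c, GenomicInterval):
            pts.append((c.chrom, c.center, c.name or f"region_{i:05d}"))
        else:
            chrom, pos = c
            pts.append((chrom, int(pos), f"region_{i:05d}"))
    if region_ids is not None:
        if len(region_ids) != len(pts):
            raise ValueError("region_ids length mismatch")
        pts = [(c, p, rid) for (c, p, _), rid in zip(pts, region_ids)]

    n_bins = 2 * flank // bin_size
    ids: list[str] = []
    rows: list[np.ndarray] = []
    for chrom, pos, rid in pts:
        v = track.get(chrom)
        if v is None or pos - flank < 0 or pos + flank > len(v):
            continue
        window = v[pos - flank : pos + flank]
        rows.append(window.reshape(n_bins, bin_size).mean(axis=1))
        ids.append(rid)
    values = np.vstack(rows) if rows else np.zeros((0, n_bins))
    return SignalMatrix(region_ids=ids, bin_size=bin_size, flank=flank, values=values)


def average_profile(
    matrix: SignalMatrix, groups: Mapping[str, str] | None = None
) -> dict[str, np.ndarray]:
    """Column-wise mean profile per region group (all regions when None).

    Groups with no member regions are omitted.
    """
    if groups is None:
        return {"all": matrix.values.mean(axis=0)} if len(matrix.region_ids) else {}
    out: dict[str, np.ndarray] = {}
    arr = np.asarray(matrix.region_ids)
    for g in sorted(set(groups.values())):
        members = [i for i, rid in enumerate(arr) if groups.get(rid) == g]
        if members:
            out[g] = matrix.values[members].mean(axis=0)
    return out


def pseudobulk_insertion_coverage(
    fragments: Iterable[FragmentRecord],
    labels: Mapping[str, str],
    chrom_lengths: Mapping[str, int],
) -> dict[str, dict[str, np.ndarray]]:
    """Per-state insertion coverage: both fragment ends, pooled over cells."""
    out: dict[str, dict[str, np.ndarray]] = {}
    for frag in fragments:
        state = labels.get(frag.barcode)
        if state is None:
            continue
        track = out.setdefault(
            state, {c: np.zeros(n) for c, n in chrom_lengths.items()}
        )
        v = track.get(frag.chrom)
        if v is None:
            continue
        for insertion in (frag.start, frag.end - 1):
            if 0 <= insertion < len(v):
                v[insertion] += frag.count
    return out
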