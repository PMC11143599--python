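"""eRNA-based enhancer calling from strand-specific nascent coverage.

Candidate enhancers are 1 kb windows centered on accessibility-peak
midpoints.  A candidate survives when

1. it does not overlap gene sense-transcription or a promoter window;
2. its eRNA signal is bidirectional: when one strand exceeds the other
   more than tenfold the signal is treated as read-through from a gene
   and only the lower strand (symmetrized, ``2 x min``) is counted;
3. it passes a counts-per-million cutoff or intersects a histone
   modification peak (H3K27ac/H3K4me1-style evidence);
4. within a tight cluster of candidates, only the best-supported one
   (largest overlap with an accessibility peak or a nucleosome-free dip,
   else maximum signal) is kept.

Nucleosome-free dips are detected inside broad (< 7.5 kb) histone peaks
as smoothed local minima dropping below half of the flanking summits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .core_io import GeneModel, GenomicInterval, StrandedCoverage

BALANCE_RATIO_MAX = 10.0  # "over tenfold" strand-imbalance rule


@dataclass
class CandidateEnhancer:
    """One 1 kb candidate window with per-strand eRNA counts and status."""

    id: str
    chrom: str
    center: int
    flank: int
    plus_count: float = 0.0
    minus_count: float = 0.0
    balance_ratio: float = math.nan
    balanced: bool = False
    effective_count: float = 0.0
    evidence: dict[str, bool] = field(
        default_factory=lambda: {
            "passed_cpm": False,
            "histone_overlap": False,
            "atac_overlap": False,
            "dip_overlap": False,
        }
    )
    status: str = "kept"  # kept | excluded_gene_overlap | excluded_no_evidence | merged_away

    @property
    def region(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.center - self.flank, self.center + self.flank,
            ".", self.id, self.effective_count,
        )

    @property
    def kept(self) -> bool:
        return self.status == "kept"


@dataclass(frozen=True)
class DipCall:
    """A nucleosome-free dip inside a broad histone peak."""

    parent_peak_id: str
    chrom: str
    dip_center: int
    valley_to_summit_ratio: float


# ---------------------------------------------------------------------------
# candidate definition
# ---------------------------------------------------------------------------


def define_candidates(
    peaks: Sequence[GenomicInterval],
    genes: Sequence[GeneModel],
    coverage: StrandedCoverage,
    flank: int = 500,
) -> list[CandidateEnhancer]:
    """Center a ``2*flank`` window on each peak midpoint and count eRNA.

    Candidates overlapping a gene body with nonzero sense coverage in the
    overlap, or any promoter window, are excluded (status
    ``excluded_gene_overlap``).  Windows that would extend past a
    chromosome edge are dropped with a warning.
    """
    if flank < 1:
        raise ValueError("flank must be >= 1")
    by_chrom_genes: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom_genes.setdefault(g.body.chrom, []).append(g)

    out: list[CandidateEnhancer] = []
    for i, peak in enumerate(peaks):
        n = coverage.chrom_lengths.get(peak.chrom)
        if n is None:
            continue
        center = peak.center
        lo, hi = center - flank, center + flank
        if lo < 0 or hi > n:
            continue  # clipped at chromosome edge: drop
        cand = CandidateEnhancer(
            id=peak.name or f"cand_{i:05d}",
            chrom=peak.chrom,
            center=center,
            flank=flank,
        )
        cand.plus_count = float(coverage.plus[peak.chrom][lo:hi].sum())
        cand.minus_count = float(coverage.minus[peak.chrom][lo:hi].sum())

        region = cand.region
        for g in by_chrom_genes.get(peak.chrom, []):
            if region.overlaps(g.promoter):
                cand.status = "excluded_gene_overlap"
                break
            if region.overlaps(g.body):
                o_lo = max(region.start, g.body.start)
                o_hi = min(region.end, g.body.end)
                sense = coverage.strand(g.body.strand)[g.body.chrom][o_lo:o_hi]
                if sense.sum() > 0:
                    cand.status = "excluded_gene_overlap"
                    break
        out.append(cand)
    return out


# ---------------------------------------------------------------------------
# strand balance
# ---------------------------------------------------------------------------


def strand_balance(candidate: CandidateEnhancer) -> CandidateEnhancer:
    """Apply the tenfold bidirectionality rule to one candidate.

    ratio <= 10  -> balanced, effective = plus + minus
    ratio > 10   -> imbalanced, effective = 2 x min (symmetrized lower strand)
    both zero    -> effective 0, excluded_no_evidence
    """
    p, m = candidate.plus_count, candidate.minus_count
    if p < 0 or m < 0:
        raise ValueError("strand counts must be non-negative")
    if p == 0 and m == 0:
        candidate.balance_ratio = math.nan
        candidate.balanced = False
        candidate.effective_count = 0.0
        if candidate.status == "kept":
            candidate.status = "excluded_no_evidence"
        return candidate
    lo, hi = min(p, m), max(p, m)
    candidate.balance_ratio = math.inf if lo == 0 else hi / lo
    candidate.balanced = candidate.balance_ratio <= BALANCE_RATIO_MAX
    candidate.effective_count = (p + m) if candidate.balanced else 2.0 * lo
    return candidate


def effective_count_rule(plus: float, minus: float) -> float:
    """Closed-form effective eRNA count for a (plus, minus) pair."""
    if plus < 0 or minus < 0:
        raise ValueError("strand counts must be non-negative")
    if plus == 0 and minus == 0:
        return 0.0
    lo, hi = min(plus, minus), max(plus, minus)
    ratio = math.inf if lo == 0 else hi / lo
    return plus + minus if ratio <= BALANCE_RATIO_MAX else 2.0 * lo


# ---------------------------------------------------------------------------
# evidence filter
# ---------------------------------------------------------------------------


def apply_evidence_filter(
    candidates: Sequence[CandidateEnhancer],
    min_cpm: float,
    library_size: float,
    histone_peaks: Sequence[GenomicInterval] = (),
) -> list[CandidateEnhancer]:
    """Keep candidates passing the cpm cutoff OR intersecting a histone peak."""
    if min_cpm < 0:
        raise ValueError("min_cpm must be non-negative")
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    hist_by_chrom: dict[str, list[GenomicInterval]] = {}
    for h in histone_peaks:
        hist_by_chrom.setdefault(h.chrom, []).append(h)
    for cand in candidates:
        if cand.status not in ("kept", "excluded_no_evidence"):
            continue
        cpm = cand.effective_count / library_size * 1e6
        cand.evidence["passed_cpm"] = cpm >= min_cpm and cand.effective_count > 0
        region = cand.region
        cand.evidence["histone_overlap"] = any(
            region.overlaps(h) for h in hist_by_chrom.get(cand.chrom, [])
        )
        if cand.evidence["passed_cpm"] or cand.evidence["histone_overlap"]:
            if cand.effective_count > 0:
                cand.status = "kept"
        else:
            cand.status = "excluded_no_evidence"
    return list(candidates)


# ---------------------------------------------------------------------------
# dip detection
# ---------------------------------------------------------------------------


def moving_average(signal: np.ndarray, window: int) -> np.ndarray:
    """Centered box-filter smoothing with edge-truncated windows."""
    if window <= 1:
        return np.asarray(signal, dtype=float)
    kernel = np.ones(window)
    num = np.convolve(signal, kernel, mode="same")
    den = np.convolve(np.ones(len(signal)), kernel, mode="same")
    return num / den


def detect_dips(
    signal: np.ndarray,
    peak: GenomicInterval,
    max_peak_width: int = 7500,
    dip_threshold: float = 0.5,
    smooth_bw: int = 50,
) -> list[DipCall]:
    """Find nucleosome-free dips in one histone peak's signal profile.

    ``signal`` is the per-base profile over ``peak`` (length == width).
    The profile is box-smoothed over ``smooth_bw`` bp; a dip is a local
    minimum whose smoothed value is below ``dip_threshold`` times the
    smaller of the two flanking summits (the maxima left and right of the
    minimum).  Dips closer than ``smooth_bw`` are merged, keeping the
    deepest.  Peaks at or above ``max_peak_width`` return no dips.
    """
    signal = np.asarray(signal, dtype=float)
    if len(signal) != peak.width:
        raise ValueError("signal length must equal peak width")
    if peak.width >= max_peak_width:
        return []
    if not np.any(signal > 0):
        return []
    sm = moving_average(signal, smooth_bw)

    n = len(sm)
    candidates: list[tuple[int, float, float]] = []  # (position, ratio, summit)
    i = 1
    while i < n - 1:
        if sm[i] <= sm[i - 1]:
            j = i
            while j + 1 < n and sm[j + 1] == sm[i]:
                j += 1
            if j < n - 1 and sm[i] < sm[i - 1] and sm[j + 1] > sm[i]:
                pos = (i + j) // 2
                left = sm[:i].max()
                right = sm[j + 1 :].max()
                summit = min(left, right)
                if summit > 0 and sm[pos] < dip_threshold * summit:
                    candidates.append((pos, sm[pos] / summit, summit))
                i = j + 1
                continue
        i += 1

    # one call per valley: minima are distinct dips only when a summit
    # above the dip cutoff line separates them; keep the deepest
    candidates.sort(key=lambda t: (t[1], t[0]))
    chosen: list[tuple[int, float]] = []
    for pos, ratio, summit in candidates:
        distinct = True
        for q, _ in chosen:
            lo, hi = (pos, q) if pos < q else (q, pos)
            if hi - lo < smooth_bw or sm[lo : hi + 1].max() < dip_threshold * summit:
                distinct = False
                break
        if distinct:
            chosen.append((pos, ratio))
    return [
        DipCall(
            parent_peak_id=peak.name or f"{peak.chrom}:{peak.start}-{peak.end}",
            chrom=peak.chrom,
            dip_center=peak.start + pos,
            valley_to_summit_ratio=float(ratio),
        )
        for pos, ratio in chosen
    ]


# ---------------------------------------------------------------------------
# clustered-enhancer resolution
# ---------------------------------------------------------------------------


def resolve_clusters(
    candidates: Sequence[CandidateEnhancer],
    atac_peaks: Sequence[GenomicInterval] = (),
    dips: Sequence[DipCall] = (),
    cluster_gap: int = 500,
) -> list[CandidateEnhancer]:
    """Collapse tightly clustered kept candidates to one representative.

    Kept candidates whose windows overlap or lie within ``cluster_gap`` bp
    form a cluster.  The representative is the member with the largest
    base-pair overlap with any accessibility peak or dip window (dip
    center +/- 100 bp); when no member overlaps either, the member with
    the maximum effective count wins.  Ties break to the smaller start
    coordinate.  All other members get status ``merged_away``.
    """
    kept = sorted(
        (c for c in candidates if c.kept),
        key=lambda c: (c.chrom, c.region.start, c.region.end),
    )
    support = list(atac_peaks) + [
        GenomicInterval(d.chrom, max(0, d.dip_center - 100), d.dip_center + 100)
        for d in dips
    ]
    supp_by_chrom: dict[str, list[GenomicInterval]] = {}
    for s in support:
        supp_by_chrom.setdefault(s.chrom, []).append(s)

    def best_overlap(c: CandidateEnhancer) -> int:
        region = c.region
        return max(
            (region.overlap_bp(s) for s in supp_by_chrom.get(c.chrom, [])),
            default=0,
        )

    clusters: list[list[CandidateEnhancer]] = []
    for c in kept:
        if (
            clusters
            and clusters[-1][-1].chrom == c.chrom
            and c.region.start - clusters[-1][-1].region.end <= cluster_gap
        ):
            clusters[-1].append(c)
        else:
            clusters.append([c])

    for members in clusters:
        if len(members) == 1:
            continue
        overlaps = [best_overlap(c) for c in members]
        if max(overlaps) > 0:
            rep = min(
                zip(overlaps, members),
                key=lambda t: (-t[0], t[1].region.start),
            )[1]
        else:
            rep = min(
                members, key=lambda c: (-c.effective_count, c.region.start)
            )
        for c in members:
            if c is not rep:
                c.status = "merged_away"
    return list(candidates)


# ---------------------------------------------------------------------------
# end-to-end driver
# ---------------------------------------------------------------------------


def call_enhancers(
    peaks: Sequence[GenomicInterval],
    genes: Sequence[GeneModel],
    coverage: StrandedCoverage,
    histone_peaks: Sequence[GenomicInterval] = (),
    atac_peaks: Sequence[GenomicInterval] | None = None,
    histone_signal: Mapping[str, np.ndarray] | None = None,
    flank: int = 500,
    min_cpm: float = 1.0,
    cluster_gap: int = 500,
    max_peak_width: int = 7500,
    dip_threshold: float = 0.5,
    smooth_bw: int = 50,
) -> tuple[list[CandidateEnhancer], list[DipCall]]:
    """Run the full enhancer-calling chain and return all candidates + dips.

    ``atac_peaks`` defaults to the input peak set (candidate centers come
    from accessibility peaks); the library size for the cpm cutoff is the
    total coverage of the track.
    """
    cands = define_candidates(peaks, genes, coverage, flank=flank)
    for c in cands:
        strand_balance(c)
    library_size = max(coverage.total(), 1.0)
    apply_evidence_filter(cands, min_cpm, library_size, histone_peaks)
    dips: list[DipCall] = []
    if histone_signal is not None:
        for h in histone_peaks:
            track = histone_signal.get(h.chrom)
            if track is None:
                continue
            dips.extend(
                detect_dips(
                    track[h.start : h.end],
                    h,
                    max_peak_width=max_peak_width,
                    dip_threshold=dip_threshold,
                    smooth_bw=smooth_bw,
                )
            )
    resolve_clusters(
        cands,
        atac_peaks if atac_peaks is not None else peaks,
        dips,
        cluster_gap=cluster_gap,
    )
    return cands, dips
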