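import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from enact.core_io import GeneModel, GenomicInterval, StrandedCoverage
from enact.enhancer_calling import (
    CandidateEnhancer,
    apply_evidence_filter,
    define_candidates,
    detect_dips,
    effective_count_rule,
    moving_average,
    resolve_clusters,
    strand_balance,
)


def make_coverage(length=20_000, chrom="chr1"):
    return StrandedCoverage.zeros({chrom: length})


class TestDefineCandidates:
    def test_peak_midpoint_extended_by_flank(self):
        cov = make_coverage()
        peak = GenomicInterval("chr1", 10_200, 10_800, name="p1")
        (cand,) = define_candidates([peak], [], cov, flank=500)
        assert cand.center == 10_500
        assert (cand.region.start, cand.region.end) == (10_000, 11_000)

    def test_gene_sense_transcription_excludes(self):
        cov = make_coverage()
        cov.plus["chr1"][12_000:15_000] = 1.0
        gene = GeneModel(GenomicInterval("chr1", 12_000, 15_000, "+", "g"))
        # window [12600, 13600) overlaps the transcribed body, not the promoter
        peak = GenomicInterval("chr1", 12_900, 13_300, name="p1")
        (cand,) = define_candidates([peak], [gene], cov, flank=500)
        assert cand.status == "excluded_gene_overlap"

    def test_gene_body_without_sense_signal_does_not_exclude(self):
        cov = make_coverage()  # silent gene
        gene = GeneModel(GenomicInterval("chr1", 12_000, 15_000, "+", "g"))
        peak = GenomicInterval("chr1", 12_900, 13_300, name="p1")
        (cand,) = define_candidates([peak], [gene], cov, flank=500)
        assert cand.status == "kept"

    def test_promoter_overlap_excludes_even_without_signal(self):
        cov = make_coverage()
        gene = GeneModel(GenomicInterval("chr1", 12_000, 15_000, "+", "g"))
        peak = GenomicInterval("chr1", 11_200, 11_400, name="p1")  # in promoter window
        (cand,) = define_candidates([peak], [gene], cov, flank=500)
        assert cand.status == "excluded_gene_overlap"

    def test_no_peaks_empty(self):
        assert define_candidates([], [], make_coverage()) == []

    def test_edge_peak_dropped(self):
        cov = make_coverage(length=2000)
        peak = GenomicInterval("chr1", 0, 400, name="edge")
        assert define_candidates([peak], [], cov, flank=500) == []

    def test_strand_counts_are_window_sums(self):
        cov = make_coverage()
        cov.plus["chr1"][10_000:11_000] = 0.5
        cov.minus["chr1"][10_400:10_600] = 2.0
        peak = GenomicInterval("chr1", 10_300, 10_700, name="p1")
        (cand,) = define_candidates([peak], [], cov, flank=500)
        assert cand.plus_count == pytest.approx(500.0)
        assert cand.minus_count == pytest.approx(400.0)


class TestStrandBalance:
    def test_balanced_sums_both_strands(self):
        c = CandidateEnhancer("x", "chr1", 1000, 500, plus_count=50, minus_count=40)
        strand_balance(c)
        assert c.balance_ratio == pytest.approx(1.25)
        assert c.balanced and c.effective_count == pytest.approx(90)

    def test_over_tenfold_keeps_twice_the_lower(self):
        c = CandidateEnhancer("x", "chr1", 1000, 500, plus_count=100, minus_count=8)
        strand_balance(c)
        assert c.balance_ratio == pytest.approx(12.5)
        assert not c.balanced and c.effective_count == pytest.approx(16)

    def test_both_zero_excluded(self):
        c = CandidateEnhancer("x", "chr1", 1000, 500)
        strand_balance(c)
        assert c.effective_count == 0 and c.status == "excluded_no_evidence"

    def test_single_zero_strand_is_infinite_ratio(self):
        c = CandidateEnhancer("x", "chr1", 1000, 500, plus_count=30, minus_count=0)
        strand_balance(c)
        assert c.balance_ratio == math.inf and c.effective_count == 0

    def test_negative_counts_error(self):
        c = CandidateEnhancer("x", "chr1", 1000, 500, plus_count=-1, minus_count=0)
        with pytest.raises(ValueError):
            strand_balance(c)

    @settings(derandomize=True, max_examples=200)
    @given(
        plus=st.floats(0, 500),
        minus=st.floats(0, 500),
        bump=st.floats(0, 50),
    )
    def test_minor_strand_increase_never_decreases_effective(self, plus, minus, bump):
        lo_key = "minus" if minus <= plus else "plus"
        before = effective_count_rule(plus, minus)
        if lo_key == "minus":
            after = effective_count_rule(plus, min(minus + bump, plus))
        else:
            after = effective_count_rule(min(plus + bump, minus), minus)
        assert after >= before - 1e-9


class TestEvidenceFilter:
    def _cand(self, effective):
        c = CandidateEnhancer("x", "chr1", 1000, 500, plus_count=effective / 2,
                              minus_count=effective / 2)
        return strand_balance(c)

    def test_low_cpm_with_histone_overlap_kept(self):
        c = self._cand(2.0)  # 0.2 cpm at library 10M
        hist = [GenomicInterval("chr1", 900, 1100)]
        apply_evidence_filter([c], min_cpm=1.0, library_size=1e7, histone_peaks=hist)
        assert c.status == "kept" and c.evidence["histone_overlap"]

    def test_high_cpm_without_histone_kept(self):
        c = self._cand(50.0)  # 5 cpm
        apply_evidence_filter([c], min_cpm=1.0, library_size=1e7)
        assert c.status == "kept" and c.evidence["passed_cpm"]

    def test_neither_evidence_excluded(self):
        c = self._cand(2.0)
        apply_evidence_filter([c], min_cpm=1.0, library_size=1e7)
        assert c.status == "excluded_no_evidence"

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            apply_evidence_filter([], min_cpm=-1, library_size=1.0)
        with pytest.raises(ValueError):
            apply_evidence_filter([], min_cpm=1, library_size=0.0)


def brute_force_dips(signal, peak, max_peak_width=7500, dip_threshold=0.5, smooth_bw=50):
    """Independent O(n^2) valley scan over the smoothed profile."""
    if peak.width >= max_peak_width or not np.any(np.asarray(signal) > 0):
        return []
    sm = moving_average(np.asarray(signal, dtype=float), smooth_bw)
    n = len(sm)
    found = []
    i = 1
    while i < n - 1:
        j = i
        while j + 1 < n and sm[j + 1] == sm[i]:
            j += 1
        if sm[i] < sm[i - 1] and j < n - 1 and sm[j + 1] > sm[i]:
            pos = (i + j) // 2
            left = max(sm[:i])
            right = max(sm[j + 1:])
            summit = min(left, right)
            if summit > 0 and sm[pos] < dip_threshold * summit:
                found.append((pos, sm[pos] / summit, summit))
            i = j + 1
        else:
            i += 1
    found.sort(key=lambda t: (t[1], t[0]))
    chosen = []
    for pos, ratio, summit in found:
        ok = True
        for q in chosen:
            lo, hi = min(pos, q), max(pos, q)
            if hi - lo < smooth_bw or max(sm[lo : hi + 1]) < dip_threshold * summit:
                ok = False
        if ok:
            chosen.append(pos)
    return [peak.start + pos for pos in chosen]


class TestDetectDips:
    def test_bimodal_profile_dips_at_center(self):
        x = np.arange(2000)
        profile = 100 * np.exp(-0.5 * ((x - 400) / 150) ** 2)
        profile += 100 * np.exp(-0.5 * ((x - 1600) / 150) ** 2)
        profile += 30.0  # valley floor at the center
        peak = GenomicInterval("chr1", 5000, 7000, name="h1")
        dips = detect_dips(profile, peak)
        assert len(dips) == 1
        assert abs(dips[0].dip_center - 6000) <= 50
        assert dips[0].valley_to_summit_ratio < 0.5

    def test_monotone_profile_has_no_dips(self):
        peak = GenomicInterval("chr1", 0, 1000, name="h")
        assert detect_dips(np.linspace(0, 10, 1000), peak) == []

    def test_wide_peak_returns_empty(self):
        peak = GenomicInterval("chr1", 0, 9000, name="wide")
        assert detect_dips(np.ones(9000), peak) == []

    def test_all_zero_signal_returns_empty(self):
        peak = GenomicInterval("chr1", 0, 1000, name="h")
        assert detect_dips(np.zeros(1000), peak) == []

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle_on_random_profiles(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(500, 5000))
        x = np.arange(n)
        profile = np.zeros(n, dtype=float)
        for _ in range(int(rng.integers(1, 5))):
            c = rng.uniform(0.1 * n, 0.9 * n)
            w = rng.uniform(50, n / 4)
            profile += rng.uniform(10, 100) * np.exp(-0.5 * ((x - c) / w) ** 2)
        profile = rng.poisson(profile).astype(float)
        peak = GenomicInterval("chr1", 1000, 1000 + n, name="h")
        got = [d.dip_center for d in detect_dips(profile, peak)]
        assert got == brute_force_dips(profile, peak)


class TestResolveClusters:
    def _cand(self, name, center, effective):
        c = CandidateEnhancer(name, "chr1", center, 500,
                              plus_count=effective / 2, minus_count=effective / 2)
        return strand_balance(c)

    def test_atac_overlap_wins(self):
        a = self._cand("a", 10_000, 40)
        b = self._cand("b", 10_300, 40)
        # only b's window [9800, 10800) reaches the accessibility peak
        atac = [GenomicInterval("chr1", 10_600, 10_900)]
        resolve_clusters([a, b], atac_peaks=atac)
        assert a.status == "merged_away" and b.status == "kept"

    def test_max_signal_fallback(self):
        a = self._cand("a", 10_000, 40)
        b = self._cand("b", 10_300, 90)
        resolve_clusters([a, b])
        assert a.status == "merged_away" and b.status == "kept"

    def test_singleton_unchanged(self):
        a = self._cand("a", 10_000, 40)
        resolve_clusters([a])
        assert a.status == "kept"

    def test_dip_window_counts_as_support(self):
        from enact.enhancer_calling import DipCall

        a = self._cand("a", 10_000, 90)
        b = self._cand("b", 10_300, 40)
        dip = DipCall("h", "chr1", 10_700, 0.2)  # window only inside b
        resolve_clusters([a, b], dips=[dip])
        assert b.status == "kept" and a.status == "merged_away"

    def test_input_order_invariance(self):
        def run(order_reversed):
            a = self._cand("a", 10_000, 40)
            b = self._cand("b", 10_300, 90)
            c = self._cand("c", 50_000, 10)
            cands = [c, b, a] if order_reversed else [a, b, c]
            resolve_clusters(cands)
            return {x.id: x.status for x in cands}

        assert run(False) == run(True)
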