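import numpy as np
import pytest
from scipy import stats

from enact.core_io import FragmentRecord, GenomicInterval
from enact.motif_activity import (
    PeakCellMatrix,
    build_peak_matrix,
    cluster_specific_motifs,
    motif_deviation_scores,
    motif_enrichment,
)


def toy_matrix(seed=0, n_peaks=100, n_cells=60):
    rng = np.random.default_rng(seed)
    peaks = [
        GenomicInterval("chr1", i * 1000, i * 1000 + 400, ".", f"p{i:03d}",
                        float(rng.uniform(0.3, 0.7)))
        for i in range(n_peaks)
    ]
    counts = rng.poisson(5.0, size=(n_peaks, n_cells))
    return PeakCellMatrix(peaks, [p.score for p in peaks],
                          [f"BC{j:03d}" for j in range(n_cells)], counts)


class TestBuildPeakMatrix:
    def test_insertion_convention(self):
        # start insertion inside the peak, end insertion (end-1) outside
        peaks = [GenomicInterval("chr1", 90, 160, ".", "p0")]
        frags = [FragmentRecord("chr1", 100, 250, "BC1")]
        pcm = build_peak_matrix(frags, peaks, ["BC1"], min_cell_fraction=0.0)
        assert pcm.counts[0, 0] == 1

    def test_rare_peak_dropped(self):
        peaks = [GenomicInterval("chr1", 0, 400, ".", "rare"),
                 GenomicInterval("chr1", 1000, 1400, ".", "common")]
        barcodes = [f"BC{i}" for i in range(200)]
        frags = [FragmentRecord("chr1", 1100, 1200, bc) for bc in barcodes]
        frags.append(FragmentRecord("chr1", 100, 200, "BC0"))  # 1 of 200 = 0.5%
        pcm = build_peak_matrix(frags, peaks, barcodes)
        assert pcm.peak_names == ["common"]

    def test_narrow_peak_discarded_before_counting(self):
        peaks = [GenomicInterval("chr1", 0, 8, ".", "narrow"),
                 GenomicInterval("chr1", 1000, 1400, ".", "wide")]
        frags = [FragmentRecord("chr1", 2, 1100, "BC1")]
        pcm = build_peak_matrix(frags, peaks, ["BC1"], min_cell_fraction=0.0)
        assert pcm.peak_names == ["wide"]

    def test_no_barcodes_errors(self):
        with pytest.raises(ValueError):
            build_peak_matrix([], [], [])


class TestDeviationScores:
    def test_aggregate_proportional_cell_has_zero_raw(self):
        pcm = toy_matrix(seed=1)
        # cell 0 proportional to the other cells' aggregate (and hence to
        # the full aggregate, which is a positive multiple of it)
        counts = pcm.counts.copy().astype(float)
        base = counts[:, 1:].sum(axis=1)
        counts[:, 0] = base / base.sum() * counts[:, 0].sum()
        pcm2 = PeakCellMatrix(pcm.peaks, pcm.gc, pcm.barcodes, counts)
        motifs = {"M": [f"p{i:03d}" for i in range(0, 30, 3)]}
        dev = motif_deviation_scores(pcm2, motifs, B=10, seed=0)
        assert abs(dev.raw[0, 0]) < 1e-9

    def test_doubling_counts_leaves_raw_unchanged(self):
        pcm = toy_matrix(seed=2)
        motifs = {"M": [f"p{i:03d}" for i in range(10)]}
        d1 = motif_deviation_scores(pcm, motifs, B=12, seed=5)
        pcm2 = PeakCellMatrix(pcm.peaks, pcm.gc, pcm.barcodes, pcm.counts * 2)
        d2 = motif_deviation_scores(pcm2, motifs, B=12, seed=5)
        np.testing.assert_allclose(d1.raw, d2.raw, atol=1e-12)

    def test_observed_counts_conserved(self):
        pcm = toy_matrix(seed=3)
        idx = list(range(0, 20))
        motifs = {"M": [f"p{i:03d}" for i in idx]}
        dev = motif_deviation_scores(pcm, motifs, B=10, seed=1)
        sub = pcm.counts[idx].astype(float)
        expected = sub.sum(axis=0).sum()
        # reconstruct observed from raw: obs = raw * exp + exp
        cell_tot = pcm.counts.sum(axis=0)
        exp = sub.sum() / pcm.counts.sum() * cell_tot
        obs = dev.raw[0] * exp + exp
        assert obs.sum() == pytest.approx(expected)

    def test_seeded_determinism(self):
        pcm = toy_matrix(seed=4)
        motifs = {"M": [f"p{i:03d}" for i in range(15)]}
        a = motif_deviation_scores(pcm, motifs, B=15, seed=9).z
        b = motif_deviation_scores(pcm, motifs, B=15, seed=9).z
        np.testing.assert_array_equal(a, b)

    def test_planted_group_scores_highest(self):
        """Cells with doubled counts in motif peaks get the top z-scores."""
        rng = np.random.default_rng(6)
        pcm = toy_matrix(seed=6, n_peaks=120, n_cells=90)
        motif_peaks = [f"p{i:03d}" for i in range(0, 120, 6)]
        counts = pcm.counts.copy()
        midx = [int(nm[1:]) for nm in motif_peaks]
        counts[np.ix_(midx, range(30))] = rng.poisson(10.0, size=(len(midx), 30))
        pcm = PeakCellMatrix(pcm.peaks, pcm.gc, pcm.barcodes, counts)
        motifs = {"M": motif_peaks}
        for i in range(8):
            motifs[f"R{i}"] = list(rng.choice(pcm.peak_names, 20, replace=False))
        dev = motif_deviation_scores(pcm, motifs, B=30, seed=2)
        labels = {bc: ("hot" if j < 30 else "rest") for j, bc in enumerate(pcm.barcodes)}
        table = cluster_specific_motifs(dev, labels, effect_threshold=0.5, fdr=0.01)
        hot = table[table.cluster == "hot"].sort_values("effect", ascending=False)
        assert hot.iloc[0]["motif"] == "M"
        assert hot.iloc[0]["significant"]

    def test_small_B_rejected(self):
        pcm = toy_matrix()
        with pytest.raises(ValueError):
            motif_deviation_scores(pcm, {"M": ["p000"]}, B=5)


class TestClusterSpecificMotifs:
    def test_single_cluster_errors(self):
        pcm = toy_matrix(seed=7)
        dev = motif_deviation_scores(pcm, {"M": ["p000", "p001"]}, B=10, seed=0)
        with pytest.raises(ValueError):
            cluster_specific_motifs(dev, {bc: "only" for bc in dev.barcodes})

    def test_permuted_labels_yield_nothing_at_strict_fdr(self):
        rng = np.random.default_rng(8)
        pcm = toy_matrix(seed=8, n_cells=80)
        motifs = {f"M{i}": list(rng.choice(pcm.peak_names, 15, replace=False))
                  for i in range(6)}
        dev = motif_deviation_scores(pcm, motifs, B=20, seed=0)
        hits = 0
        for rep in range(20):
            labs = rng.permutation(["A"] * 40 + ["B"] * 40)
            table = cluster_specific_motifs(
                dev, dict(zip(dev.barcodes, labs)), effect_threshold=1.5, fdr=1e-4
            )
            if table["significant"].any():
                hits += 1
        assert hits <= 1


class TestMotifEnrichment:
    def _regions(self, n, offset=0):
        return [GenomicInterval("chr1", offset + i * 1000, offset + i * 1000 + 100,
                                ".", f"r{offset + i}") for i in range(n)]

    def test_odds_ratio_hand_value(self):
        targets = self._regions(20)
        background = self._regions(100, offset=1_000_000)
        sites = {"M": [GenomicInterval("chr1", t.start, t.end) for t in targets[:10]]
                 + [GenomicInterval("chr1", b.start, b.end) for b in background[:10]]}
        table = motif_enrichment(targets, background, sites)
        assert table.iloc[0]["odds_ratio"] == pytest.approx(9.0)
        # p agrees with the scipy Fisher oracle on the same 2x2 table
        _, p = stats.fisher_exact([[10, 10], [10, 90]])
        assert table.iloc[0]["pvalue"] == pytest.approx(p)

    def test_no_sites_anywhere(self):
        table = motif_enrichment(self._regions(5), self._regions(10, offset=1_000_000),
                                 {"M": []})
        assert table.iloc[0]["pvalue"] == 1.0
        assert np.isfinite(table.iloc[0]["odds_ratio"])

    def test_extreme_enrichment_significant(self):
        targets = self._regions(20)
        background = self._regions(100, offset=1_000_000)
        sites = {"M": [GenomicInterval("chr1", t.start, t.end) for t in targets]}
        table = motif_enrichment(targets, background, sites)
        _, p = stats.fisher_exact([[20, 0], [0, 100]])
        assert table.iloc[0]["pvalue"] == pytest.approx(p)
        assert table.iloc[0]["pvalue"] < 1e-6

    def test_empty_inputs_error(self):
        with pytest.raises(ValueError):
            motif_enrichment([], self._regions(5), {})
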