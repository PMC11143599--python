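import numpy as np
import pytest

import enact


@pytest.fixture(scope="session")
def truth():
    """Default synthetic locus set (2 x 2 Mb, 60 genes, 120 enhancers, 80 decoys)."""
    return enact.simulate_locus_set(seed=1)


@pytest.fixture(scope="session")
def coverage(truth):
    return enact.simulate_nascent_coverage(truth, "DMSO", seed=2)


@pytest.fixture(scope="session")
def histone_signal(truth):
    return enact.simulate_histone_coverage(truth, seed=3)


@pytest.fixture(scope="session")
def fragments_and_labels(truth):
    return enact.simulate_fragments(truth, seed=9)


@pytest.fixture(scope="session")
def cell_metrics(truth, fragments_and_labels):
    frags, _ = fragments_and_labels
    tss = [(g.model.body.chrom, g.model.tss) for g in truth.genes]
    return enact.per_cell_metrics(frags, truth.peaks, truth.blacklist, tss)


@pytest.fixture(scope="session")
def called_enhancers(truth, coverage, histone_signal):
    genes = [g.model for g in truth.genes]
    return enact.call_enhancers(
        truth.peaks, genes, coverage,
        histone_peaks=truth.histone_peaks, histone_signal=histone_signal,
    )


@pytest.fixture(scope="session")
def peak_matrix(truth, fragments_and_labels, cell_metrics):
    frags, _ = fragments_and_labels
    kept = enact.qc_filter(cell_metrics)
    return enact.build_peak_matrix(frags, truth.peaks, kept)


def nb_counts(rng: np.random.Generator, mu, dispersion: float, shape) -> np.ndarray:
    """Gamma-Poisson (negative binomial) counts for simulations."""
    mu = np.broadcast_to(np.asarray(mu, dtype=float), shape)
    return rng.poisson(rng.gamma(1.0 / dispersion, dispersion * mu))
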