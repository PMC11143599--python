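"""Region quantification and differential nascent-activity statistics.

The differential machinery is a negative-binomial quasi-likelihood
workflow for small-replicate count data:

* counts are quantified from base-level coverage with an optional
  per-position cap (saturating PCR/pileup artifacts) and exon masking for
  gene bodies;
* library composition is normalized with RLE (median-of-ratios) size
  factors;
* per-feature NB dispersions maximize a Cox-Reid adjusted profile
  likelihood on a grid and are shrunk toward a mean-binned trend by a
  weighted-likelihood empirical-Bayes prior;
* two-group contrasts use a quasi-likelihood F-test: the deviance drop of
  the contrast over an empirical-Bayes moderated quasi-dispersion
  (moment-matched scaled-F prior on the residual deviance ratios, with
  the prior df added to the denominator df);
* any-change tests across >= 2 conditions use a likelihood-ratio
  chi-square test of the per-condition-means model against the intercept
  model;
* multiplicity is controlled with Benjamini-Hochberg.

None of this is bit-matched to any existing package; it is validated by
its operating characteristics (null type-I error, power on planted fold
changes) in the test suite.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from sklearn.cluster import KMeans

from .core_io import CountMatrix, GenomicInterval, StrandedCoverage
from .enhancer_calling import effective_count_rule

DISPERSION_FLOOR = 1e-6
QL_S2_FLOOR = 1e-8


# ---------------------------------------------------------------------------
# quantification
# ---------------------------------------------------------------------------


def quantify_regions(
    coverage: StrandedCoverage,
    regions: Sequence[GenomicInterval],
    per_position_cap: float | None = None,
    exon_mask: Mapping[str, Sequence[GenomicInterval]] | None = None,
    strand_mode: str = "both",
) -> np.ndarray:
    """Count signal per region, one value per input region.

    ``per_position_cap`` clips the per-base, per-strand signal before
    summation.  ``exon_mask`` maps region names to exon intervals whose
    bases are excluded (gene bodies are quantified without exons).
    ``strand_mode``:

    * ``both`` — plus + minus summed;
    * ``sense`` — the region's own strand only (requires +/- strand);
    * ``effective`` — the bidirectionality rule applied to the per-strand
      sums (balanced: sum; over-tenfold imbalanced: 2 x lower strand).
    """
    if per_position_cap is not None and per_position_cap < 1:
        raise ValueError("per_position_cap must be >= 1")
    if strand_mode not in ("both", "sense", "effective"):
        raise ValueError(f"unknown strand_mode {strand_mode!r}")

    out = np.zeros(len(regions))
    for i, region in enumerate(regions):
        mask = np.ones(region.width, dtype=bool)
        if exon_mask and region.name in exon_mask:
            for ex in exon_mask[region.name]:
                lo = max(ex.start, region.start) - region.start
                hi = min(ex.end, region.end) - region.start
                if hi > lo:
                    mask[lo:hi] = False

        def strand_sum(track: Mapping[str, np.ndarray]) -> float:
            v = track.get(region.chrom)
            if v is None:
                return 0.0
            seg = v[region.start : region.end][mask]
            if per_position_cap is not None:
                seg = np.minimum(seg, per_position_cap)
            return float(seg.sum())

        if strand_mode == "both":
            out[i] = strand_sum(coverage.plus) + strand_sum(coverage.minus)
        elif strand_mode == "sense":
            if region.strand not in ("+", "-"):
                raise ValueError(f"region {region.name!r} lacks a strand for sense mode")
            out[i] = strand_sum(coverage.strand(region.strand))
        else:
            out[i] = effective_count_rule(
                strand_sum(coverage.plus), strand_sum(coverage.minus)
            )
    return out


def filter_low_expression(
    matrix: CountMatrix,
    cutoff: float,
    min_samples: int = 2,
    unit: str = "cpm",
    rpkm_cutoff: float | None = None,
) -> CountMatrix:
    """Drop features not reaching ``cutoff`` in at least ``min_samples`` samples.

    ``unit`` selects the scale of the primary cutoff (``cpm`` or ``raw``
    counts); ``rpkm_cutoff`` adds a joint length-normalized requirement
    and needs feature lengths.
    """
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")
    if unit not in ("cpm", "raw"):
        raise ValueError(f"unknown unit {unit!r}")
    values = matrix.cpm() if unit == "cpm" else matrix.counts
    keep = (values >= cutoff).sum(axis=1) >= min_samples
    if rpkm_cutoff is not None:
        if matrix.feature_lengths is None:
            raise ValueError("rpkm cutoff requires feature lengths")
        keep &= (matrix.rpkm() >= rpkm_cutoff).sum(axis=1) >= min_samples
    return matrix.subset(keep)


def rle_size_factors(matrix: CountMatrix) -> dict[str, float]:
    """Median-of-ratios (RLE) size factors, rescaled to geometric mean 1.

    The reference is the per-feature geometric mean across samples;
    features with a zero in any sample are excluded from the reference.
    """
    counts = matrix.counts
    allpos = np.all(counts > 0, axis=1)
    if not np.any(allpos):
        raise ValueError(
            "no feature has all-positive counts; RLE needs a pseudo-reference"
        )
    sub = counts[allpos]
    log_ref = np.mean(np.log(sub), axis=1)
    log_factors = np.median(np.log(sub) - log_ref[:, None], axis=0)
    log_factors -= log_factors.mean()  # geometric mean 1
    return dict(zip(matrix.sample_ids, np.exp(log_factors)))


# ---------------------------------------------------------------------------
# NB GLM internals
# ---------------------------------------------------------------------------


def _nb_group_fit(
    y: np.ndarray, offsets: np.ndarray, phi: np.ndarray, groups: list[np.ndarray]
) -> tuple[np.ndarray, np.ndarray]:
    """Fit per-group NB means with log link and offsets.

    Returns (beta, mu): ``beta`` is features x groups, ``mu`` is the
    fitted mean matrix features x samples.  Each group coefficient is the
    1-D NB maximum-likelihood solution found by Newton iteration of the
    score equation sum (y - mu) / (1 + phi * mu) = 0.
    """
    n_feat, n_samp = y.shape
    beta = np.zeros((n_feat, len(groups)))
    mu = np.zeros_like(y, dtype=float)
    for gi, idx in enumerate(groups):
        yg = y[:, idx]
        og = offsets[idx]
        norm = yg / np.exp(og)[None, :]
        b = np.log(np.maximum(norm.mean(axis=1), 1e-8))
        for _ in range(50):
            m = np.exp(b[:, None] + og[None, :])
            w = 1.0 + phi[:, None] * m
            score = ((yg - m) / w).sum(axis=1)
            info = (m * (1.0 + phi[:, None] * yg) / w**2).sum(axis=1)
            step = score / np.maximum(info, 1e-12)
            step = np.clip(step, -5.0, 5.0)
            b = b + step
            if np.max(np.abs(step)) < 1e-10:
                break
        beta[:, gi] = b
        mu[:, idx] = np.exp(b[:, None] + og[None, :])
    return beta, mu


def _nb_deviance(y: np.ndarray, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Per-feature NB residual deviance (Poisson limit at phi == 0)."""
    mu = np.maximum(mu, 1e-12)
    phi = phi[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        term1 = np.where(y > 0, y * np.log(np.maximum(y, 1e-300) / mu), 0.0)
        nbterm = np.where(
            phi > 0,
            (y + 1.0 / np.maximum(phi, 1e-300))
            * np.log((1.0 + phi * y) / (1.0 + phi * mu)),
            y - mu,
        )
    return 2.0 * (term1 - nbterm).sum(axis=1)


def estimate_dispersions(
    y: np.ndarray,
    offsets: np.ndarray,
    groups: list[np.ndarray],
    prior_df: float = 10.0,
    grid_size: int = 61,
) -> np.ndarray:
    """Trended, empirical-Bayes-shrunk NB dispersions.

    Per-feature dispersions maximize a Cox-Reid adjusted profile
    likelihood on a log-spaced grid, shrunk toward a mean-binned trend by
    adding ``prior_df / residual_df`` copies of the bin-average profile
    likelihood (weighted-likelihood empirical Bayes).  Fitted group means
    are the phi-independent ML means (exact under equal offsets within a
    group).  Estimates are floored at ``DISPERSION_FLOOR``.
    """
    n_feat, n_samp = y.shape
    df = max(n_samp - len(groups), 1)
    _, mu = _nb_group_fit(y, offsets, np.zeros(n_feat), groups)
    mu = np.maximum(mu, 1e-8)
    grid = np.exp(np.linspace(np.log(1e-4), np.log(5.0), grid_size))

    ll = np.empty((n_feat, grid_size))
    for j, phi in enumerate(grid):
        r = 1.0 / phi
        ll[:, j] = (
            special.gammaln(y + r)
            - special.gammaln(r)
            + y * np.log(phi * mu / (1.0 + phi * mu))
            - r * np.log1p(phi * mu)
        ).sum(axis=1)
        # Cox-Reid adjustment: -1/2 log det of the per-group information
        for idx in groups:
            info = (mu[:, idx] / (1.0 + phi * mu[:, idx])).sum(axis=1)
            ll[:, j] -= 0.5 * np.log(info + 1e-300)

    # trend: features binned by abundance share a bin-average likelihood
    logmean = np.log(mu.mean(axis=1) + 0.5)
    n_bins = min(10, max(1, n_feat // 50))
    edges = np.quantile(logmean, np.linspace(0, 1, n_bins + 1)[1:-1])
    bin_of = np.searchsorted(edges, logmean, side="right")
    prior_n = prior_df / df
    phi_hat = np.empty(n_feat)
    for b in np.unique(bin_of):
        members = np.flatnonzero(bin_of == b)
        ll_bar = ll[members].mean(axis=0)
        weighted = ll[members] + prior_n * ll_bar[None, :]
        phi_hat[members] = grid[np.argmax(weighted, axis=1)]
    return np.maximum(phi_hat, DISPERSION_FLOOR)


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        x = max(x, 1e-8)
        if abs(dif) < 1e-10 * x:
            break
    return x


def _squeeze_var(s2: np.ndarray, df: float) -> tuple[np.ndarray, float]:
    """Empirical-Bayes moderation of variances toward a scaled-F prior.

    Moment-matching on log variances: returns the posterior variances and
    the estimated prior df (possibly inf when the s2 are homogeneous).
    """
    ok = s2 > QL_S2_FLOOR
    if ok.sum() < 3:
        return np.maximum(s2, QL_S2_FLOOR), np.inf
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    evar = np.var(e, ddof=1) - float(special.polygamma(1, df / 2.0))
    if evar <= 0:
        d0 = np.inf
        s20 = float(np.exp(np.mean(e)))
    else:
        d0 = 2.0 * _trigamma_inverse(evar)
        s20 = float(
            np.exp(np.mean(e) + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
        )
    s2f = np.maximum(s2, 0.0)
    if np.isfinite(d0):
        post = (d0 * s20 + df * s2f) / (d0 + df)
    else:
        post = np.full_like(s2f, s20)
    return np.maximum(post, QL_S2_FLOOR), d0


def _offsets(matrix: CountMatrix, size_factors: Mapping[str, float] | None) -> np.ndarray:
    # RLE size factors already capture sequencing depth (median of ratios
    # against the geometric-mean reference), so they replace, not rescale,
    # the library-size offset.
    if size_factors is not None:
        return np.log(np.array([size_factors[s] for s in matrix.sample_ids]))
    return np.log(np.maximum(matrix.library_sizes, 1.0))


# ---------------------------------------------------------------------------
# differential tests
# ---------------------------------------------------------------------------


def nbql_test(
    matrix: CountMatrix,
    design: Sequence[str],
    contrast: tuple[str, str] | None = None,
    size_factors: Mapping[str, float] | None = None,
    dispersion_prior_df: float = 10.0,
) -> pd.DataFrame:
    """Two-group NB quasi-likelihood F-test.

    ``design`` assigns a condition label to each sample; ``contrast``
    names (reference, treatment); the log2 fold change is treatment over
    reference.  Returns a frame with columns feature, log2FC, stat,
    pvalue, qvalue.
    """
    design = list(design)
    if len(design) != len(matrix.sample_ids):
        raise ValueError("design length must match the number of samples")
    levels = sorted(set(design))
    if contrast is None:
        if len(levels) != 2:
            raise ValueError("contrast required when design has != 2 levels")
        contrast = (levels[0], levels[1])
    ref, trt = contrast
    sel = [i for i, d in enumerate(design) if d in (ref, trt)]
    groups = [
        np.array([j for j, i in enumerate(sel) if design[i] == ref]),
        np.array([j for j, i in enumerate(sel) if design[i] == trt]),
    ]
    if min(len(g) for g in groups) < 2:
        raise ValueError("need >= 2 samples per condition in the contrast")

    y = matrix.counts[:, sel]
    offsets = _offsets(matrix, size_factors)[sel]
    n_feat, n_samp = y.shape
    df_resid = n_samp - 2
    allzero = y.sum(axis=1) == 0

    phi = estimate_dispersions(y, offsets, groups, prior_df=dispersion_prior_df)
    beta_full, mu_full = _nb_group_fit(y, offsets, phi, groups)
    _, mu_null = _nb_group_fit(y, offsets, phi, [np.arange(n_samp)])
    dev_full = _nb_deviance(y, mu_full, phi)
    dev_null = _nb_deviance(y, mu_null, phi)

    s2 = np.maximum(dev_full, 0.0) / df_resid
    s2_post, d0 = _squeeze_var(s2, df_resid)
    df_denom = df_resid + (d0 if np.isfinite(d0) else 1e6)
    fstat = np.maximum(dev_null - dev_full, 0.0) / 1.0 / s2_post
    pvals = stats.f.sf(fstat, 1, df_denom)
    pvals[allzero] = 1.0
    fstat[allzero] = 0.0

    log2fc = (beta_full[:, 1] - beta_full[:, 0]) / np.log(2.0)
    log2fc[allzero] = 0.0
    return pd.DataFrame(
        {
            "feature": matrix.feature_ids,
            "log2FC": log2fc,
            "stat": fstat,
            "pvalue": pvals,
            "qvalue": bh_fdr(pvals),
        }
    )


def lrt_any_change(
    matrix: CountMatrix,
    design: Sequence[str],
    size_factors: Mapping[str, float] | None = None,
    dispersion_prior_df: float = 10.0,
) -> pd.DataFrame:
    """Any-change likelihood-ratio test across >= 2 conditions.

    Per-condition-means NB model against the intercept model; p-values
    from chi-square with (levels - 1) df.  The reported log2FC is the
    largest absolute pairwise log2 difference of condition means.
    """
    design = list(design)
    if len(design) != len(matrix.sample_ids):
        raise ValueError("design length must match the number of samples")
    levels = sorted(set(design))
    if len(levels) < 2:
        raise ValueError("need >= 2 conditions for an any-change test")
    groups = [
        np.array([i for i, d in enumerate(design) if d == lv]) for lv in levels
    ]
    y = matrix.counts
    offsets = _offsets(matrix, size_factors)
    allzero = y.sum(axis=1) == 0

    phi = estimate_dispersions(y, offsets, groups, prior_df=dispersion_prior_df)
    beta_full, mu_full = _nb_group_fit(y, offsets, phi, groups)
    _, mu_null = _nb_group_fit(y, offsets, phi, [np.arange(y.shape[1])])
    lrt = np.maximum(
        _nb_deviance(y, mu_null, phi) - _nb_deviance(y, mu_full, phi), 0.0
    )
    pvals = stats.chi2.sf(lrt, len(levels) - 1)
    pvals[allzero] = 1.0
    lrt[allzero] = 0.0
    spread = (beta_full.max(axis=1) - beta_full.min(axis=1)) / np.log(2.0)
    spread[allzero] = 0.0
    return pd.DataFrame(
        {
            "feature": matrix.feature_ids,
            "log2FC": spread,
            "stat": lrt,
            "pvalue": pvals,
            "qvalue": bh_fdr(pvals),
        }
    )


# ---------------------------------------------------------------------------
# clustering and multiplicity
# ---------------------------------------------------------------------------


def kmeans_profiles(z_matrix: np.ndarray, k: int = 6, seed: int = 0) -> np.ndarray:
    """k-means on standardized profiles; labels renumbered by cluster size.

    Uses k-means++ with 25 restarts under a fixed seed; the largest
    cluster gets label 0, the next 1, and so on (ties break on the
    original k-means label).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    z_matrix = np.asarray(z_matrix, dtype=float)
    if k > z_matrix.shape[0]:
        raise ValueError("k exceeds the number of features")
    km = KMeans(n_clusters=k, init="k-means++", n_init=25, random_state=seed)
    raw = km.fit_predict(z_matrix)
    sizes = np.bincount(raw, minlength=k)
    order = np.argsort(-sizes, kind="stable")
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(k)
    return remap[raw]


def bh_fdr(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving.

    q_(i) = min over j >= i of p_(j) * m / j on the sorted scale, capped
    at 1 and mapped back to the input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q
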