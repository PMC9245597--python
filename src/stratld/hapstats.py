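"""Estimators on haplotype panels: windowed pairwise-difference correlations,
the time-stratified joint LD statistic, and supporting inference utilities.

The joint LD statistic generalises the classical ratio-of-expectations
``sigma_d^2`` to two sampling timepoints: for a site pair (A, B) it
accumulates ``D(0) * D(t)`` in the numerator and
``p_A(0)(1-p_A(t)) * p_B(0)(1-p_B(t))`` in the denominator, where
``D(t) = p_AB(t) - p_A(t) p_B(t)`` is computed within the sample from
timepoint ``t``.  Per-bin estimates take the ratio of sums, mirroring the
convention used for ``sigma_d^2`` estimation, and can become a poor
approximation to E[r^2-like quantities] at low allele frequencies — hence the
pooled minor-allele-frequency filter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .haplotypes import HaplotypeMatrix

__all__ = [
    "WindowPair",
    "pairwise_diff_in_windows",
    "paired_window_corr",
    "ld_products",
    "sigma_t2_hat",
    "combine_sigma_t2",
    "sign_test_curves",
    "pearson_se",
    "default_bins",
]


@dataclass(frozen=True)
class WindowPair:
    """A pair of non-overlapping windows and their summaries."""

    start_a: int
    end_a: int
    start_b: int
    end_b: int
    r_morgans: float
    pi_a: float
    pi_b: float

    def __post_init__(self):
        if self.r_morgans < 0 or self.pi_a < 0 or self.pi_b < 0:
            raise ValueError("distances and difference counts must be >= 0")


def pearson_se(r: float, n: int) -> float:
    """Asymptotic standard error of a Pearson correlation, sqrt((1-r^2)/(n-2))."""
    if n < 3:
        raise ValueError("need n >= 3 for the asymptotic Pearson SE")
    if abs(r) > 1:
        raise ValueError("|r| must be <= 1")
    return float(np.sqrt((1.0 - r * r) / (n - 2)))


def _site_diff(g_i, ploidy_i, g_j, ploidy_j):
    """Per-site expected difference between two rows; NaN where either is missing.

    Haploid vs haploid: 0/1 mismatch indicator.  Haploid vs unphased diploid:
    the probability that a haplotype drawn at random from the diploid differs
    (0.5 at a heterozygous site, 1 for an opposing homozygote, else 0).
    """
    if ploidy_i == "D" and ploidy_j == "D":
        raise ValueError("diploid-vs-diploid comparisons are not supported")
    if ploidy_i == "D":
        g_i, g_j = g_j, g_i
        ploidy_i, ploidy_j = ploidy_j, ploidy_i
    miss = (g_i < 0) | (g_j < 0)
    if ploidy_j == "H":
        d = (g_i != g_j).astype(float)
    else:
        d = np.abs(g_j - 2.0 * g_i) / 2.0  # het -> 0.5, opposing hom -> 1
    d[miss] = np.nan
    return d


def pairwise_diff_in_windows(
    haps: HaplotypeMatrix, hap_i: int, hap_j: int, window_bp: int, chrom=None
):
    """Weighted pairwise-difference counts in non-overlapping basepair windows.

    Windows are 0-based half-open ``[k*L, (k+1)*L)``.  Returns
    ``(diffs, callable_sites)`` arrays over windows; missing sites contribute
    nothing to the difference count and are excluded from the callable count.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be > 0")
    n = haps.n_rows
    if not (0 <= hap_i < n and 0 <= hap_j < n) or hap_i == hap_j:
        raise ValueError("hap_i and hap_j must be distinct valid row indices")
    if chrom is None:
        chroms = list(dict.fromkeys(haps.chrom))
        if len(chroms) != 1:
            raise ValueError("multiple chromosomes present; pass chrom=")
        chrom = chroms[0]
    sel = haps.chrom == chrom
    pos = haps.positions_bp[sel]
    d = _site_diff(
        haps.genotypes[hap_i, sel], haps.ploidy[hap_i],
        haps.genotypes[hap_j, sel], haps.ploidy[hap_j],
    )
    n_windows = int(pos.max() // window_bp) + 1 if pos.size else 0
    diffs = np.zeros(n_windows)
    callable_sites = np.zeros(n_windows, dtype=np.int64)
    widx = (pos // window_bp).astype(np.int64)
    ok = ~np.isnan(d)
    np.add.at(diffs, widx[ok], d[ok])
    np.add.at(callable_sites, widx[ok], 1)
    return diffs, callable_sites


def paired_window_corr(
    window_pi: np.ndarray,
    window_map: np.ndarray,
    r_targets,
    n_mc: int = 5000,
    rng_seed=0,
    window_chrom=None,
) -> pd.DataFrame:
    """Monte-Carlo correlation of per-window difference counts at target distances.

    For each target recombination distance ``r`` (Morgans): draw ``n_mc``
    anchor windows uniformly, pick a search direction at random (trying the
    other direction if the first leaves the anchor's chromosome map span),
    take as partner the window on the same chromosome whose midpoint genetic
    position is closest to the target, and report the Pearson correlation of
    ``(pi_anchor, pi_partner)`` across draws with its asymptotic SE.  Draws
    with no valid partner are dropped; targets unreachable from every anchor
    are reported as missing (NaN), not raised.
    """
    if n_mc < 10:
        raise ValueError("n_mc must be >= 10")
    pi = np.asarray(window_pi, dtype=float)
    gmap = np.asarray(window_map, dtype=float)
    if pi.size != gmap.size or pi.size < 2:
        raise ValueError("need >= 2 windows with matching pi and map arrays")
    n_win = pi.size
    if window_chrom is None:
        code = np.zeros(n_win, dtype=np.int64)
    else:
        _, code = np.unique(np.asarray(window_chrom), return_inverse=True)
    r_arr = np.atleast_1d(np.asarray(r_targets, dtype=float))

    # sort windows by (chromosome, map position) and search on a combined key
    # so every lookup stays inside the anchor's chromosome block
    order = np.lexsort((gmap, code))
    gmap_s = gmap[order]
    code_s = code[order]
    n_blocks = int(code.max()) + 1
    block_start = np.searchsorted(code_s, np.arange(n_blocks))
    block_end = np.searchsorted(code_s, np.arange(n_blocks), side="right") - 1
    lo = gmap_s[block_start]
    hi = gmap_s[block_end]
    big = (gmap.max() - gmap.min()) + (r_arr.max() if r_arr.size else 0.0) * 2 + 1.0
    key_s = code_s * big + gmap_s

    rng = np.random.default_rng(rng_seed)
    rows = []
    for r in r_arr:
        anchors = rng.integers(0, n_win, n_mc)
        ac = code[anchors]
        sign = np.where(rng.random(n_mc) < 0.5, 1.0, -1.0)
        target = gmap[anchors] + sign * r
        out = (target < lo[ac]) | (target > hi[ac])
        target[out] = gmap[anchors[out]] - sign[out] * r
        ok = (target >= lo[ac]) & (target <= hi[ac])
        if r == 0:
            partners = anchors.copy()
        else:
            ok &= block_end[ac] > block_start[ac]  # single-window chromosomes have no partner
            j = np.searchsorted(key_s, ac * big + target)
            j = np.clip(j, block_start[ac] + 1, block_end[ac])
            left_closer = (target - gmap_s[j - 1]) <= (gmap_s[j] - target)
            best = np.where(left_closer, j - 1, j)
            other = np.where(left_closer, j, j - 1)
            # never pair a window with itself at r > 0
            best = np.where(order[best] == anchors, other, best)
            partners = order[best]
            ok &= partners != anchors
        a, b = anchors[ok], partners[ok]
        n_pairs = int(ok.sum())
        if n_pairs < 3:
            rows.append((r, np.nan, np.nan, n_pairs))
            continue
        if np.std(pi[a]) == 0 or np.std(pi[b]) == 0:
            corr = 1.0 if np.array_equal(pi[a], pi[b]) else np.nan
        else:
            corr = float(stats.pearsonr(pi[a], pi[b]).statistic)
        rows.append((r, corr, pearson_se(corr, n_pairs) if np.isfinite(corr) else np.nan, n_pairs))
    return pd.DataFrame(rows, columns=["r_target", "corr", "se", "n_pairs"])


def default_bins(r_min: float = 1e-5, r_max: float = 1e-3, n_bins: int = 30) -> np.ndarray:
    """Log-spaced genetic-distance bin edges in Morgans."""
    return np.logspace(np.log10(r_min), np.log10(r_max), n_bins + 1)


def _hap_only(haps: HaplotypeMatrix, label: str) -> np.ndarray:
    if np.any(haps.ploidy != "H"):
        raise ValueError(f"{label} panel must contain phased/haploid rows only")
    return haps.genotypes


def ld_products(modern: HaplotypeMatrix, ancient: HaplotypeMatrix, maf_min: float = 0.05):
    """Per-site-pair cross-timepoint LD products after the pooled-MAF filter.

    Returns ``(distance, numerator, denominator)`` arrays over retained site
    pairs, where numerator ``= D(0) D(t)`` and denominator
    ``= p_A(0)(1-p_A(t)) p_B(0)(1-p_B(t))``.  Sites whose pooled minor-allele
    fraction across the two timepoints is not strictly above ``maf_min`` are
    excluded.  Both inputs must cover the same sites in the same order.
    """
    if modern.n_sites != ancient.n_sites or modern.n_sites == 0:
        raise ValueError("modern and ancient matrices must share a non-empty site set")
    if not np.array_equal(modern.positions_bp, ancient.positions_bp):
        raise ValueError("modern and ancient matrices must be site-aligned")
    x0 = _hap_only(modern, "modern").astype(float)
    xt = _hap_only(ancient, "ancient").astype(float)

    d0, t0 = modern.allele_counts()
    dt_, tt_ = ancient.allele_counts()
    with np.errstate(invalid="ignore", divide="ignore"):
        pooled = (d0 + dt_) / (t0 + tt_)
    keep = np.minimum(pooled, 1.0 - pooled) > maf_min
    if not np.any(keep):
        return (np.array([]),) * 3

    x0 = x0[:, keep]
    xt = xt[:, keep]
    gmap = modern.map_pos[keep]
    p0 = x0.mean(axis=0)
    pt = xt.mean(axis=0)
    n0 = x0.shape[0]
    nt = xt.shape[0]
    # within-timepoint LD coefficient for every site pair
    d_mat0 = x0.T @ x0 / n0 - np.outer(p0, p0)
    d_matt = xt.T @ xt / nt - np.outer(pt, pt)
    num = d_mat0 * d_matt
    den = np.outer(p0 * (1.0 - pt), p0 * (1.0 - pt))
    dist = np.abs(gmap[:, None] - gmap[None, :])
    iu = np.triu_indices(gmap.size, k=1)
    return dist[iu], num[iu], den[iu]


def sigma_t2_hat(
    modern: HaplotypeMatrix,
    ancient: HaplotypeMatrix,
    maf_min: float = 0.05,
    bins: np.ndarray | None = None,
) -> pd.DataFrame:
    """Binned ratio-of-sums estimator of the time-stratified joint LD statistic.

    ``bins`` are genetic-distance bin edges in Morgans (default: 30 log-spaced
    bins over (1e-5, 1e-3)).  Bins with zero denominator are reported with a
    NaN estimate rather than raised.
    """
    if bins is None:
        bins = default_bins()
    dist, num, den = ld_products(modern, ancient, maf_min=maf_min)
    return combine_sigma_t2([(dist, num, den)], bins)


def combine_sigma_t2(products, bins: np.ndarray) -> pd.DataFrame:
    """Pool ``ld_products`` outputs (e.g. across replicates) into binned estimates."""
    bins = np.asarray(bins, dtype=float)
    nb = bins.size - 1
    num_sum = np.zeros(nb)
    den_sum = np.zeros(nb)
    n_pairs = np.zeros(nb, dtype=np.int64)
    for dist, num, den in products:
        if len(dist) == 0:
            continue
        which = np.digitize(dist, bins) - 1
        ok = (which >= 0) & (which < nb)
        np.add.at(num_sum, which[ok], num[ok])
        np.add.at(den_sum, which[ok], den[ok])
        np.add.at(n_pairs, which[ok], 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        est = np.where(den_sum > 0, num_sum / den_sum, np.nan)
    return pd.DataFrame(
        {
            "bin_left": bins[:-1],
            "bin_right": bins[1:],
            "sigma_t2": est,
            "n_pairs": n_pairs,
            "num_sum": num_sum,
            "den_sum": den_sum,
        }
    )


def sign_test_curves(curve1, curve2) -> float:
    """Two-sided exact binomial sign test comparing two per-bin curves.

    Tests H0: P(curve1 > curve2) = 0.5 across bins; tied (or jointly missing)
    bins are dropped.  Raises if every bin is tied.
    """
    c1 = np.asarray(curve1, dtype=float)
    c2 = np.asarray(curve2, dtype=float)
    if c1.size != c2.size:
        raise ValueError("curves must have equal length")
    ok = np.isfinite(c1) & np.isfinite(c2) & (c1 != c2)
    if not np.any(ok):
        raise ValueError("all bins tied; sign test undefined")
    wins = int(np.sum(c1[ok] > c2[ok]))
    return float(stats.binomtest(wins, int(ok.sum()), 0.5).pvalue)
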