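"""Composite-likelihood-ratio scan for selective sweeps.

The model follows the composite-likelihood framework of SweepFinder/
SweeD: the genome-wide site frequency spectrum (SFS) is the null; near a
putative sweep each sampled lineage is caught by the sweep with a
probability that decays with genetic distance, and caught lineages
coalesce onto the sweeping haplotype, distorting the local SFS toward
fixed and extreme-frequency classes.

Parameterisation: a lineage at distance ``d`` bp from the test position
escapes the sweep with probability ``exp(-alpha / d)``, where ``alpha``
(bp) is the sweep-strength/footprint parameter.  At ``alpha = 0`` every
lineage escapes and the model collapses to the background SFS, so the
CLR — ``2 * (max_alpha l_sweep - l_background)`` — is non-negative
whenever the grid includes 0; larger ``alpha`` means a stronger sweep
with a wider footprint.  Only polymorphic sites are modelled (per-site
likelihoods are conditioned on polymorphism); the folded spectrum is the
default since no ancestral polarisation is assumed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .vcf_io import GenotypeMatrix, allele_counts
from .window_stats import Window

DEFAULT_CLR_THRESHOLD = 20.0
DEFAULT_FLANK = 200_000
_PROB_FLOOR = 1e-300


@dataclass(frozen=True)
class SiteFrequency:
    pos: int
    count: int  # alt-allele count; folding happens downstream
    n: int

    def __post_init__(self) -> None:
        if not 0 < self.count < self.n:
            raise ValueError("SiteFrequency requires a polymorphic site (0 < count < n)")


@dataclass
class CLRResult:
    bin: Window
    test_pos: float
    clr: float
    alpha_hat: float
    n_sites: int
    is_sweep: bool


def bin_chromosome(chrom_length: int, n_bins: int, chrom: str = "chr") -> list[Window]:
    """Partition a chromosome into ``n_bins`` contiguous near-equal bins.

    The remainder is spread one bp at a time over the leading bins, so
    widths differ by at most 1.  Test positions are evaluated at bin
    midpoints.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if n_bins > chrom_length:
        raise ValueError(f"n_bins={n_bins} exceeds chromosome length {chrom_length}")
    base, rem = divmod(chrom_length, n_bins)
    widths = [base + 1] * rem + [base] * (n_bins - rem)
    bins = []
    start = 0
    for w in widths:
        bins.append(Window(chrom, start, start + w))
        start += w
    return bins


def background_sfs(sites: Sequence[SiteFrequency], folded: bool = True) -> np.ndarray:
    """Empirical genome-wide SFS, normalised to sum 1.

    Folded: vector over minor-allele classes ``1..n//2``.  Unfolded:
    classes ``1..n-1``.  All sites must share the same ``n``.
    """
    if not sites:
        raise ValueError("no polymorphic sites for the background SFS")
    ns = {s.n for s in sites}
    if len(ns) > 1:
        raise ValueError(
            f"mixed called-allele counts {sorted(ns)}; drop incomplete sites first"
        )
    n = ns.pop()
    if folded:
        vec = np.zeros(n // 2)
        for s in sites:
            vec[min(s.count, n - s.count) - 1] += 1
    else:
        vec = np.zeros(n - 1)
        for s in sites:
            vec[s.count - 1] += 1
    return vec / vec.sum()


def _unfold(background: np.ndarray, n: int) -> np.ndarray:
    """Symmetric unfolded surrogate spectrum over classes 1..n-1."""
    if background.size == n - 1:
        return background / background.sum()
    if background.size != n // 2:
        raise ValueError("background SFS size matches neither folded nor unfolded n")
    phi = np.zeros(n - 1)
    for j, mass in enumerate(background, start=1):
        if j == n - j:
            phi[j - 1] += mass
        else:
            phi[j - 1] += mass / 2.0
            phi[n - j - 1] += mass / 2.0
    return phi / phi.sum()


_kernel_cache: dict = {}


def _sweep_kernel(n: int, phi: np.ndarray) -> np.ndarray:
    """M[k, c] = P(post-sweep derived count c | k of n lineages escaped).

    The k escapees plus the single swept ancestral lineage form a
    background sample of size k+1; the swept lineage's allele is
    replicated n-k times.  ``k = n`` is the no-sweep row: the background
    spectrum itself.  Shape (n+1, n+1) with columns c = 0..n.
    """
    key = (n, phi.tobytes())
    hit = _kernel_cache.get(key)
    if hit is not None:
        return hit
    M = np.zeros((n + 1, n + 1))
    j = np.arange(1, n)
    for k in range(n + 1):
        if k == n:
            M[n, 1:n] = phi
            continue
        m = k + 1
        i = np.arange(0, m + 1)
        q = np.zeros(m + 1)  # q[i] = P(i derived among m background lineages)
        for jj, pj in zip(j, phi):
            q += pj * hypergeom.pmf(i, n, jj, m)
        for ii in range(m + 1):
            if q[ii] == 0.0:
                continue
            p_swept_derived = ii / m
            if ii >= 1:
                # swept lineage derived; escapees carry the other ii-1 copies
                M[k, (ii - 1) + (n - k)] += q[ii] * p_swept_derived
            M[k, ii] += q[ii] * (1.0 - p_swept_derived)
    _kernel_cache[key] = M
    return M


def default_alpha_grid(n_points: int = 15, lo: float = 50.0, hi: float = 5e5) -> np.ndarray:
    """0 (the null) plus log-spaced footprint scales from sub-kb upward."""
    return np.concatenate([[0.0], np.geomspace(lo, hi, n_points)])


def _site_class_columns(counts: np.ndarray, n: int, folded: bool) -> tuple[np.ndarray, np.ndarray]:
    """Column indices (primary, mirror) into the derived-class axis per site."""
    if folded:
        minor = np.minimum(counts, n - counts)
        mirror = n - minor
        same = minor == mirror
        return minor, np.where(same, minor, mirror)
    return counts, counts


def clr_at(
    test_pos: float,
    sites: Sequence[SiteFrequency],
    background: np.ndarray,
    alpha_grid: Optional[np.ndarray] = None,
    folded: bool = True,
) -> tuple[float, float]:
    """Composite likelihood ratio and best alpha at one test position.

    Returns ``(nan, nan)`` when the site set is empty.
    """
    if len(sites) == 0:
        return float("nan"), float("nan")
    if alpha_grid is None:
        alpha_grid = default_alpha_grid()
    alpha_grid = np.asarray(alpha_grid, dtype=float)
    n = sites[0].n
    if any(s.n != n for s in sites):
        raise ValueError("all sites must share the same called-allele count n")
    phi = _unfold(np.asarray(background, dtype=float), n)
    M = _sweep_kernel(n, phi)

    pos = np.array([s.pos for s in sites], dtype=float)
    cnt = np.array([s.count for s in sites], dtype=int)
    d = np.abs(pos - test_pos)
    col_a, col_b = _site_class_columns(cnt, n, folded)
    rows = np.arange(len(sites))

    # background (null) log-likelihood
    p_bg = M[n]
    bg_site = p_bg[col_a] + np.where(col_b != col_a, p_bg[col_b], 0.0)
    ll_bg = float(np.log(np.maximum(bg_site, _PROB_FLOOR)).sum())

    k_arr = np.arange(n + 1)
    log_comb = np.array([math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)
                         for k in k_arr])

    best_ll = -np.inf
    best_alpha = float("nan")
    with np.errstate(divide="ignore"):
        for alpha in alpha_grid:
            if alpha == 0.0:
                ll = ll_bg
            else:
                p_esc = np.exp(-alpha / np.maximum(d, 1e-9))
                p_esc = np.clip(p_esc, 1e-12, 1.0 - 1e-12)
                # binomial escape-count weights, sites x (n+1), in log space
                logw = (
                    log_comb[None, :]
                    + k_arr[None, :] * np.log(p_esc)[:, None]
                    + (n - k_arr)[None, :] * np.log1p(-p_esc)[:, None]
                )
                W = np.exp(logw)
                P = W @ M  # sites x (n+1) derived-class probabilities
                poly_mass = 1.0 - P[:, 0] - P[:, n]
                p_site = P[rows, col_a] + np.where(col_b != col_a, P[rows, col_b], 0.0)
                p_site = p_site / np.maximum(poly_mass, _PROB_FLOOR)
                ll = float(np.log(np.maximum(p_site, _PROB_FLOOR)).sum())
            if ll > best_ll:
                best_ll = ll
                best_alpha = float(alpha)

    clr = 2.0 * (best_ll - ll_bg)
    return max(clr, 0.0), best_alpha


def sites_from_matrix(
    matrix: GenotypeMatrix, population: Sequence[str], chrom: str
) -> list[SiteFrequency]:
    """Polymorphic, fully called sites for one population on one chromosome.

    Sites with missing calls in the population are dropped so that all
    retained sites share one ``n`` (required by the SFS machinery).
    """
    counts = allele_counts(matrix, population)
    on_chrom = matrix.chroms == chrom
    n_max = counts[:, 2].max(initial=0)
    keep = on_chrom & (counts[:, 2] == n_max) & (counts[:, 1] > 0) & (counts[:, 0] > 0)
    return [
        SiteFrequency(pos=int(matrix.positions[i]), count=int(counts[i, 1]), n=int(n_max))
        for i in np.flatnonzero(keep)
    ]


def scan(
    matrix: GenotypeMatrix,
    population: Sequence[str],
    chrom_lengths: dict[str, int],
    n_bins: int = 2000,
    clr_threshold: float = DEFAULT_CLR_THRESHOLD,
    flank: int = DEFAULT_FLANK,
    alpha_grid: Optional[np.ndarray] = None,
    folded: bool = True,
) -> list[CLRResult]:
    """Genome-wide CLR scan: ``n_bins`` bins per chromosome, one test per bin.

    The background SFS is estimated once from all chromosomes pooled;
    each bin's test position is its midpoint and draws on polymorphic
    sites within ``flank`` bp of it.  Bins with no usable sites carry an
    undefined (nan) CLR and are never flagged.
    """
    if len(population) == 0:
        raise ValueError("empty population")
    per_chrom = {c: sites_from_matrix(matrix, population, c) for c in chrom_lengths}
    all_sites = [s for sites in per_chrom.values() for s in sites]
    background = background_sfs(all_sites, folded=folded) if all_sites else None

    results: list[CLRResult] = []
    for chrom, length in chrom_lengths.items():
        sites = per_chrom[chrom]
        pos = np.array([s.pos for s in sites], dtype=float)
        order = np.argsort(pos)
        pos = pos[order]
        sites = [sites[i] for i in order]
        for b in bin_chromosome(length, n_bins, chrom=chrom):
            mid = (b.start + b.end) / 2.0
            if len(sites) == 0 or background is None:
                results.append(CLRResult(b, mid, float("nan"), float("nan"), 0, False))
                continue
            lo = int(np.searchsorted(pos, mid - flank, side="left"))
            hi = int(np.searchsorted(pos, mid + flank, side="right"))
            nearby = sites[lo:hi]
            clr, alpha = clr_at(mid, nearby, background, alpha_grid, folded=folded)
            flagged = bool(np.isfinite(clr) and clr > clr_threshold)
            results.append(CLRResult(b, mid, clr, alpha, len(nearby), flagged))
    return results


def results_table(results: Sequence[CLRResult]) -> pd.DataFrame:
    """Per-bin TSV-ready frame: chrom, bin_start, bin_end, clr, alpha_hat, is_sweep."""
    return pd.DataFrame(
        {
            "chrom": [r.bin.chrom for r in results],
            "bin_start": [r.bin.start for r in results],
            "bin_end": [r.bin.end for r in results],
            "test_pos": [r.test_pos for r in results],
            "n_sites": [r.n_sites for r in results],
            "clr": [r.clr for r in results],
            "alpha_hat": [r.alpha_hat for r in results],
            "is_sweep": [r.is_sweep for r in results],
        }
    )
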