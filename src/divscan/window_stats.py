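"""Per-window population-genetic statistics.

Implements nucleotide diversity, segregating sites, Tajima's D, the
Weir & Cockerham (1984) FST estimator, absolute divergence (Dxy) and
fixed-difference counts on non-overlapping windows, plus a whole-matrix
mode for short non-recombining molecules.

Conventions
-----------
* pi and Dxy are normalised by the full window length by default
  (the ``--window-pi`` convention); a callable-sites denominator is
  available via ``denominator="called"``.
* Undefined statistics are ``numpy.nan`` in memory and an explicit
  ``NA`` token in TSV output, never 0.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .vcf_io import GenotypeMatrix, allele_counts, het_counts

log = logging.getLogger(__name__)

NA_TOKEN = "NA"


@dataclass(frozen=True)
class Window:
    """Half-open genomic interval [start, end) in 0-based coordinates."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"window start must precede end: {self}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains_pos(self, pos_1based: np.ndarray) -> np.ndarray:
        """Mask of 1-based positions falling inside the window."""
        zero = pos_1based - 1
        return (zero >= self.start) & (zero < self.end)


def make_windows(chrom_lengths: dict[str, int], size: int) -> list[Window]:
    """Tile each chromosome with non-overlapping windows of ``size`` bp.

    The terminal window may be shorter than ``size``.
    """
    if size <= 0:
        raise ValueError("window size must be positive")
    windows: list[Window] = []
    for chrom, length in chrom_lengths.items():
        if length <= 0:
            warnings.warn(f"chromosome {chrom} has zero length; no windows")
            continue
        for start in range(0, length, size):
            windows.append(Window(chrom, start, min(start + size, length)))
    return windows


# ---------------------------------------------------------------------------
# per-site building blocks (vectorised over sites)


def _site_pi(counts: np.ndarray) -> np.ndarray:
    """Unbiased per-site heterozygosity 2p(1-p) * n/(n-1); nc<2 -> 0."""
    ref = counts[:, 0].astype(float)
    alt = counts[:, 1].astype(float)
    n = counts[:, 2].astype(float)
    out = np.zeros(len(counts))
    ok = n >= 2
    p = np.divide(alt, n, out=np.zeros_like(alt), where=ok)
    out[ok] = 2.0 * p[ok] * (1.0 - p[ok]) * n[ok] / (n[ok] - 1.0)
    return out


def nucleotide_diversity(
    counts: np.ndarray,
    window_length: int,
    denominator: str = "length",
    n_called_sites: Optional[int] = None,
) -> float:
    """Average pairwise diversity per bp over a window.

    ``counts`` is the (sites, 3) ref/alt/total array restricted to the
    window.  With ``denominator="length"`` (default) the divisor is the
    window length in bp; with ``"called"`` it is ``n_called_sites``.
    """
    if window_length <= 0:
        raise ValueError("window length must be positive")
    total = float(_site_pi(counts).sum())
    if denominator == "length":
        return total / window_length
    if denominator == "called":
        if not n_called_sites:
            raise ValueError("callable-site denominator requires n_called_sites")
        return total / n_called_sites
    raise ValueError(f"unknown denominator {denominator!r}")


def segregating_sites(counts: np.ndarray) -> int:
    """Number of sites polymorphic within the population."""
    ref, alt, n = counts[:, 0], counts[:, 1], counts[:, 2]
    return int(((ref > 0) & (alt > 0) & (n >= 2)).sum())


def tajima_constants(n: int) -> dict[str, float]:
    """The Tajima (1989) normalisation constants for sample size ``n``."""
    if n < 2:
        raise ValueError("n must be >= 2")
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2,
            "e1": e1, "e2": e2}


def tajimas_d(counts: np.ndarray, n_tolerance: float = 0.20) -> float:
    """Tajima's D from per-site allele counts in a window.

    The sample size ``n`` is taken as the median called-allele count over
    polymorphic sites; sites deviating from it by more than
    ``n_tolerance`` are excluded (missing-data policy, logged).  Returns
    ``nan`` when S == 0 or n < 4.
    """
    ref, alt, nc = counts[:, 0], counts[:, 1], counts[:, 2]
    poly = (ref > 0) & (alt > 0) & (nc >= 2)
    if not poly.any():
        return float("nan")
    n = int(np.median(nc[poly]))
    if n < 4:
        return float("nan")
    keep = poly & (np.abs(nc - n) <= n_tolerance * n)
    n_dropped = int(poly.sum() - keep.sum())
    if n_dropped:
        log.debug("Tajima's D: dropped %d sites deviating >%d%% from n=%d",
                  n_dropped, int(100 * n_tolerance), n)
    if not keep.any():
        return float("nan")
    S = int(keep.sum())
    k_hat = float(_site_pi(counts[keep]).sum())
    c = tajima_constants(n)
    theta_w = S / c["a1"]
    var = c["e1"] * S + c["e2"] * S * (S - 1)
    if var <= 0:
        return float("nan")
    return (k_hat - theta_w) / math.sqrt(var)


# ---------------------------------------------------------------------------
# two-population statistics


def wc_fst_components(
    counts1: np.ndarray,
    counts2: np.ndarray,
    het1: Optional[np.ndarray] = None,
    het2: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Weir & Cockerham (1984) per-site variance components (a, b, c).

    With ``het1``/``het2`` (per-site [n het individuals, n called
    individuals]) supplied, the full diploid estimator with the observed
    heterozygosity term is used — the form VCFtools reports.  Without
    them, the haploid analogue is used (c = 0), treating called alleles
    as the sample units.

    Sites where either population has < 2 called alleles yield nan
    components.
    """
    r = 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        if het1 is not None and het2 is not None:
            n1 = het1[:, 1].astype(float)  # individuals
            n2 = het2[:, 1].astype(float)
            p1 = counts1[:, 1] / counts1[:, 2].astype(float)
            p2 = counts2[:, 1] / counts2[:, 2].astype(float)
            h1 = np.divide(het1[:, 0], n1, out=np.zeros_like(n1), where=n1 > 0)
            h2 = np.divide(het2[:, 0], n2, out=np.zeros_like(n2), where=n2 > 0)
            usable = (n1 >= 1) & (n2 >= 1) & (n1 + n2 >= 3)
            nbar = (n1 + n2) / r
            nc = (n1 + n2 - (n1**2 + n2**2) / (n1 + n2)) / (r - 1)
            pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
            s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
            hbar = (n1 * h1 + n2 * h2) / (n1 + n2)
            a = (nbar / nc) * (
                s2
                - (1.0 / (nbar - 1))
                * (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4.0)
            )
            b = (nbar / (nbar - 1)) * (
                pbar * (1 - pbar)
                - s2 * (r - 1) / r
                - (2 * nbar - 1) / (4 * nbar) * hbar
            )
            c = hbar / 2.0
        else:
            n1 = counts1[:, 2].astype(float)  # alleles as sample units
            n2 = counts2[:, 2].astype(float)
            p1 = np.divide(counts1[:, 1], n1, out=np.zeros_like(n1), where=n1 > 0)
            p2 = np.divide(counts2[:, 1], n2, out=np.zeros_like(n2), where=n2 > 0)
            usable = (n1 >= 2) & (n2 >= 2)
            nbar = (n1 + n2) / r
            nc = (n1 + n2 - (n1**2 + n2**2) / (n1 + n2)) / (r - 1)
            pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
            msp = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / (r - 1)
            msg = (n1 * p1 * (1 - p1) + n2 * p2 * (1 - p2)) / (n1 - 1 + n2 - 1)
            a = (msp - msg) / nc
            b = msg
            c = np.zeros_like(a)
    a = np.where(usable, a, np.nan)
    b = np.where(usable, b, np.nan)
    c = np.where(usable, c, np.nan)
    return a, b, c


def wc_fst(
    counts1: np.ndarray,
    counts2: np.ndarray,
    het1: Optional[np.ndarray] = None,
    het2: Optional[np.ndarray] = None,
) -> tuple[float, float, np.ndarray]:
    """Windowed Weir & Cockerham FST.

    Returns ``(weighted, mean_of_ratios, per_site)`` where ``weighted`` is
    the ratio-of-sums estimator sum(a)/sum(a+b+c).  Negative estimates are
    reported as computed.  All-nan input yields nan.
    """
    a, b, c = wc_fst_components(counts1, counts2, het1, het2)
    denom = a + b + c
    ok = np.isfinite(denom) & (denom != 0)
    per_site = np.full(len(a), np.nan)
    per_site[ok] = a[ok] / denom[ok]
    if not ok.any():
        return float("nan"), float("nan"), per_site
    weighted = float(a[ok].sum() / denom[ok].sum())
    mean_ratio = float(np.nanmean(per_site[ok]))
    return weighted, mean_ratio, per_site


def dxy(
    counts1: np.ndarray, counts2: np.ndarray, window_length: int
) -> float:
    """Absolute divergence per bp: mean between-population difference.

    Invariant or uncallable positions contribute 0 to the numerator;
    the denominator is the full window length.
    """
    if window_length <= 0:
        raise ValueError("window length must be positive")
    n1 = counts1[:, 2].astype(float)
    n2 = counts2[:, 2].astype(float)
    ok = (n1 > 0) & (n2 > 0)
    p1 = np.divide(counts1[:, 1], n1, out=np.zeros_like(n1), where=ok)
    p2 = np.divide(counts2[:, 1], n2, out=np.zeros_like(n2), where=ok)
    num = np.where(ok, p1 * (1 - p2) + (1 - p1) * p2, 0.0)
    return float(num.sum()) / window_length


def fixed_sites(counts1: np.ndarray, counts2: np.ndarray) -> int:
    """Count sites where the two populations are fixed for different alleles.

    A population containing any alternative allele alongside the reference
    (including via heterozygotes, which contribute one of each) is not
    fixed, so such sites never count.
    """
    r1, a1, n1 = counts1[:, 0], counts1[:, 1], counts1[:, 2]
    r2, a2, n2 = counts2[:, 0], counts2[:, 1], counts2[:, 2]
    fixed_ref1 = (a1 == 0) & (n1 > 0)
    fixed_alt1 = (r1 == 0) & (n1 > 0)
    fixed_ref2 = (a2 == 0) & (n2 > 0)
    fixed_alt2 = (r2 == 0) & (n2 > 0)
    return int(((fixed_ref1 & fixed_alt2) | (fixed_alt1 & fixed_ref2)).sum())


# ---------------------------------------------------------------------------
# window table assembly


def window_stats_table(
    matrix: GenotypeMatrix,
    pop1: Sequence[str],
    pop2: Sequence[str],
    windows: Sequence[Window],
    pop1_name: str = "pop1",
    pop2_name: str = "pop2",
    denominator: str = "length",
) -> pd.DataFrame:
    """One row per window with pi/S/D per population, FST, Dxy and Fs.

    The first three columns are BED-compatible (0-based half-open).
    """
    c1 = allele_counts(matrix, pop1)
    c2 = allele_counts(matrix, pop2)
    h1 = het_counts(matrix, pop1) if matrix.ploidy == 2 else None
    h2 = het_counts(matrix, pop2) if matrix.ploidy == 2 else None

    rows = []
    for w in windows:
        mask = (matrix.chroms == w.chrom) & w.contains_pos(matrix.positions)
        idx = np.flatnonzero(mask)
        wc1, wc2 = c1[idx], c2[idx]
        wh1 = h1[idx] if h1 is not None else None
        wh2 = h2[idx] if h2 is not None else None
        fst_w, fst_m, _ = wc_fst(wc1, wc2, wh1, wh2)
        rows.append(
            {
                "chrom": w.chrom,
                "start": w.start,
                "end": w.end,
                "n_snps": len(idx),
                f"pi_{pop1_name}": nucleotide_diversity(wc1, w.length, denominator,
                                                        n_called_sites=len(idx) or None),
                f"pi_{pop2_name}": nucleotide_diversity(wc2, w.length, denominator,
                                                        n_called_sites=len(idx) or None),
                f"S_{pop1_name}": segregating_sites(wc1),
                f"S_{pop2_name}": segregating_sites(wc2),
                f"D_{pop1_name}": tajimas_d(wc1),
                f"D_{pop2_name}": tajimas_d(wc2),
                "fst_weighted": fst_w,
                "fst_mean": fst_m,
                "dxy": dxy(wc1, wc2, w.length),
                "fs": fixed_sites(wc1, wc2),
            }
        )
    return pd.DataFrame(rows)


def whole_matrix_stats(
    matrix: GenotypeMatrix,
    populations: dict[str, Sequence[str]],
    total_length: int,
) -> pd.DataFrame:
    """Single-row-per-population statistics treating the matrix as one window.

    Used for short non-recombining molecules where windowing is
    disproportionate; ``total_length`` is the reference length of the
    molecule in bp.
    """
    if total_length <= 0:
        raise ValueError("total_length must be positive")
    rows = []
    for name, samples in populations.items():
        counts = allele_counts(matrix, samples)
        rows.append(
            {
                "population": name,
                "n_samples": len(samples),
                "pi": nucleotide_diversity(counts, total_length),
                "S": segregating_sites(counts),
                "tajima_d": tajimas_d(counts),
                "n_snps": int(((counts[:, 0] > 0) | (counts[:, 1] > 0)).sum()),
            }
        )
    return pd.DataFrame(rows)


def write_stats_tsv(df: pd.DataFrame, path: str, header_lines: Sequence[str] = ()) -> None:
    """Write the window table with NA tokens and optional provenance header."""
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write("#" + line.rstrip("\n") + "\n")
        df.to_csv(fh, sep="\t", index=False, na_rep=NA_TOKEN, float_format="%.8g")


def read_stats_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", na_values=[NA_TOKEN])
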