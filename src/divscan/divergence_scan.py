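"""Selection-candidate classification from windowed statistics.

Flags low-nucleotide-diversity (LND) windows per species and
high/low-interspecific-differentiation (HIGD/LIGD) windows, combines
them into candidate categories, and provides the window-vector rank
correlation and shared/taxon-specific variant partition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .vcf_io import GenotypeMatrix

CATEGORIES = (
    "divergent_candidate",
    "adaptive_candidate_sp1",
    "adaptive_candidate_sp2",
    "shared_lnd_low_divergence",
    "none",
)


def quantile_threshold(values: np.ndarray, q: float, tail: str) -> float:
    """Empirical threshold delimiting the lower or upper ``q`` tail.

    NA entries are dropped before ranking.  Ties at the threshold are
    inclusive: every value equal to the returned threshold belongs to the
    tail, so the tail may exceed q*n.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("cannot compute a quantile of an all-NA vector")
    if not 0 < q < 1:
        raise ValueError("q must lie in (0, 1)")
    if v.min() == v.max():
        warnings.warn("constant statistic vector: every window ties at the threshold")
    v = np.sort(v)
    k = max(1, int(np.floor(q * v.size)))
    if tail == "lower":
        return float(v[k - 1])
    if tail == "upper":
        return float(v[v.size - k])
    raise ValueError("tail must be 'lower' or 'upper'")


@dataclass
class OutlierSummary:
    n_windows: int
    n_lnd_sp1: int
    n_lnd_sp2: int
    n_shared_lnd: int
    n_sp1_specific_lnd: int
    n_sp2_specific_lnd: int
    n_higd: int
    n_adaptive_sp1: int
    n_adaptive_sp2: int
    n_divergent: int
    n_shared_lnd_low_divergence: int

    def narrative(self) -> str:
        lines = [
            f"windows analysed: {self.n_windows}",
            f"LND windows (bottom-5%% pi): sp1={self.n_lnd_sp1}, sp2={self.n_lnd_sp2}",
            f"shared LND: {self.n_shared_lnd}; species-specific: "
            f"sp1={self.n_sp1_specific_lnd}, sp2={self.n_sp2_specific_lnd}",
            f"HIGD windows (top-5%% FST): {self.n_higd}",
            f"adaptive candidates (LND in one species + HIGD): "
            f"sp1={self.n_adaptive_sp1}, sp2={self.n_adaptive_sp2}",
            f"divergent candidates (shared LND + HIGD): {self.n_divergent}",
            f"shared LND with low divergence (bottom-5%% FST): "
            f"{self.n_shared_lnd_low_divergence}",
        ]
        return "\n".join(lines)


def classify_outliers(
    stats_df: pd.DataFrame,
    q: float = 0.05,
    pi1_col: str = "pi_pop1",
    pi2_col: str = "pi_pop2",
    fst_col: str = "fst_weighted",
) -> tuple[pd.DataFrame, OutlierSummary]:
    """Assign each window its outlier flags and a single candidate category.

    Categories (checked in priority order so every window gets exactly one):

    - ``divergent_candidate``: LND in both species and HIGD
    - ``adaptive_candidate_spX``: LND in species X only and HIGD
    - ``shared_lnd_low_divergence``: LND in both species and bottom-q FST
    - ``none``: everything else
    """
    for col in (pi1_col, pi2_col, fst_col):
        if col not in stats_df.columns:
            raise ValueError(f"missing column {col!r} in window table")
    pi1 = stats_df[pi1_col].to_numpy(float)
    pi2 = stats_df[pi2_col].to_numpy(float)
    fst = stats_df[fst_col].to_numpy(float)

    lnd1_thr = quantile_threshold(pi1, q, "lower")
    lnd2_thr = quantile_threshold(pi2, q, "lower")
    higd_thr = quantile_threshold(fst, q, "upper")
    ligd_thr = quantile_threshold(fst, q, "lower")

    lnd1 = np.isfinite(pi1) & (pi1 <= lnd1_thr)
    lnd2 = np.isfinite(pi2) & (pi2 <= lnd2_thr)
    higd = np.isfinite(fst) & (fst >= higd_thr)
    ligd = np.isfinite(fst) & (fst <= ligd_thr)

    category = np.full(len(stats_df), "none", dtype=object)
    category[lnd1 & lnd2 & ligd] = "shared_lnd_low_divergence"
    category[lnd1 & ~lnd2 & higd] = "adaptive_candidate_sp1"
    category[~lnd1 & lnd2 & higd] = "adaptive_candidate_sp2"
    category[lnd1 & lnd2 & higd] = "divergent_candidate"

    out = stats_df[["chrom", "start", "end"]].copy()
    out["lnd_sp1"] = lnd1
    out["lnd_sp2"] = lnd2
    out["higd"] = higd
    out["ligd"] = ligd
    out["category"] = category

    summary = OutlierSummary(
        n_windows=len(out),
        n_lnd_sp1=int(lnd1.sum()),
        n_lnd_sp2=int(lnd2.sum()),
        n_shared_lnd=int((lnd1 & lnd2).sum()),
        n_sp1_specific_lnd=int((lnd1 & ~lnd2).sum()),
        n_sp2_specific_lnd=int((~lnd1 & lnd2).sum()),
        n_higd=int(higd.sum()),
        n_adaptive_sp1=int((category == "adaptive_candidate_sp1").sum()),
        n_adaptive_sp2=int((category == "adaptive_candidate_sp2").sum()),
        n_divergent=int((category == "divergent_candidate").sum()),
        n_shared_lnd_low_divergence=int(
            (category == "shared_lnd_low_divergence").sum()
        ),
    )
    return out, summary


def correlate_windows(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation over pairwise-complete windows.

    Windows where either vector is NA are dropped; average ranks are used
    for ties.  Fewer than 3 complete pairs is an error.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape:
        raise ValueError("vectors must have equal length")
    ok = np.isfinite(xa) & np.isfinite(ya)
    if ok.sum() < 3:
        raise ValueError("fewer than 3 complete pairs")
    rho, _ = stats.spearmanr(xa[ok], ya[ok])
    return float(rho)


def _present_variants(matrix: GenotypeMatrix) -> set[tuple[str, int]]:
    """Variants carried (any non-reference allele) by any sample."""
    carries = (matrix.calls > 0).any(axis=(1, 2))
    return {
        (str(matrix.chroms[i]), int(matrix.positions[i]))
        for i in np.flatnonzero(carries)
    }


def venn_partition(matrices) -> pd.DataFrame:
    """Shared/taxon-specific variant counts for 2-4 taxa.

    ``matrices`` is a mapping label -> GenotypeMatrix or an iterable of
    (label, matrix) pairs.  A variant is present in a taxon when any of
    its samples carries a non-reference allele.  Returns one row per
    membership region of the Venn partition, with counts and percentage
    of the union.
    """
    pairs = list(matrices.items()) if hasattr(matrices, "items") else list(matrices)
    labels = [lab for lab, _ in pairs]
    if len(labels) != len(set(labels)):
        raise ValueError("duplicated taxon labels")
    if not 2 <= len(labels) <= 4:
        raise ValueError("venn partition supports 2-4 taxa")
    present = {lab: _present_variants(m) for lab, m in pairs}
    union: set[tuple[str, int]] = set().union(*present.values())

    rows = []
    for k in range(1, len(labels) + 1):
        for combo in combinations(labels, k):
            inside = set.intersection(*(present[lab] for lab in combo))
            outside: set[tuple[str, int]] = set().union(
                *(present[lab] for lab in labels if lab not in combo), set()
            )
            region = inside - outside
            rows.append(
                {
                    "taxa": "&".join(combo),
                    "n_taxa": k,
                    "count": len(region),
                    "pct_of_union": 100.0 * len(region) / len(union) if union else 0.0,
                }
            )
    return pd.DataFrame(rows)
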