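import itertools
import math

import numpy as np
import pytest

from divscan import window_stats as ws
from divscan.vcf_io import allele_counts, het_counts
from conftest import diploid_matrix, haploid_matrix, haplotypes_of, random_diploid_matrix


# --- independent oracles ----------------------------------------------------


def brute_pi(haplotypes, L, unbiased=True):
    """Mean pairwise haplotype differences / L, enumerated over all pairs."""
    n = haplotypes.shape[1]
    pairs = list(itertools.combinations(range(n), 2))
    total = sum((haplotypes[:, i] != haplotypes[:, j]).sum() for i, j in pairs)
    if not unbiased:
        return total / len(pairs) / L
    return total / len(pairs) / L


def brute_k_hat(haplotypes):
    n = haplotypes.shape[1]
    pairs = list(itertools.combinations(range(n), 2))
    return sum(float((haplotypes[:, i] != haplotypes[:, j]).sum()) for i, j in pairs) / len(pairs)


def brute_dxy(hap1, hap2, L):
    """Mean differences over all between-population haplotype pairs / L."""
    total = sum(
        (hap1[:, i] != hap2[:, j]).sum()
        for i in range(hap1.shape[1])
        for j in range(hap2.shape[1])
    )
    return total / (hap1.shape[1] * hap2.shape[1]) / L


def oracle_tajima_d(k_hat, S, n):
    """Literal transcription of the Tajima (1989) normalisation."""
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return (k_hat - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


def oracle_wc_fst_counts(n1, p1, n2, p2):
    """Weir & Cockerham (1984) with alleles as sample units (haploid form)."""
    r = 2
    msp = (n1 * (p1 - (n1 * p1 + n2 * p2) / (n1 + n2)) ** 2
           + n2 * (p2 - (n1 * p1 + n2 * p2) / (n1 + n2)) ** 2) / (r - 1)
    msg = (n1 * p1 * (1 - p1) + n2 * p2 * (1 - p2)) / (n1 - 1 + n2 - 1)
    nc = (n1 + n2 - (n1**2 + n2**2) / (n1 + n2)) / (r - 1)
    a = (msp - msg) / nc
    b = msg
    return a / (a + b)


# --- make_windows -----------------------------------------------------------


def test_make_windows_terminal_short_window():
    wins = ws.make_windows({"chr1": 250_000}, 100_000)
    assert len(wins) == 3
    assert wins[-1].length == 50_000


def test_make_windows_exact_fit():
    wins = ws.make_windows({"chr1": 100_000}, 100_000)
    assert len(wins) == 1


def test_make_windows_seven_chromosomes():
    wins = ws.make_windows({f"chr{i}": 1_000_000 for i in range(1, 8)}, 100_000)
    assert len(wins) == 70


def test_make_windows_tile_disjointly():
    wins = ws.make_windows({"chr1": 314_159}, 50_000)
    assert wins[0].start == 0
    for a, b in zip(wins, wins[1:]):
        assert a.end == b.start
    assert wins[-1].end == 314_159


def test_make_windows_zero_length_warns():
    with pytest.warns(UserWarning):
        assert ws.make_windows({"chr1": 0}, 100) == []


# --- nucleotide diversity ---------------------------------------------------


def test_pi_monomorphic_window_is_zero():
    counts = np.array([[4, 0, 4], [0, 4, 4]])
    assert ws.nucleotide_diversity(counts, 100) == 0.0


def test_pi_single_site_matches_brute_force():
    # 2 diploids, one site with counts (2,2), L=100 -> 4/3 * 0.5 / 100
    counts = np.array([[2, 2, 4]])
    got = ws.nucleotide_diversity(counts, 100)
    hap = np.array([[0, 0, 1, 1]])
    assert got == pytest.approx(brute_pi(hap, 100), abs=1e-12)
    assert got == pytest.approx(0.006667, abs=5e-7)


def test_pi_all_missing_window():
    counts = np.array([[0, 0, 0]])
    assert ws.nucleotide_diversity(counts, 100) == 0.0


def test_pi_zero_length_window_raises():
    with pytest.raises(ValueError):
        ws.nucleotide_diversity(np.array([[2, 2, 4]]), 0)


def test_pi_oracle_equivalence_random_matrices():
    rng = np.random.default_rng(11)
    for _ in range(10):
        m = random_diploid_matrix(rng, n_sites=50, n_samples=8)
        counts = allele_counts(m, m.samples)
        hap = haplotypes_of(m, m.samples)
        got = ws.nucleotide_diversity(counts, 1000)
        assert got == pytest.approx(brute_pi(hap, 1000), abs=1e-12)


# --- Tajima's D -------------------------------------------------------------


def test_tajimas_d_undefined_when_no_segregating_sites():
    counts = np.array([[4, 0, 4]])
    assert math.isnan(ws.tajimas_d(counts))


def test_tajimas_d_worked_fixture_n4_s2():
    counts = np.array([[3, 1, 4], [2, 2, 4]])
    hap = np.array([[0, 0, 0, 1], [0, 0, 1, 1]])
    expected = oracle_tajima_d(brute_k_hat(hap), 2, 4)
    got = ws.tajimas_d(counts)
    assert got == pytest.approx(expected, abs=1e-9)
    assert got == pytest.approx(0.592, abs=1e-3)


def test_tajimas_d_oracle_on_random_complete_matrices():
    rng = np.random.default_rng(5)
    for _ in range(5):
        m = random_diploid_matrix(rng, n_sites=30, n_samples=6)
        counts = allele_counts(m, m.samples)
        poly = (counts[:, 0] > 0) & (counts[:, 1] > 0)
        if not poly.any():
            continue
        hap = haplotypes_of(m, m.samples)[poly]
        expected = oracle_tajima_d(brute_k_hat(hap), int(poly.sum()), 12)
        assert ws.tajimas_d(counts) == pytest.approx(expected, abs=1e-9)


def test_tajima_constants_reject_tiny_n():
    with pytest.raises(ValueError):
        ws.tajima_constants(1)


# --- Weir & Cockerham FST ---------------------------------------------------


def test_fst_identical_populations_nonpositive():
    c = np.array([[2, 2, 4]])
    w, _, _ = ws.wc_fst(c, c)
    assert w <= 0


def test_fst_fixed_difference_is_one():
    w, m, per = ws.wc_fst(np.array([[4, 0, 4]]), np.array([[0, 4, 4]]))
    assert w == pytest.approx(1.0, abs=1e-12)
    assert per[0] == pytest.approx(1.0, abs=1e-12)


def test_fst_single_site_matches_hand_components():
    c1 = np.array([[6, 2, 8]])
    c2 = np.array([[1, 7, 8]])
    w, _, _ = ws.wc_fst(c1, c2)
    assert w == pytest.approx(oracle_wc_fst_counts(8, 2 / 8, 8, 7 / 8), abs=1e-12)


def test_fst_diploid_form_with_heterozygosity():
    # full W&C 1984 with the observed-heterozygosity term, hand-evaluated
    m = diploid_matrix(
        [[(0, 1), (0, 0), (1, 1), (0, 1), (1, 1), (1, 1)]],
        samples=[f"S{i}" for i in range(6)],
    )
    pop1, pop2 = m.samples[:3], m.samples[3:]
    c1, c2 = allele_counts(m, pop1), allele_counts(m, pop2)
    h1, h2 = het_counts(m, pop1), het_counts(m, pop2)
    w, _, _ = ws.wc_fst(c1, c2, h1, h2)

    n1 = n2 = 3.0
    p1, p2 = 3 / 6, 5 / 6
    hb1, hb2 = 1 / 3, 1 / 3
    r, nbar = 2.0, 3.0
    nc = (6 - (9 + 9) / 6) / 1
    pbar = (n1 * p1 + n2 * p2) / 6
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * hb1 + n2 * hb2) / 6
    a = (nbar / nc) * (s2 - (1 / (nbar - 1)) * (pbar * (1 - pbar) - s2 / 2 - hbar / 4))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - s2 / 2 - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    assert w == pytest.approx(a / (a + b + c), abs=1e-12)


def test_fst_weighted_is_ratio_of_sums():
    rng = np.random.default_rng(3)
    c1 = np.column_stack([rng.integers(1, 8, 20), rng.integers(1, 8, 20)])
    c1 = np.column_stack([c1, c1.sum(axis=1)])
    c2 = np.column_stack([rng.integers(1, 8, 20), rng.integers(1, 8, 20)])
    c2 = np.column_stack([c2, c2.sum(axis=1)])
    w, mean_r, per = ws.wc_fst(c1, c2)
    a, b, c = ws.wc_fst_components(c1, c2)
    assert w == pytest.approx(np.nansum(a) / np.nansum(a + b + c), abs=1e-12)
    assert mean_r == pytest.approx(np.nanmean(per), abs=1e-12)


def test_fst_no_usable_sites_is_nan():
    w, m, per = ws.wc_fst(np.array([[1, 0, 1]]), np.array([[1, 0, 1]]))
    assert math.isnan(w) and math.isnan(m)


def test_fst_hudson_agreement_symmetric():
    # W&C ~ Hudson within 0.02 for equal sample sizes and moderate divergence
    rng = np.random.default_rng(19)
    n = 40
    p1 = rng.uniform(0.05, 0.95, 300)
    p2 = np.clip(p1 + rng.normal(0, 0.25, 300), 0.01, 0.99)
    a1 = np.round(p1 * n).astype(int)
    a2 = np.round(p2 * n).astype(int)
    c1 = np.column_stack([n - a1, a1, np.full(300, n)])
    c2 = np.column_stack([n - a2, a2, np.full(300, n)])
    w, _, _ = ws.wc_fst(c1, c2)
    f1, f2 = a1 / n, a2 / n
    num = (f1 - f2) ** 2 - f1 * (1 - f1) / (n - 1) - f2 * (1 - f2) / (n - 1)
    den = f1 * (1 - f2) + f2 * (1 - f1)
    hudson = num.sum() / den.sum()
    assert w == pytest.approx(hudson, abs=0.02)


# --- Dxy --------------------------------------------------------------------


def test_dxy_identical_monomorphic_zero():
    c = np.array([[4, 0, 4]])
    assert ws.dxy(c, c, 100) == 0.0


def test_dxy_fixed_difference():
    assert ws.dxy(np.array([[4, 0, 4]]), np.array([[0, 4, 4]]), 100) == pytest.approx(0.01)


def test_dxy_single_site_frequencies():
    got = ws.dxy(np.array([[2, 2, 4]]), np.array([[3, 1, 4]]), 100)
    # oracle: average over all between-population haplotype pairs
    hap1 = np.array([[0, 0, 1, 1]])
    hap2 = np.array([[0, 0, 0, 1]])
    assert got == pytest.approx(brute_dxy(hap1, hap2, 100), abs=1e-12)
    assert got == pytest.approx(0.005, abs=1e-12)


def test_dxy_oracle_equivalence_random():
    rng = np.random.default_rng(23)
    for _ in range(10):
        m = random_diploid_matrix(rng, n_sites=50, n_samples=8)
        pop1, pop2 = m.samples[:4], m.samples[4:]
        got = ws.dxy(allele_counts(m, pop1), allele_counts(m, pop2), 777)
        expected = brute_dxy(haplotypes_of(m, pop1), haplotypes_of(m, pop2), 777)
        assert got == pytest.approx(expected, abs=1e-12)


def test_dxy_of_population_with_itself_is_uncorrected_pi():
    rng = np.random.default_rng(29)
    m = random_diploid_matrix(rng, n_sites=40, n_samples=6)
    c = allele_counts(m, m.samples)
    p = c[:, 1] / c[:, 2]
    uncorrected_pi = float((2 * p * (1 - p)).sum()) / 500
    assert ws.dxy(c, c, 500) == pytest.approx(uncorrected_pi, abs=1e-12)


def test_pooled_pi_at_least_mean_within_pi():
    rng = np.random.default_rng(31)
    for _ in range(10):
        m = random_diploid_matrix(rng, n_sites=40, n_samples=8)
        pop1, pop2 = m.samples[:4], m.samples[4:]
        # holds exactly for the plugin (frequency) estimator with equal
        # sizes: 2*pbar*(1-pbar) - mean(2*p*(1-p)) = (p1-p2)^2/2 >= 0;
        # the n/(n-1) correction can violate it by O(1/n), so the plugin
        # form is what the invariant is asserted on
        p1 = (haplotypes_of(m, pop1) == 1).mean(axis=1)
        p2 = (haplotypes_of(m, pop2) == 1).mean(axis=1)
        pooled = (2 * ((p1 + p2) / 2) * (1 - (p1 + p2) / 2)).sum()
        within = ((2 * p1 * (1 - p1)).sum() + (2 * p2 * (1 - p2)).sum()) / 2
        assert pooled >= within - 1e-12


# --- fixed sites ------------------------------------------------------------


def test_fixed_sites_basic():
    assert ws.fixed_sites(np.array([[4, 0, 4]]), np.array([[0, 4, 4]])) == 1


def test_fixed_sites_shared_polymorphism():
    assert ws.fixed_sites(np.array([[2, 2, 4]]), np.array([[1, 3, 4]])) == 0


def test_fixed_sites_five_site_fixture():
    # disjoint allele sets at sites 2 and 4 only
    c1 = np.array([[4, 0, 4], [4, 0, 4], [2, 2, 4], [0, 4, 4], [4, 0, 4]])
    c2 = np.array([[4, 0, 4], [0, 4, 4], [0, 4, 4], [4, 0, 4], [3, 1, 4]])
    assert ws.fixed_sites(c1, c2) == 2


def test_fixed_sites_heterozygote_breaks_fixation():
    m = diploid_matrix([[(0, 0), (0, 1), (1, 1), (1, 1)]])
    c1 = allele_counts(m, m.samples[:2])  # contains a het -> not fixed
    c2 = allele_counts(m, m.samples[2:])
    assert ws.fixed_sites(c1, c2) == 0


def test_fixed_sites_empty_input():
    empty = np.empty((0, 3), dtype=int)
    assert ws.fixed_sites(empty, empty) == 0


# --- whole-matrix mode ------------------------------------------------------


def test_whole_matrix_haploid_pair_single_difference():
    m = haploid_matrix([[0, 1]])
    df = ws.whole_matrix_stats(m, {"all": m.samples}, total_length=1000)
    assert df.loc[0, "pi"] == pytest.approx(0.001)


def test_whole_matrix_monomorphic():
    m = haploid_matrix([[0, 0], [0, 0]])
    df = ws.whole_matrix_stats(m, {"all": m.samples}, total_length=1000)
    assert df.loc[0, "pi"] == 0.0
    assert df.loc[0, "S"] == 0
    assert math.isnan(df.loc[0, "tajima_d"])


def test_whole_matrix_five_haplotypes_brute_force():
    rng = np.random.default_rng(13)
    hap = rng.integers(0, 2, size=(30, 5))
    m = haploid_matrix(hap)
    df = ws.whole_matrix_stats(m, {"all": m.samples}, total_length=2000)
    assert df.loc[0, "pi"] == pytest.approx(brute_pi(hap, 2000), abs=1e-12)


# --- table assembly ---------------------------------------------------------


def test_window_table_columns_and_na_token(tmp_path):
    rng = np.random.default_rng(17)
    m = random_diploid_matrix(rng, n_sites=20, n_samples=6)
    wins = ws.make_windows({"chr1": 40}, 20)
    df = ws.window_stats_table(m, m.samples[:3], m.samples[3:], wins,
                               pop1_name="x", pop2_name="y")
    assert list(df.columns) == [
        "chrom", "start", "end", "n_snps", "pi_x", "pi_y", "S_x", "S_y",
        "D_x", "D_y", "fst_weighted", "fst_mean", "dxy", "fs",
    ]
    assert len(df) == 2
    path = tmp_path / "w.tsv"
    empty_win = ws.window_stats_table(
        m, m.samples[:3], m.samples[3:],
        [ws.Window("chr1", 100, 200)],
    )
    ws.write_stats_tsv(empty_win, str(path))
    text = path.read_text()
    assert "NA" in text  # undefined D/FST written as NA, not 0
    back = ws.read_stats_tsv(str(path))
    assert math.isnan(back.loc[0, "fst_weighted"])
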