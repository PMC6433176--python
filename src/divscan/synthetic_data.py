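"""Two-species divergence simulator with truth tracking.

Generates multi-sample genotype matrices (and VCFs) with the structure
the analysis pipeline assumes: two diploid species split from a common
ancestor, optional bottlenecks near the split, optional (possibly
time-restricted, i.e. secondary-contact) migration, optional selective
sweeps, F1 hybrids, several nuclear chromosomes and a short haploid
non-recombining organellar molecule.  Neutral coalescent realisations
come from msprime; sweeps are imposed post hoc by coalescing lineages
onto a sweeping haplotype with a distance-decaying capture probability
(an approximation whose bias is toward cleaner, more localised
footprints — downstream sweep tests rely on relative calibration only).

Every run emits a :class:`SimTruth` record sufficient to replay it.
"""

from __future__ import annotations

import dataclasses
import json
import math
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import msprime
import numpy as np

from .vcf_io import GenotypeMatrix, PopulationMap

CHLOROPLAST = "chloroplast"

_DEFAULT_NUCLEAR = {f"chr{i}": 5_000_000 for i in range(1, 8)}


@dataclass
class SweepConfig:
    """A completed hard sweep to stamp onto one species' haplotypes."""

    chrom: str
    position: int
    s: float = 0.05
    t_fix: float = 0.0  # generations since fixation
    species: str = "sp1"
    footprint: Optional[float] = None  # bp; derived from s, r, N when None

    def __post_init__(self) -> None:
        if self.s <= 0:
            raise ValueError("selection coefficient must be positive")

    def width(self, n_e: float, r: float) -> float:
        if self.footprint is not None:
            return self.footprint
        # classic hitchhiking footprint scale s / (r * ln(2 N s))
        return self.s / (r * max(math.log(max(2 * n_e * self.s, math.e)), 1.0))


@dataclass
class DemographyConfig:
    n_anc: float = 10_000
    n_sp1: float = 10_000
    n_sp2: float = 10_000
    t_split: float = 20_000  # generations
    # (time_ago, size, duration) per species; None disables
    bottleneck_sp1: Optional[tuple[float, float, float]] = None
    bottleneck_sp2: Optional[tuple[float, float, float]] = None
    migration_rate: float = 0.0
    migration_window: Optional[tuple[float, float]] = None  # (start, end) gens ago
    mu: float = 1e-8
    mu_chloroplast: float = 1e-9
    generation_time: float = 1.0  # years
    r: float = 1e-8
    chrom_lengths: dict = field(default_factory=lambda: dict(_DEFAULT_NUCLEAR))
    chloroplast_length: int = 129_000
    n_samples_sp1: int = 16
    n_samples_sp2: int = 16
    n_hybrids: int = 2
    seed: int = 1

    def validate(self) -> None:
        problems = []
        for name in ("n_anc", "n_sp1", "n_sp2", "mu", "mu_chloroplast", "r",
                     "migration_rate"):
            if getattr(self, name) < 0:
                problems.append(f"{name} must be >= 0")
        if self.t_split <= 0:
            problems.append("t_split must be positive")
        for sp, bn in (("sp1", self.bottleneck_sp1), ("sp2", self.bottleneck_sp2)):
            if bn is not None:
                t, size, dur = bn
                if t < 0 or size <= 0 or dur <= 0:
                    problems.append(f"bottleneck_{sp} times/sizes must be positive")
                if t + dur > self.t_split:
                    problems.append(
                        f"bottleneck_{sp} extends past t_split "
                        f"({t} + {dur} > {self.t_split})"
                    )
        if self.migration_window is not None:
            a, b = self.migration_window
            if not 0 <= a < b <= self.t_split:
                problems.append("migration_window must satisfy 0 <= start < end <= t_split")
        if problems:
            raise ValueError("infeasible demography config: " + "; ".join(problems))

    def sample_names(self) -> tuple[list[str], list[str], list[str]]:
        sp1 = [f"sp1_{i:02d}" for i in range(self.n_samples_sp1)]
        sp2 = [f"sp2_{i:02d}" for i in range(self.n_samples_sp2)]
        hyb = [f"hyb_{i:02d}" for i in range(self.n_hybrids)]
        return sp1, sp2, hyb

    def population_map(self) -> PopulationMap:
        """Species + geographic-group assignment mirroring the sampling design."""
        pm = PopulationMap()
        sp1, sp2, hyb = self.sample_names()
        for i, s in enumerate(sp1):
            pm.add(s, "sp1", "southern" if i < len(sp1) / 2 else "northern")
        groups2 = ["southern", "middle", "northern"]
        for i, s in enumerate(sp2):
            pm.add(s, "sp2", groups2[min(3 * i // max(len(sp2), 1), 2)])
        for s in hyb:
            pm.add(s, "hybrid", "hybrid")
        return pm


@dataclass
class SimTruth:
    config: DemographyConfig
    sweeps: list[SweepConfig]
    seed: int
    variant_counts: dict = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "config": dataclasses.asdict(self.config),
            "sweeps": [dataclasses.asdict(s) for s in self.sweeps],
            "seed": self.seed,
            "variant_counts": self.variant_counts,
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SimTruth":
        payload = json.loads(text)
        cfg = payload["config"]
        for key in ("bottleneck_sp1", "bottleneck_sp2", "migration_window"):
            if cfg.get(key) is not None:
                cfg[key] = tuple(cfg[key])
        return cls(
            config=DemographyConfig(**cfg),
            sweeps=[SweepConfig(**s) for s in payload["sweeps"]],
            seed=payload["seed"],
            variant_counts=payload["variant_counts"],
        )


def _build_demography(cfg: DemographyConfig) -> msprime.Demography:
    dem = msprime.Demography()
    dem.add_population(name="SP1", initial_size=cfg.n_sp1)
    dem.add_population(name="SP2", initial_size=cfg.n_sp2)
    dem.add_population(name="ANC", initial_size=cfg.n_anc)
    dem.add_population_split(time=cfg.t_split, derived=["SP1", "SP2"], ancestral="ANC")
    for pop, bn, base in (
        ("SP1", cfg.bottleneck_sp1, cfg.n_sp1),
        ("SP2", cfg.bottleneck_sp2, cfg.n_sp2),
    ):
        if bn is not None:
            t, size, dur = bn
            dem.add_population_parameters_change(time=t, population=pop, initial_size=size)
            dem.add_population_parameters_change(time=t + dur, population=pop, initial_size=base)
    if cfg.migration_rate > 0:
        if cfg.migration_window is None:
            dem.set_symmetric_migration_rate(["SP1", "SP2"], cfg.migration_rate)
        else:
            start, end = cfg.migration_window
            if start == 0:
                dem.set_symmetric_migration_rate(["SP1", "SP2"], cfg.migration_rate)
            else:
                dem.add_symmetric_migration_rate_change(
                    time=start, populations=["SP1", "SP2"], rate=cfg.migration_rate
                )
            dem.add_symmetric_migration_rate_change(
                time=end, populations=["SP1", "SP2"], rate=0.0
            )
    dem.sort_events()
    return dem


def _simulate_haplotypes(
    cfg: DemographyConfig,
    length: int,
    recomb: float,
    mu: float,
    ploidy: int,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Neutral realisation: (positions 1-based, haplotypes sites x n_hap)."""
    dem = _build_demography(cfg)
    ts = msprime.sim_ancestry(
        samples={"SP1": cfg.n_samples_sp1, "SP2": cfg.n_samples_sp2},
        demography=dem,
        sequence_length=length,
        recombination_rate=recomb,
        ploidy=ploidy,
        random_seed=seed,
    )
    ts = msprime.sim_mutations(ts, rate=mu, random_seed=seed + 7)
    positions = []
    rows = []
    for var in ts.variants():
        if len(var.alleles) != 2:
            continue  # multiallelic under the finite-sites overlay: drop
        positions.append(int(var.site.position) + 1)
        rows.append(var.genotypes.astype(np.int16))
    if not rows:
        return np.empty(0, dtype=int), np.empty((0, ts.num_samples), dtype=np.int16)
    return np.asarray(positions), np.vstack(rows)


def apply_sweep(
    haplotypes: np.ndarray,
    positions: np.ndarray,
    sweep_pos: int,
    width: float,
    rng: np.random.Generator,
    attenuation: float = 1.0,
) -> np.ndarray:
    """Coalesce haplotypes onto one sweeping haplotype near ``sweep_pos``.

    At each site, every haplotype is independently captured with
    probability ``attenuation * exp(-d / width)`` (d = distance in bp)
    and then carries the sweeping haplotype's allele; escapes keep their
    own.  Returns a modified copy.
    """
    out = haplotypes.copy()
    n_hap = out.shape[1]
    h_star = int(rng.integers(0, n_hap))
    d = np.abs(positions.astype(float) - sweep_pos)
    p_caught = attenuation * np.exp(-d / width)
    caught = rng.random((len(positions), n_hap)) < p_caught[:, None]
    caught[:, h_star] = False
    sweep_alleles = out[:, h_star]
    out[caught] = np.broadcast_to(sweep_alleles[:, None], out.shape)[caught]
    return out


def _meiosis(
    parent_calls: np.ndarray, positions: np.ndarray, length: int, r: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One recombinant gamete from a diploid parent's (sites, 2) calls."""
    n_cross = rng.poisson(r * length)
    breaks = np.sort(rng.integers(1, length + 1, size=n_cross))
    phase = int(rng.integers(0, 2))
    segment = np.searchsorted(breaks, positions, side="right")
    choose = (segment + phase) % 2
    return parent_calls[np.arange(len(positions)), choose]


def make_hybrids(
    matrix: GenotypeMatrix,
    sp1_samples: Sequence[str],
    sp2_samples: Sequence[str],
    n: int,
    seed: int,
    chrom_lengths: Optional[dict] = None,
    r: float = 1e-8,
) -> GenotypeMatrix:
    """F1 hybrids: one recombinant gamete from a random parent per species.

    Hybrids are heterozygous at every between-species fixed difference by
    construction.
    """
    if n < 1:
        raise ValueError("need n >= 1 hybrids")
    rng = np.random.default_rng(seed)
    idx1 = matrix.sample_indices(sp1_samples)
    idx2 = matrix.sample_indices(sp2_samples)
    names = [f"hyb_{i:02d}" for i in range(n)]
    calls = np.empty((matrix.n_sites, n, matrix.ploidy), dtype=matrix.calls.dtype)
    for h in range(n):
        for allele, idx in ((0, idx1), (1, idx2)):
            parent = int(rng.choice(idx))
            if matrix.ploidy == 1:
                calls[:, h, allele if matrix.ploidy > 1 else 0] = matrix.calls[:, parent, 0]
                continue
            gam = np.empty(matrix.n_sites, dtype=matrix.calls.dtype)
            for chrom in dict.fromkeys(matrix.chroms.tolist()):
                mask = matrix.chroms == chrom
                pos = matrix.positions[mask]
                length = int(chrom_lengths[chrom]) if chrom_lengths else int(pos.max())
                gam[mask] = _meiosis(matrix.calls[mask][:, parent, :], pos, length, r, rng)
            calls[:, h, allele] = gam
    return GenotypeMatrix(
        chroms=matrix.chroms,
        positions=matrix.positions,
        samples=names,
        calls=calls,
        ploidy=matrix.ploidy,
        ref=matrix.ref,
        alt=matrix.alt,
    )


def _append_samples(a: GenotypeMatrix, b: GenotypeMatrix) -> GenotypeMatrix:
    return GenotypeMatrix(
        chroms=a.chroms,
        positions=a.positions,
        samples=list(a.samples) + list(b.samples),
        calls=np.concatenate([a.calls, b.calls], axis=1),
        ploidy=a.ploidy,
        ref=a.ref,
        alt=a.alt,
    )


def simulate(
    cfg: DemographyConfig,
    sweeps: Sequence[SweepConfig] = (),
) -> tuple[dict[str, GenotypeMatrix], SimTruth]:
    """Run the full scenario; returns per-chromosome matrices and the truth.

    Keys of the returned dict are nuclear chromosome names plus
    ``"chloroplast"``.  Identical config and seed give identical output.
    """
    cfg.validate()
    for sw in sweeps:
        if sw.chrom not in cfg.chrom_lengths:
            raise ValueError(f"sweep chromosome {sw.chrom!r} not in chrom_lengths")
        if not 0 < sw.position <= cfg.chrom_lengths[sw.chrom]:
            raise ValueError(f"sweep position {sw.position} outside {sw.chrom}")
        if sw.species not in ("sp1", "sp2"):
            raise ValueError("sweep species must be 'sp1' or 'sp2'")

    sp1_names, sp2_names, hyb_names = cfg.sample_names()
    ss = np.random.SeedSequence(cfg.seed)
    chrom_seeds = ss.generate_state(len(cfg.chrom_lengths) + 2)
    rng = np.random.default_rng(ss.spawn(1)[0])

    matrices: dict[str, GenotypeMatrix] = {}
    counts: dict[str, int] = {}
    n1h = 2 * cfg.n_samples_sp1  # haplotype columns of sp1 come first
    for ci, (chrom, length) in enumerate(cfg.chrom_lengths.items()):
        seed_c = int(chrom_seeds[ci] % (2**31 - 2)) + 1
        positions, hap = _simulate_haplotypes(
            cfg, length, cfg.r, cfg.mu, ploidy=2, seed=seed_c
        )
        for sw in sweeps:
            if sw.chrom != chrom or len(positions) == 0:
                continue
            cols = slice(0, n1h) if sw.species == "sp1" else slice(n1h, hap.shape[1])
            n_e = cfg.n_sp1 if sw.species == "sp1" else cfg.n_sp2
            width = sw.width(n_e, cfg.r)
            atten = math.exp(-sw.t_fix / (2.0 * n_e)) if n_e > 0 else 1.0
            hap[:, cols] = apply_sweep(
                hap[:, cols], positions, sw.position, width, rng, attenuation=atten
            )
        if len(positions):
            variable = (hap > 0).any(axis=1)  # sweeps can fix the ancestral allele
            positions, hap = positions[variable], hap[variable]
        n_ind = hap.shape[1] // 2
        calls = hap.reshape(len(positions), n_ind, 2)
        matrix = GenotypeMatrix(
            chroms=np.full(len(positions), chrom, dtype=object),
            positions=positions.astype(int),
            samples=sp1_names + sp2_names,
            calls=calls.astype(np.int16),
            ploidy=2,
            ref=np.full(len(positions), "A", dtype=object),
            alt=np.full(len(positions), "T", dtype=object),
        )
        if cfg.n_hybrids > 0:
            hyb = make_hybrids(
                matrix, sp1_names, sp2_names, cfg.n_hybrids,
                seed=int(chrom_seeds[ci] % (2**31 - 2)) + 11,
                chrom_lengths={chrom: length}, r=cfg.r,
            )
            matrix = _append_samples(matrix, hyb)
        matrices[chrom] = matrix
        counts[chrom] = matrix.n_sites

    # chloroplast: haploid, non-recombining, uniparental
    seed_cp = int(chrom_seeds[-1] % (2**31 - 2)) + 1
    positions, hap = _simulate_haplotypes(
        cfg, cfg.chloroplast_length, 0.0, cfg.mu_chloroplast, ploidy=1, seed=seed_cp
    )
    cp_rng = np.random.default_rng(seed_cp + 3)
    n_total = cfg.n_samples_sp1 + cfg.n_samples_sp2 + cfg.n_hybrids
    hyb_cols = []
    for _ in range(cfg.n_hybrids):  # maternal (sp1-side) transmission
        donor = int(cp_rng.integers(0, cfg.n_samples_sp1))
        hyb_cols.append(hap[:, donor])
    if hyb_cols:
        hap = np.column_stack([hap] + hyb_cols) if len(positions) else hap
    if len(positions) == 0:
        hap = np.empty((0, n_total), dtype=np.int16)
    matrices[CHLOROPLAST] = GenotypeMatrix(
        chroms=np.full(len(positions), CHLOROPLAST, dtype=object),
        positions=positions.astype(int),
        samples=sp1_names + sp2_names + hyb_names,
        calls=hap.reshape(len(positions), n_total, 1).astype(np.int16),
        ploidy=1,
        ref=np.full(len(positions), "A", dtype=object),
        alt=np.full(len(positions), "T", dtype=object),
    )
    counts[CHLOROPLAST] = matrices[CHLOROPLAST].n_sites

    truth = SimTruth(config=cfg, sweeps=list(sweeps), seed=cfg.seed,
                     variant_counts=counts)
    return matrices, truth


_BASES = np.array(list("ACGT"))


def write_vcf(
    matrices: dict[str, GenotypeMatrix],
    truth: SimTruth,
    outdir: str,
    dp_mean: float = 30.0,
    mq: float = 60.0,
) -> dict[str, str]:
    """Write nuclear + organellar VCFs, population map and truth sidecar.

    MQ (site INFO) and per-sample DP (FORMAT) are populated so the
    variant-filter path is exercised; DP is Poisson(``dp_mean``) from the
    truth seed, so output is reproducible byte for byte.
    """
    os.makedirs(outdir, exist_ok=True)
    rng = np.random.default_rng(truth.seed ^ 0x5EED)
    paths = {}

    def write_one(path: str, mats: list[GenotypeMatrix]) -> None:
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write("##source=divscan-simulate\n")
            fh.write('##INFO=<ID=MQ,Number=1,Type=Float,Description="Mapping quality">\n')
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
            for m in mats:
                for chrom in dict.fromkeys(m.chroms.tolist()):
                    clen = truth.config.chrom_lengths.get(
                        chrom, truth.config.chloroplast_length
                    )
                    fh.write(f"##contig=<ID={chrom},length={clen}>\n")
            samples = mats[0].samples
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + "\t".join(samples) + "\n"
            )
            for m in mats:
                refs = _BASES[rng.integers(0, 4, size=m.n_sites)]
                dp = rng.poisson(dp_mean, size=(m.n_sites, m.n_samples))
                for i in range(m.n_sites):
                    ref = refs[i]
                    alt = "T" if ref != "T" else "C"
                    fields = []
                    for j in range(m.n_samples):
                        gt = "/".join(str(int(a)) for a in m.calls[i, j])
                        fields.append(f"{gt}:{dp[i, j]}")
                    fh.write(
                        f"{m.chroms[i]}\t{m.positions[i]}\t.\t{ref}\t{alt}\t.\tPASS"
                        f"\tMQ={mq:g}\tGT:DP\t" + "\t".join(fields) + "\n"
                    )

    nuclear = [m for c, m in matrices.items() if c != CHLOROPLAST]
    if nuclear:
        paths["nuclear"] = os.path.join(outdir, "nuclear.vcf")
        write_one(paths["nuclear"], nuclear)
    if CHLOROPLAST in matrices:
        paths["chloroplast"] = os.path.join(outdir, "chloroplast.vcf")
        write_one(paths["chloroplast"], [matrices[CHLOROPLAST]])

    paths["popmap"] = os.path.join(outdir, "popmap.tsv")
    truth.config.population_map().write_tsv(paths["popmap"])
    paths["truth"] = os.path.join(outdir, "truth.json")
    with open(paths["truth"], "w") as fh:
        fh.write(truth.to_json() + "\n")
    return paths
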