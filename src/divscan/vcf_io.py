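"""VCF reading, variant filtering, and genotype-matrix construction.

Genotypes are held as integer allele indices in a sites x samples x ploidy
array with ``-1`` marking missing calls, so a missing genotype is always
distinguishable from homozygous reference.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
from cyvcf2 import VCF

log = logging.getLogger(__name__)

MISSING = -1

#: default per-site missing-genotype ceiling (fraction of samples)
DEFAULT_MAX_MISSING = 0.20


class VcfParseError(ValueError):
    """Raised when a VCF record or header cannot be interpreted."""


@dataclass
class VariantSite:
    """A single VCF record with the annotations the filters need."""

    chrom: str
    pos: int  # 1-based
    ref_allele: str
    alt_alleles: list[str]
    site_quality_mq: Optional[float]
    genotypes: np.ndarray  # (n_samples, ploidy) allele indices, -1 missing
    per_sample_depth: Optional[np.ndarray]  # (n_samples,) or None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise VcfParseError(f"position must be >= 1, got {self.pos}")
        n_alleles = 1 + len(self.alt_alleles)
        gt = np.asarray(self.genotypes)
        if gt.size and (gt.max() >= n_alleles or (gt[gt != MISSING].size and gt[gt != MISSING].min() < 0)):
            raise VcfParseError(
                f"{self.chrom}:{self.pos}: allele index out of range for "
                f"{n_alleles} alleles"
            )

    @property
    def is_snp(self) -> bool:
        return len(self.ref_allele) == 1 and all(len(a) == 1 for a in self.alt_alleles)

    @property
    def is_biallelic(self) -> bool:
        return len(self.alt_alleles) == 1

    @property
    def ploidy(self) -> int:
        return self.genotypes.shape[1]


@dataclass
class GenotypeMatrix:
    """Sites x samples genotype calls with an explicit missing state.

    ``calls`` has shape (n_sites, n_samples, ploidy); entries are allele
    indices (0 = ref, 1 = alt) or ``MISSING``.
    """

    chroms: np.ndarray  # (n_sites,) str
    positions: np.ndarray  # (n_sites,) int, 1-based
    samples: list[str]
    calls: np.ndarray
    ploidy: int
    ref: Optional[np.ndarray] = None  # per-site ref allele strings
    alt: Optional[np.ndarray] = None  # per-site alt allele strings

    def __post_init__(self) -> None:
        if self.calls.ndim != 3:
            raise ValueError("calls must be (sites, samples, ploidy)")
        n_sites, n_samples, ploidy = self.calls.shape
        if n_sites != len(self.chroms) or n_sites != len(self.positions):
            raise ValueError("site annotation length mismatch")
        if n_samples != len(self.samples):
            raise ValueError("sample count mismatch")
        if ploidy != self.ploidy:
            raise ValueError("ploidy mismatch with calls array")

    @property
    def n_sites(self) -> int:
        return self.calls.shape[0]

    @property
    def n_samples(self) -> int:
        return self.calls.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        """(sites, samples) True where the genotype has any missing allele."""
        return (self.calls == MISSING).any(axis=2)

    def sample_indices(self, samples: Sequence[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([lookup[s] for s in samples], dtype=int)
        except KeyError as exc:
            raise KeyError(f"sample {exc.args[0]!r} not in matrix") from None

    def take_sites(self, idx: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            chroms=self.chroms[idx],
            positions=self.positions[idx],
            samples=list(self.samples),
            calls=self.calls[idx],
            ploidy=self.ploidy,
            ref=None if self.ref is None else self.ref[idx],
            alt=None if self.alt is None else self.alt[idx],
        )

    def subset_samples(self, samples: Sequence[str]) -> "GenotypeMatrix":
        idx = self.sample_indices(samples)
        return GenotypeMatrix(
            chroms=self.chroms,
            positions=self.positions,
            samples=[self.samples[i] for i in idx],
            calls=self.calls[:, idx, :],
            ploidy=self.ploidy,
            ref=self.ref,
            alt=self.alt,
        )


@dataclass
class PopulationMap:
    """Sample -> (species, geographic group) assignment."""

    species: dict[str, str] = field(default_factory=dict)
    group: dict[str, str] = field(default_factory=dict)

    def add(self, sample: str, species: str, group: str) -> None:
        if sample in self.species:
            raise ValueError(f"duplicate sample {sample!r} in population map")
        self.species[sample] = species
        self.group[sample] = group

    @property
    def samples(self) -> list[str]:
        return list(self.species)

    def species_labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for sp in self.species.values():
            seen.setdefault(sp, None)
        return list(seen)

    def samples_of_species(self, species: str) -> list[str]:
        return [s for s, sp in self.species.items() if sp == species]

    def samples_of_group(self, group: str) -> list[str]:
        return [s for s, g in self.group.items() if g == group]

    def validate_against(self, matrix: GenotypeMatrix) -> None:
        missing = [s for s in matrix.samples if s not in self.species]
        if missing:
            raise ValueError(f"samples without population assignment: {missing}")

    @classmethod
    def read_tsv(cls, path: str) -> "PopulationMap":
        """Read a 3-column ``sample<TAB>species<TAB>group`` file; # comments."""
        pm = cls()
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 3:
                    raise VcfParseError(
                        f"{path}:{lineno}: expected 3 tab-separated columns, "
                        f"got {len(parts)}"
                    )
                pm.add(*parts)
        return pm

    def write_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("#sample\tspecies\tgroup\n")
            for s in self.species:
                fh.write(f"{s}\t{self.species[s]}\t{self.group[s]}\n")


def read_vcf(path: str, region: Optional[str] = None) -> Iterator[VariantSite]:
    """Yield :class:`VariantSite` records from a VCF in coordinate order.

    Parameters
    ----------
    path
        Plain or bgzipped VCF v4.x file.
    region
        Optional ``chrom`` or ``chrom:start-end`` restriction (requires an
        index for bgzipped input; plain VCFs are scanned linearly).
    """
    try:
        vcf = VCF(path, gts012=False)
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception on bad headers
        raise VcfParseError(f"{path}: cannot parse VCF header: {exc}") from exc

    n_samples = len(vcf.samples)
    it: Iterable = vcf(region) if region else vcf
    expected_ploidy: Optional[int] = None
    recno = 0
    for rec in it:
        recno += 1
        # genotype array: columns are alleles + phase flag
        gt = np.asarray(rec.genotype.array())
        if gt.ndim != 2 or gt.shape[0] != n_samples:
            raise VcfParseError(f"{path}: record {recno} ({rec.CHROM}:{rec.POS}): bad genotype block")
        alleles = gt[:, :-1].astype(np.int16)  # strip phase column
        ploidy = alleles.shape[1]
        if expected_ploidy is None:
            expected_ploidy = ploidy
        elif ploidy != expected_ploidy:
            raise VcfParseError(
                f"{path}: record {recno} ({rec.CHROM}:{rec.POS}): ploidy {ploidy} "
                f"differs from {expected_ploidy}; mixed-ploidy input is not supported"
            )
        alleles[alleles < 0] = MISSING

        mq = rec.INFO.get("MQ")
        dp = None
        try:
            dp_arr = rec.format("DP")
        except KeyError:
            dp_arr = None
        if dp_arr is not None:
            dp = dp_arr.reshape(-1).astype(float)
            dp[dp < 0] = np.nan
        else:
            site_dp = rec.INFO.get("DP")
            if site_dp is not None:
                log.warning(
                    "%s:%s no per-sample DP; falling back to site DP / n_samples",
                    rec.CHROM, rec.POS,
                )
                dp = np.full(n_samples, float(site_dp) / n_samples)

        yield VariantSite(
            chrom=rec.CHROM,
            pos=rec.POS,
            ref_allele=rec.REF,
            alt_alleles=list(rec.ALT),
            site_quality_mq=float(mq) if mq is not None else None,
            genotypes=alleles,
            per_sample_depth=dp,
        )


def filter_variants(
    sites: Iterable[VariantSite],
    mq_min: Optional[float] = 20.0,
    depth_min: Optional[float] = 3.0,
    max_missing: float = DEFAULT_MAX_MISSING,
    snps_only: bool = True,
) -> GenotypeMatrix:
    """Apply the variant filters and assemble a biallelic genotype matrix.

    Thresholds are strict: a site passes only with MQ > ``mq_min`` and a
    genotype is kept only with per-sample depth > ``depth_min``; genotypes
    failing the depth rule are set to missing.  Sites without an MQ
    annotation fail the MQ rule.  Passing ``None`` disables a threshold.
    Multiallelic sites are dropped, not decomposed.  Sites whose missing
    fraction after the depth rule exceeds ``max_missing`` are removed.
    """
    chroms: list[str] = []
    positions: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    calls: list[np.ndarray] = []
    samples: Optional[list[str]] = None
    ploidy: Optional[int] = None

    for site in sites:
        if ploidy is None:
            ploidy = site.ploidy
        elif site.ploidy != ploidy:
            raise VcfParseError(
                f"{site.chrom}:{site.pos}: mixed ploidy within one matrix"
            )
        if not site.is_biallelic:
            continue
        if snps_only and not site.is_snp:
            continue
        if mq_min is not None and (
            site.site_quality_mq is None or not site.site_quality_mq > mq_min
        ):
            continue
        gt = site.genotypes.copy()
        if depth_min is not None and site.per_sample_depth is not None:
            low = ~(site.per_sample_depth > depth_min)  # NaN depth -> missing
            gt[low, :] = MISSING
        miss_frac = (gt == MISSING).any(axis=1).mean()
        if miss_frac > max_missing:
            continue
        chroms.append(site.chrom)
        positions.append(site.pos)
        refs.append(site.ref_allele)
        alts.append(site.alt_alleles[0])
        calls.append(gt)

    if ploidy is None:
        ploidy = 2
    if not calls:
        warnings.warn("all sites removed by filters; matrix is empty")
        n_samp = 0 if samples is None else len(samples)
        return GenotypeMatrix(
            chroms=np.array([], dtype=object),
            positions=np.array([], dtype=int),
            samples=[],
            calls=np.empty((0, n_samp, ploidy), dtype=np.int16),
            ploidy=ploidy,
        )

    arr = np.stack(calls).astype(np.int16)
    return GenotypeMatrix(
        chroms=np.array(chroms, dtype=object),
        positions=np.array(positions, dtype=int),
        samples=[f"S{i}" for i in range(arr.shape[1])],
        calls=arr,
        ploidy=ploidy,
        ref=np.array(refs, dtype=object),
        alt=np.array(alts, dtype=object),
    )


def matrix_from_vcf(
    path: str,
    region: Optional[str] = None,
    mq_min: Optional[float] = 20.0,
    depth_min: Optional[float] = 3.0,
    max_missing: float = DEFAULT_MAX_MISSING,
    snps_only: bool = True,
) -> GenotypeMatrix:
    """Read + filter in one pass, preserving the VCF's sample names."""
    vcf = VCF(path)
    sample_names = list(vcf.samples)
    vcf.close()
    matrix = filter_variants(
        read_vcf(path, region=region),
        mq_min=mq_min,
        depth_min=depth_min,
        max_missing=max_missing,
        snps_only=snps_only,
    )
    if matrix.n_sites and len(sample_names) != matrix.n_samples:
        raise VcfParseError(f"{path}: sample count changed during filtering")
    matrix.samples = sample_names if sample_names else matrix.samples
    return matrix


def split_hom_het(matrix: GenotypeMatrix) -> tuple[GenotypeMatrix, GenotypeMatrix]:
    """Split into the all-homozygous matrix and the full matrix.

    Only sites with no missing data are eligible (both outputs are
    restricted to them).  The first output keeps exactly the sites at which
    every sample is homozygous; the second keeps all complete sites.
    """
    if matrix.ploidy != 2:
        raise ValueError("hom/het split is defined for diploid matrices only")
    complete = ~matrix.missing_mask.any(axis=1)
    full = matrix.take_sites(np.flatnonzero(complete))
    het_any = (full.calls[:, :, 0] != full.calls[:, :, 1]).any(axis=1)
    hom = full.take_sites(np.flatnonzero(~het_any))
    return hom, full


def allele_counts(
    matrix: GenotypeMatrix, population: Sequence[str]
) -> np.ndarray:
    """Per-site (ref count, alt count, called total) for a sample subset.

    Missing alleles are excluded; columns satisfy ref + alt == total.
    """
    if len(population) == 0:
        raise ValueError("empty population")
    idx = matrix.sample_indices(population)
    sub = matrix.calls[:, idx, :]
    called = sub != MISSING
    alt = ((sub == 1) & called).sum(axis=(1, 2))
    total = called.sum(axis=(1, 2))
    ref = total - alt
    return np.stack([ref, alt, total], axis=1).astype(np.int64)


def het_counts(matrix: GenotypeMatrix, population: Sequence[str]) -> np.ndarray:
    """Per-site (n heterozygous individuals, n fully-called individuals)."""
    idx = matrix.sample_indices(population)
    sub = matrix.calls[:, idx, :]
    full_call = (sub != MISSING).all(axis=2)
    if matrix.ploidy == 1:
        het = np.zeros(matrix.n_sites, dtype=np.int64)
    else:
        het = ((sub[:, :, 0] != sub[:, :, 1]) & full_call).sum(axis=1)
    return np.stack([het, full_call.sum(axis=1)], axis=1).astype(np.int64)


def write_vcf(matrix: GenotypeMatrix, path: str, extra_header: Sequence[str] = ()) -> None:
    """Write a GenotypeMatrix back out as a minimal VCF v4.2 file."""
    ref = matrix.ref if matrix.ref is not None else np.full(matrix.n_sites, "A", dtype=object)
    alt = matrix.alt if matrix.alt is not None else np.full(matrix.n_sites, "T", dtype=object)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for line in extra_header:
            fh.write(line.rstrip("\n") + "\n")
        for chrom in dict.fromkeys(matrix.chroms.tolist()):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.samples)
            + "\n"
        )
        sep = "/"
        for i in range(matrix.n_sites):
            gts = []
            for j in range(matrix.n_samples):
                al = matrix.calls[i, j]
                gts.append(sep.join("." if a == MISSING else str(int(a)) for a in al))
            fh.write(
                f"{matrix.chroms[i]}\t{matrix.positions[i]}\t.\t{ref[i]}\t{alt[i]}"
                f"\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
            )


def write_matrix_tsv(matrix: GenotypeMatrix, path: str) -> None:
    """Debug dump: one row per site, genotypes as a/b strings."""
    with open(path, "w") as fh:
        fh.write("chrom\tpos\t" + "\t".join(matrix.samples) + "\n")
        for i in range(matrix.n_sites):
            gts = [
                "/".join("." if a == MISSING else str(int(a)) for a in matrix.calls[i, j])
                for j in range(matrix.n_samples)
            ]
            fh.write(f"{matrix.chroms[i]}\t{matrix.positions[i]}\t" + "\t".join(gts) + "\n")
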