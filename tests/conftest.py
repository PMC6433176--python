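import textwrap

import numpy as np
import pytest

from divscan.vcf_io import GenotypeMatrix


@pytest.fixture
def write_vcf_text(tmp_path):
    """Write a VCF file from header spec + record lines; returns the path."""

    def _write(records, samples=("A", "B"), name="test.vcf"):
        header = textwrap.dedent(
            """\
            ##fileformat=VCFv4.2
            ##INFO=<ID=MQ,Number=1,Type=Float,Description="Mapping quality">
            ##INFO=<ID=DP,Number=1,Type=Integer,Description="Depth">
            ##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
            ##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">
            ##contig=<ID=chr1,length=1000000>
            ##contig=<ID=chr2,length=1000000>
            """
        )
        path = tmp_path / name
        body = "\n".join(records)
        cols = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples)
        path.write_text(header + cols + "\n" + (body + "\n" if body else ""))
        return str(path)

    return _write


def diploid_matrix(genotypes, positions=None, chrom="chr1", samples=None):
    """Build a diploid GenotypeMatrix from a nested list.

    ``genotypes[site][sample]`` is a (a, b) pair; -1 marks missing.
    """
    calls = np.asarray(genotypes, dtype=np.int16)
    n_sites, n_samples = calls.shape[0], calls.shape[1]
    if positions is None:
        positions = list(range(1, n_sites + 1))
    if samples is None:
        samples = [f"S{i}" for i in range(n_samples)]
    return GenotypeMatrix(
        chroms=np.full(n_sites, chrom, dtype=object),
        positions=np.asarray(positions, dtype=int),
        samples=list(samples),
        calls=calls,
        ploidy=2,
        ref=np.full(n_sites, "A", dtype=object),
        alt=np.full(n_sites, "T", dtype=object),
    )


def haploid_matrix(genotypes, positions=None, chrom="chloroplast", samples=None):
    calls = np.asarray(genotypes, dtype=np.int16)[:, :, None]
    n_sites, n_samples = calls.shape[0], calls.shape[1]
    if positions is None:
        positions = list(range(1, n_sites + 1))
    if samples is None:
        samples = [f"H{i}" for i in range(n_samples)]
    return GenotypeMatrix(
        chroms=np.full(n_sites, chrom, dtype=object),
        positions=np.asarray(positions, dtype=int),
        samples=list(samples),
        calls=calls,
        ploidy=1,
        ref=np.full(n_sites, "A", dtype=object),
        alt=np.full(n_sites, "T", dtype=object),
    )


def random_diploid_matrix(rng, n_sites=30, n_samples=6, p_missing=0.0):
    calls = rng.integers(0, 2, size=(n_sites, n_samples, 2)).astype(np.int16)
    if p_missing > 0:
        miss = rng.random((n_sites, n_samples)) < p_missing
        calls[miss] = -1
    return diploid_matrix(calls)


def haplotypes_of(matrix, samples):
    """All haplotype columns (sites x n_haplotypes) for a sample subset."""
    idx = matrix.sample_indices(samples)
    sub = matrix.calls[:, idx, :]
    return sub.reshape(matrix.n_sites, -1)
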