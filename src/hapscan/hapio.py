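"""Phased-haplotype input/output.

Reads phased, biallelic VCFs into :class:`HaplotypeMatrix` objects (one per
population), applies simple site filters, and writes toy/simulated matrices
back out as VCF for round-tripping.  All coordinates at the interface are
1-based inclusive base pairs.

Missing or unphased genotypes are hard errors: the scan statistics are only
defined on complete phased data, so anything short of that is rejected at
load time rather than silently imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


class VcfContractError(ValueError):
    """Input VCF violates the phased-biallelic input contract."""


@dataclass
class HaplotypeMatrix:
    """Phased binary haplotypes by ordered sites for one population.

    Parameters
    ----------
    chrom
        Chromosome label shared by all sites.
    positions
        Physical coordinates in bp, 1-based, strictly increasing.
    alleles
        ``(n_haplotypes, n_sites)`` array with values in {0, 1}; 0 is the
        reference/ancestral allele, 1 the alternate/derived allele.
    sample_ids
        One label per haplotype (two per diploid sample).
    """

    chrom: str
    positions: np.ndarray
    alleles: np.ndarray
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.alleles = np.asarray(self.alleles, dtype=np.uint8)
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be a 2-D haplotype-by-site array")
        if self.alleles.shape[0] < 1:
            raise ValueError("need at least one haplotype")
        if self.alleles.shape[1] != self.positions.shape[0]:
            raise ValueError(
                f"{self.alleles.shape[1]} allele columns but "
                f"{self.positions.shape[0]} positions"
            )
        if self.positions.size and np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if self.alleles.size and self.alleles.max() > 1:
            raise ValueError("allele values must be 0 or 1")
        if not self.sample_ids:
            self.sample_ids = [f"hap{i}" for i in range(self.alleles.shape[0])]
        if len(self.sample_ids) != self.alleles.shape[0]:
            raise ValueError("one sample_id required per haplotype")

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    def derived_freq(self) -> np.ndarray:
        """Frequency of the 1 (alternate/derived) allele at each site."""
        return self.alleles.mean(axis=0)

    def take_sites(self, index: np.ndarray) -> "HaplotypeMatrix":
        """New matrix restricted to the given site index (order preserved)."""
        return HaplotypeMatrix(
            chrom=self.chrom,
            positions=self.positions[index],
            alleles=self.alleles[:, index],
            sample_ids=list(self.sample_ids),
        )


@dataclass
class PopulationMap:
    """Assignment of sample ids to population labels."""

    assignments: dict[str, str]

    def __post_init__(self) -> None:
        pops = self.populations()
        if not pops:
            raise ValueError("population map is empty")

    def populations(self) -> list[str]:
        seen: list[str] = []
        for p in self.assignments.values():
            if p not in seen:
                seen.append(p)
        return seen

    def samples(self, population: str) -> list[str]:
        return [s for s, p in self.assignments.items() if p == population]

    def require_two_populations(self) -> tuple[str, str]:
        pops = self.populations()
        if len(pops) != 2:
            raise ValueError(
                f"cross-population scan needs exactly 2 populations, got {pops}"
            )
        if not self.samples(pops[0]) or not self.samples(pops[1]):
            raise ValueError("both populations must be non-empty")
        return pops[0], pops[1]


def read_popmap(path: str | Path) -> PopulationMap:
    """Read a two-column TSV of ``sample_id<TAB>population``."""
    assignments: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            sample, pop = parts
            if sample in assignments:
                raise ValueError(f"{path}:{lineno}: duplicate sample {sample!r}")
            assignments[sample] = pop
    return PopulationMap(assignments)


def read_phased_vcf(path: str | Path, samples: list[str] | None = None) -> HaplotypeMatrix:
    """Load a phased biallelic VCF into a haplotype matrix.

    Every requested sample contributes two haplotype rows (``<id>_1`` and
    ``<id>_2``), in the sample order given (file order when *samples* is
    None).  The VCF must contain a single chromosome; records must be
    biallelic SNVs or indels with fully phased, non-missing genotypes.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    if samples is not None:
        missing = set(samples) - set(vcf.samples)
        if missing:
            raise VcfContractError(f"samples not in VCF: {sorted(missing)}")
        vcf.set_samples(samples)
        order = [vcf.samples.index(s) for s in samples]
    else:
        samples = list(vcf.samples)
        order = list(range(len(samples)))
    if not samples:
        raise VcfContractError("VCF contains no samples")

    chrom = None
    positions: list[int] = []
    columns: list[np.ndarray] = []
    for var in vcf:
        where = f"{var.CHROM}:{var.POS}"
        if chrom is None:
            chrom = var.CHROM
        elif var.CHROM != chrom:
            raise VcfContractError(
                f"multiple chromosomes in one matrix ({chrom} and {var.CHROM})"
            )
        if len(var.ALT) != 1:
            raise VcfContractError(f"multiallelic record at {where}")
        col = np.empty(2 * len(samples), dtype=np.uint8)
        genos = var.genotypes
        for out_idx, samp_idx in enumerate(order):
            g = genos[samp_idx]
            if len(g) != 3:
                raise VcfContractError(
                    f"non-diploid genotype at {where} sample {samples[out_idx]!r}"
                )
            a, b, phased = g[0], g[1], g[2]
            if a < 0 or b < 0:
                raise VcfContractError(
                    f"missing genotype at {where} sample {samples[out_idx]!r}"
                )
            if not phased:
                raise VcfContractError(
                    f"unphased genotype at {where} sample {samples[out_idx]!r}"
                )
            col[2 * out_idx] = a
            col[2 * out_idx + 1] = b
        positions.append(var.POS)
        columns.append(col)
    vcf.close()
    if not columns:
        raise VcfContractError(f"no usable records in {path}")
    hap_ids = [f"{s}_{h}" for s in samples for h in (1, 2)]
    return HaplotypeMatrix(
        chrom=str(chrom),
        positions=np.array(positions, dtype=np.int64),
        alleles=np.column_stack(columns),
        sample_ids=hap_ids,
    )


def write_phased_vcf(
    matrix: HaplotypeMatrix,
    path: str | Path,
    sample_names: list[str] | None = None,
) -> Path:
    """Write a haplotype matrix as a phased VCF (fixture writer).

    Consecutive haplotype rows are paired into diploid samples, so the
    haplotype count must be even.  Round-trips exactly through
    :func:`read_phased_vcf`.
    """
    if matrix.n_haplotypes % 2 != 0:
        raise ValueError("need an even number of haplotypes to write diploid VCF")
    n_samp = matrix.n_haplotypes // 2
    if sample_names is None:
        sample_names = [f"s{i}" for i in range(n_samp)]
    if len(sample_names) != n_samp:
        raise ValueError(f"expected {n_samp} sample names")
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={matrix.chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_names)
            + "\n"
        )
        for j in range(matrix.n_sites):
            gts = "\t".join(
                f"{matrix.alleles[2 * i, j]}|{matrix.alleles[2 * i + 1, j]}"
                for i in range(n_samp)
            )
            fh.write(
                f"{matrix.chrom}\t{matrix.positions[j]}\t.\tA\tT\t.\tPASS\t.\tGT\t{gts}\n"
            )
    return path


def _maf(freq: np.ndarray) -> np.ndarray:
    return np.minimum(freq, 1.0 - freq)


def filter_sites(matrix: HaplotypeMatrix, maf_min: float) -> HaplotypeMatrix:
    """Drop sites with minor allele frequency below *maf_min*.

    Frequency is computed over all haplotypes in the matrix; site order is
    preserved.  ``maf_min=0`` is the identity.
    """
    if not 0 <= maf_min < 0.5:
        raise ValueError("maf_min must be in [0, 0.5)")
    keep = _maf(matrix.derived_freq()) >= maf_min
    return matrix.take_sites(np.flatnonzero(keep))


def filter_sites_joint(
    pop1: HaplotypeMatrix, pop2: HaplotypeMatrix, maf_min: float
) -> tuple[HaplotypeMatrix, HaplotypeMatrix]:
    """Joint MAF filter over the pooled haplotypes of a population pair."""
    if not 0 <= maf_min < 0.5:
        raise ValueError("maf_min must be in [0, 0.5)")
    if not np.array_equal(pop1.positions, pop2.positions):
        raise ValueError("population matrices must share the same site list")
    n1, n2 = pop1.n_haplotypes, pop2.n_haplotypes
    pooled = (n1 * pop1.derived_freq() + n2 * pop2.derived_freq()) / (n1 + n2)
    keep = np.flatnonzero(_maf(pooled) >= maf_min)
    return pop1.take_sites(keep), pop2.take_sites(keep)
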