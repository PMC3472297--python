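"""Per-SNP, per-cell-type integer genotypes for simulated tumour samples.

A sample is a mixture of one normal cell type and one or more tumour
subclones.  Each locus carries, per cell type, a total copy number ``x`` and
a B-allele count ``z`` with ``0 <= z <= x``.  Two coherence rules hold:

* loci homozygous in the normal cells stay homozygous, for the same allele,
  in every tumour subclone;
* within one altered region all heterozygous loci must be explainable by a
  single per-clone event acting on the two parental haplotypes, so across
  SNPs the B-allele count can only flip between ``m`` and ``x - m`` where
  ``(m, x - m)`` are the per-haplotype copy counts of the event.

Phases (which parental haplotype carries the B allele at a heterozygous SNP)
are i.i.d. fair coin flips, sampled once per SNP and shared by all clones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SNPGrid",
    "CellPopulation",
    "RegionSpec",
    "GenotypeMatrix",
    "RegionSpecError",
    "sample_normal_genotypes",
    "enumerate_tumour_genotypes",
    "assign_region_genotypes",
    "validate_region",
]


class RegionSpecError(ValueError):
    """A region specification is internally inconsistent."""


def _rng(seed):
    """Coerce an int seed / SeedSequence / Generator into a Generator."""
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class SNPGrid:
    """The probe scaffold: names, coordinates and population B-allele freqs."""

    probe_name: np.ndarray
    chrom: np.ndarray
    position: np.ndarray
    pfb: np.ndarray

    def __post_init__(self):
        n = len(self.probe_name)
        if not (len(self.chrom) == len(self.position) == len(self.pfb) == n):
            raise ValueError("SNPGrid arrays must have equal length")
        pfb = np.asarray(self.pfb, dtype=float)
        if np.any(pfb < 0) or np.any(pfb > 1) or np.any(~np.isfinite(pfb)):
            raise ValueError("pfb values must lie in [0, 1]")
        if len(np.unique(self.probe_name)) != n:
            raise ValueError("probe names must be unique")
        # positions strictly increasing within each chromosome
        chrom = np.asarray(self.chrom)
        pos = np.asarray(self.position)
        for c in np.unique(chrom):
            p = pos[chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on {c}")

    def __len__(self) -> int:
        return len(self.probe_name)

    @classmethod
    def synthetic(cls, pfb, snps_per_chrom: int = 2000, spacing_bp: int = 5000,
                  prefix: str = "chr") -> "SNPGrid":
        """Build an evenly spaced synthetic grid from a PFB vector.

        SNP ``k`` (0-based within its chromosome) sits at 1-based position
        ``k * spacing_bp + 1``, so the bp interval covered by SNP indices
        ``[a, b)`` is ``[a * spacing_bp, b * spacing_bp)`` in BED coordinates.
        """
        pfb = np.asarray(pfb, dtype=float)
        n = len(pfb)
        idx = np.arange(n)
        chrom_idx = idx // snps_per_chrom
        within = idx % snps_per_chrom
        chrom = np.array([f"{prefix}{i + 1}" for i in chrom_idx])
        position = within * spacing_bp + 1
        names = np.array([f"snp{i:07d}" for i in idx])
        return cls(probe_name=names, chrom=chrom, position=position, pfb=pfb)


@dataclass(frozen=True)
class CellPopulation:
    """Mixture structure of the sample: one normal type plus tumour clones."""

    n_cell_types: int
    normal_fraction: float

    def __post_init__(self):
        if self.n_cell_types < 1:
            raise ValueError("n_cell_types must be >= 1")
        if not (0 <= self.normal_fraction < 1):
            raise ValueError("normal_fraction must lie in [0, 1)")


@dataclass(frozen=True)
class RegionSpec:
    """One altered region: per-clone copy numbers and haplotype events.

    ``haps[j] = (a, b)`` gives the copy count of parental haplotype 1 and 2
    in tumour clone ``j``; ``a + b`` must equal ``cns[j]``.  This pair is the
    imbalance descriptor: a heterozygous-in-normal SNP whose B allele sits on
    haplotype 1 gets ``z = a`` in that clone, otherwise ``z = b``.
    """

    snp_start: int
    snp_end: int
    cns: tuple = (2,)
    haps: tuple = ((1, 1),)
    subclone_fractions: tuple = (1.0,)
    germline_loh: bool = False
    label: str = ""

    @property
    def n_clones(self) -> int:
        return len(self.cns)

    @property
    def n_snps(self) -> int:
        return self.snp_end - self.snp_start

    @property
    def cn_eff(self) -> float:
        """Subclone-fraction-weighted mean tumour copy number."""
        return float(np.dot(self.subclone_fractions, self.cns))

    @property
    def is_complex(self) -> bool:
        return self.n_clones > 1

    @property
    def loh_status(self) -> str:
        """``germline``, ``somatic`` or ``none``.

        Somatic LOH: one and the same parental haplotype has zero copies in
        every tumour clone while the normal cells are diploid-heterozygous.
        """
        if self.germline_loh:
            return "germline"
        for h in (0, 1):
            if all(hap[h] == 0 for hap in self.haps):
                return "somatic"
        return "none"

    def validate(self, cn_max: int = 5) -> list:
        """Return a list of violation strings (empty when consistent)."""
        v = []
        if self.snp_end <= self.snp_start:
            v.append(f"region {self.label or self.snp_start}: empty region "
                     f"(snp_end {self.snp_end} <= snp_start {self.snp_start})")
        if not (len(self.cns) == len(self.haps) == len(self.subclone_fractions)):
            v.append(f"region {self.label}: cns/haps/fractions length mismatch")
            return v
        for j, (cn, hap) in enumerate(zip(self.cns, self.haps)):
            if cn < 0 or cn > cn_max:
                v.append(f"region {self.label}: clone {j} copy number {cn} "
                         f"outside [0, {cn_max}]")
            if hap[0] < 0 or hap[1] < 0 or hap[0] + hap[1] != cn:
                v.append(f"region {self.label}: clone {j} haplotype counts "
                         f"{hap} incompatible with copy number {cn}")
        frac = np.asarray(self.subclone_fractions, dtype=float)
        if np.any(frac <= 0):
            v.append(f"region {self.label}: non-positive subclone fraction")
        if abs(frac.sum() - 1.0) > 1e-9:
            v.append(f"region {self.label}: fractions sum != 1 "
                     f"(got {frac.sum():g})")
        return v


@dataclass
class GenotypeMatrix:
    """Integer genotypes, SNPs x cell types; column 0 is the normal clone."""

    x: np.ndarray
    z: np.ndarray

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=np.int64)
        self.z = np.asarray(self.z, dtype=np.int64)
        if self.x.shape != self.z.shape:
            raise ValueError("x and z must have the same shape")
        if np.any(self.z < 0) or np.any(self.z > self.x):
            raise ValueError("B-allele counts must satisfy 0 <= z <= x")

    @property
    def n_snps(self) -> int:
        return self.x.shape[0]

    @property
    def n_cell_types(self) -> int:
        return self.x.shape[1]


def sample_normal_genotypes(grid: SNPGrid, seed) -> np.ndarray:
    """Draw the normal-clone B-allele counts, ``z ~ Binomial(2, pfb)``."""
    rng = _rng(seed)
    pfb = np.asarray(grid.pfb, dtype=float)
    if np.any(pfb < 0) or np.any(pfb > 1):
        raise ValueError("pfb values must lie in [0, 1]")
    return rng.binomial(2, pfb).astype(np.int64)


def enumerate_tumour_genotypes(z_normal: int, x_tumour: int) -> set:
    """Admissible tumour B-allele counts given the normal genotype.

    Homozygous normals force the same homozygous allele in the tumour; a
    heterozygous normal only bounds ``z`` by the copy number.
    """
    if z_normal not in (0, 1, 2):
        raise ValueError("z_normal must be 0, 1 or 2")
    if x_tumour < 0:
        raise ValueError("x_tumour must be >= 0")
    if z_normal == 0:
        return {0}
    if z_normal == 2:
        return {x_tumour}
    return set(range(x_tumour + 1))


def assign_region_genotypes(region: RegionSpec, pfb: np.ndarray,
                            normal_z: np.ndarray, seed) -> GenotypeMatrix:
    """Realize the genotypes of one region (normal column included).

    ``pfb`` and ``normal_z`` are the region-local slices.  Germline-LOH
    regions resample the normal genotype as a run of homozygosity,
    ``z = 2 * Bernoulli(pfb)``.  Heterozygous-in-normal SNPs read their
    per-clone ``z`` off the haplotype event through a per-SNP phase coin.
    """
    violations = region.validate(cn_max=max(max(region.cns, default=2), 5))
    if violations:
        raise RegionSpecError("; ".join(violations))
    rng = _rng(seed)
    n = region.n_snps
    pfb = np.asarray(pfb, dtype=float)
    z1 = np.asarray(normal_z, dtype=np.int64)
    if len(pfb) != n or len(z1) != n:
        raise ValueError("pfb/normal_z slices must match the region length")

    if region.germline_loh:
        z1 = 2 * rng.binomial(1, pfb).astype(np.int64)
    phase = rng.integers(0, 2, size=n)

    J = region.n_clones
    x = np.empty((n, J + 1), dtype=np.int64)
    z = np.empty((n, J + 1), dtype=np.int64)
    x[:, 0] = 2
    z[:, 0] = z1
    for j, (cn, hap) in enumerate(zip(region.cns, region.haps), start=1):
        x[:, j] = cn
        zj = np.where(phase == 0, hap[0], hap[1])
        zj = np.where(z1 == 0, 0, zj)
        zj = np.where(z1 == 2, cn, zj)
        z[:, j] = zj
    return GenotypeMatrix(x=x, z=z)


def validate_region(region: RegionSpec, population: CellPopulation) -> list:
    """Diagnostics for a region against its sample's mixture structure."""
    v = region.validate()
    if region.n_clones != population.n_cell_types - 1 and population.n_cell_types > 1:
        v.append(
            f"region {region.label}: {region.n_clones} tumour clones but "
            f"population declares {population.n_cell_types - 1}")
    return v
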