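"""Shared domain types for the linked-read NIPD workflow.

Coordinates are 0-based, half-open throughout the library; the VCF adapters
convert to 1-based on output. Alleles at heterozygous SNPs are coded 0 (ref)
and 1 (alt); because every informative SNP is heterozygous in the mother, one
haplotype carries allele ``a`` and the other ``1 - a``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

SV_KINDS = ("deletion", "duplication", "point")


@dataclass(frozen=True)
class RegionSpec:
    """Target region (e.g. the ~2.2 Mb dystrophin locus on chrX) and the
    number of informative heterozygous SNPs it contains."""

    chrom: str
    start: int
    end: int
    n_snps: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"RegionSpec: end ({self.end}) must exceed start ({self.start})")
        if self.n_snps < 2:
            raise ValueError(f"RegionSpec: n_snps must be >= 2, got {self.n_snps}")
        if self.n_snps > self.end - self.start - 1:
            raise ValueError("RegionSpec: n_snps exceeds the number of available positions")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SVMutation:
    """Pathogenic mutation carried by the mother on one haplotype.

    ``kind`` is one of ``deletion``, ``duplication`` or ``point``; for a point
    mutation the interval is a single base (``end == start + 1``).
    """

    kind: str
    start: int
    end: int
    description: str = ""

    def __post_init__(self) -> None:
        if self.kind not in SV_KINDS:
            raise ValueError(f"SVMutation: kind must be one of {SV_KINDS}, got {self.kind!r}")
        if self.end < self.start:
            raise ValueError("SVMutation: end must be >= start")
        if self.kind == "point" and self.end != self.start + 1:
            raise ValueError("SVMutation: a point mutation must satisfy end == start + 1")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SimParams:
    """Sequencing-regime parameters for the linked-read simulator.

    molecule_mean_len
        Mean length (bp) of the high-molecular-weight input molecules;
        lengths are exponential around this mean. Default 52,700 bp.
    molecules_per_gem
        Number of input molecules partitioned into one barcoded droplet
        (gem). Molecules within a gem may come from either haplotype.
    target_coverage
        Target short-read coverage (fold) over the region, summed over both
        haplotypes. Default 676.
    read_len
        Read length in bp; only used by the optional SAM export, the
        simulator emits allele observations directly.
    seq_error_rate
        Per-observation probability that the emitted allele is flipped.
    molecule_read_depth
        Per-base short-read depth along a single molecule (linked-read
        libraries sequence each molecule sparsely). Together with
        target_coverage this fixes the number of molecules simulated.
    seed
        Seed for the simulator's random generator.
    """

    molecule_mean_len: float = 52_700.0
    molecules_per_gem: int = 10
    target_coverage: float = 676.0
    read_len: int = 150
    seq_error_rate: float = 0.001
    molecule_read_depth: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.molecule_mean_len <= 0 or self.target_coverage < 0:
            raise ValueError("SimParams: molecule_mean_len and target_coverage must be positive")
        if self.molecules_per_gem < 1 or self.read_len < 1:
            raise ValueError("SimParams: molecules_per_gem and read_len must be >= 1")
        if not 0.0 <= self.seq_error_rate < 0.5:
            raise ValueError("SimParams: seq_error_rate must lie in [0, 0.5)")
        if self.molecule_read_depth <= 0:
            raise ValueError("SimParams: molecule_read_depth must be positive")


@dataclass
class MaternalDiplotype:
    """The carrier mother's two haplotypes over the target region.

    ``hap1`` holds the allele (0/1) of haplotype 1 at each SNP; haplotype 2
    is its complement because every informative SNP is heterozygous. The
    pathogenic mutation sits on haplotype ``mutation_hap`` (1 or 2).
    """

    region: RegionSpec
    positions: np.ndarray  # int64, strictly increasing
    ref: np.ndarray  # unicode bases
    alt: np.ndarray
    hap1: np.ndarray  # int8 alleles 0/1
    mutation: SVMutation
    mutation_hap: int

    def __post_init__(self) -> None:
        if self.mutation_hap not in (1, 2):
            raise ValueError("MaternalDiplotype: mutation_hap must be 1 or 2")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("MaternalDiplotype: SNP positions must be strictly increasing")
        if not (self.mutation.start >= self.region.start and self.mutation.end <= self.region.end):
            raise ValueError("MaternalDiplotype: mutation lies outside the region")

    @property
    def n_snps(self) -> int:
        return len(self.positions)

    @property
    def hap2(self) -> np.ndarray:
        return (1 - self.hap1).astype(np.int8)

    def hap(self, which: int) -> np.ndarray:
        if which == 1:
            return self.hap1
        if which == 2:
            return self.hap2
        raise ValueError("haplotype index must be 1 or 2")

    @property
    def mutant_hap_alleles(self) -> np.ndarray:
        """Allele vector of the mutation-carrying haplotype (truth HapA)."""
        return self.hap(self.mutation_hap)


@dataclass
class BarcodedReadSet:
    """Read-level allele observations at het SNPs, tagged with gem barcodes.

    Observations are stored as flat parallel arrays (one entry per sequenced
    read overlapping a SNP). ``mut_obs_*`` hold reads covering a point
    mutation site (allele 1 = mutant base). ``mol_*`` arrays are simulator
    truth used only by test oracles.
    """

    snp_positions: np.ndarray
    barcode: np.ndarray  # int64 per observation
    snp_index: np.ndarray  # int32
    allele: np.ndarray  # int8 0/1
    molecule_id: Optional[np.ndarray] = None
    # point-mutation site observations
    mut_obs_barcode: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    mut_obs_allele: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int8))
    # molecule truth (oracles only)
    mol_barcode: Optional[np.ndarray] = None
    mol_hap: Optional[np.ndarray] = None
    mol_start: Optional[np.ndarray] = None
    mol_end: Optional[np.ndarray] = None

    @property
    def n_obs(self) -> int:
        return len(self.barcode)

    @property
    def n_snps(self) -> int:
        return len(self.snp_positions)

    def subset_barcodes(self, keep: np.ndarray) -> "BarcodedReadSet":
        """Return a copy restricted to observations from ``keep`` barcodes."""
        mask = np.isin(self.barcode, keep)
        mmask = np.isin(self.mut_obs_barcode, keep)
        return BarcodedReadSet(
            snp_positions=self.snp_positions,
            barcode=self.barcode[mask],
            snp_index=self.snp_index[mask],
            allele=self.allele[mask],
            molecule_id=None if self.molecule_id is None else self.molecule_id[mask],
            mut_obs_barcode=self.mut_obs_barcode[mmask],
            mut_obs_allele=self.mut_obs_allele[mmask],
        )


@dataclass(frozen=True)
class PlasmaSpec:
    """Conditions for one maternal-plasma draw.

    fetal_fraction
        Fetal cfDNA fraction f on autosomal genome equivalents. On chrX with
        a male fetus the fetal share of reads is phi = f / (2 - f).
    transmitted_hap
        Maternal haplotype (1/2) the fetus inherited at the first SNP; it
        flips across each recombination breakpoint.
    fetal_recomb_breakpoints
        Strictly increasing SNP indices; transmission flips at each index.
    depth_per_snp
        Plasma sequencing depth at every SNP (default 200).
    """

    fetal_fraction: float
    transmitted_hap: int
    fetal_recomb_breakpoints: tuple = ()
    depth_per_snp: int = 200
    fetus_male: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.fetal_fraction < 1.0:
            raise ValueError("PlasmaSpec: fetal_fraction must lie in [0, 1)")
        if self.transmitted_hap not in (1, 2):
            raise ValueError("PlasmaSpec: transmitted_hap must be 1 or 2")
        bps = tuple(self.fetal_recomb_breakpoints)
        if any(b2 <= b1 for b1, b2 in zip(bps, bps[1:])):
            raise ValueError("PlasmaSpec: breakpoints must be strictly increasing")
        if self.depth_per_snp < 1:
            raise ValueError("PlasmaSpec: depth_per_snp must be >= 1")
        if not self.fetus_male:
            raise ValueError("PlasmaSpec: only male fetuses are modeled")

    @property
    def chrx_fetal_share(self) -> float:
        """phi = f/(2-f): fetal share of chrX reads for a male fetus."""
        f = self.fetal_fraction
        return f / (2.0 - f)


@dataclass
class PlasmaCounts:
    """Per-SNP plasma allelic depths (ref/alt), ordered by position."""

    positions: np.ndarray
    ref_depth: np.ndarray
    alt_depth: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("PlasmaCounts: positions must be strictly increasing")
        if np.any(self.ref_depth < 0) or np.any(self.alt_depth < 0):
            raise ValueError("PlasmaCounts: depths must be non-negative")

    @property
    def depth(self) -> np.ndarray:
        return self.ref_depth + self.alt_depth

    @property
    def n_snps(self) -> int:
        return len(self.positions)


@dataclass
class FamilyDataset:
    """One simulated family: maternal diplotype + linked reads + plasma draws
    + a truth record sufficient for scoring."""

    name: str
    diplotype: MaternalDiplotype
    reads: BarcodedReadSet
    plasma: list
    truth: dict
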