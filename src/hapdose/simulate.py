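"""Synthetic linked-read and plasma-cfDNA generator.

Emulates the study regime the downstream analysis assumes: a carrier mother
heterozygous for a dystrophin mutation on a ~2.2 Mb chrX target, high
molecular weight molecules (exponential lengths, mean 52.7 kb) partitioned
into barcoded gems, ~676x targeted coverage, and male-fetus plasma mixtures
at low fetal fractions sequenced ~200x per SNP.

Structural mutations are simulated geometrically: the mutant haplotype's
coordinate space excises a deletion (so molecules genuinely span the gap)
or tandem-duplicates a duplication (so interior SNPs on that haplotype are
observed at doubled rate).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .model import (
    BarcodedReadSet,
    FamilyDataset,
    MaternalDiplotype,
    PlasmaCounts,
    PlasmaSpec,
    RegionSpec,
    SimParams,
    SVMutation,
)

__all__ = [
    "DMD_REGION",
    "DrawSpec",
    "FamilyConfig",
    "simulate_diplotype",
    "simulate_linked_reads",
    "simulate_plasma",
    "simulate_family",
]

#: Default target: a dystrophin-like 2.2 Mb region on chrX with 850
#: informative het SNPs (midpoint of the 700-1000 range).
DMD_REGION = RegionSpec("chrX", 31_100_000, 33_300_000, 850)

_BASES = np.array(list("ACGT"))


def simulate_diplotype(region: RegionSpec, mutation: SVMutation, seed: int) -> MaternalDiplotype:
    """Draw a heterozygous maternal diplotype over ``region``.

    SNP positions are uniform-random distinct sites strictly inside the
    region; haplotype-1 alleles are fair coin flips per SNP; the mutation is
    placed on haplotype 1 or 2 by a seeded coin. Deterministic per seed.
    """
    if not (mutation.start >= region.start and mutation.end <= region.end):
        raise ValueError("simulate_diplotype: mutation lies outside the region")
    rng = np.random.default_rng(seed)
    positions = rng.choice(
        np.arange(region.start + 1, region.end, dtype=np.int64), size=region.n_snps, replace=False
    )
    positions.sort()
    ref_idx = rng.integers(0, 4, size=region.n_snps)
    alt_idx = (ref_idx + rng.integers(1, 4, size=region.n_snps)) % 4
    hap1 = rng.integers(0, 2, size=region.n_snps).astype(np.int8)
    mutation_hap = int(rng.integers(1, 3))
    return MaternalDiplotype(
        region=region,
        positions=positions,
        ref=_BASES[ref_idx],
        alt=_BASES[alt_idx],
        hap1=hap1,
        mutation=mutation,
        mutation_hap=mutation_hap,
    )


def _hap_space(diplo: MaternalDiplotype, hap: int):
    """SNP layout of one haplotype in its own coordinate space.

    Returns (snp_pos, snp_idx, space_start, space_end). A deletion on this
    haplotype removes interior SNPs and shifts downstream coordinates left; a
    tandem duplication lists interior SNPs twice (one entry per copy) and
    shifts downstream coordinates right.
    """
    mut = diplo.mutation
    pos = diplo.positions
    region = diplo.region
    if hap != diplo.mutation_hap or mut.kind == "point":
        return pos.copy(), np.arange(len(pos), dtype=np.int32), region.start, region.end
    L = mut.length
    idx = np.arange(len(pos), dtype=np.int32)
    upstream = pos < mut.start
    interior = (pos >= mut.start) & (pos < mut.end)
    downstream = pos >= mut.end
    if mut.kind == "deletion":
        snp_pos = np.concatenate([pos[upstream], pos[downstream] - L])
        snp_idx = np.concatenate([idx[upstream], idx[downstream]])
        return snp_pos, snp_idx, region.start, region.end - L
    # tandem duplication: [start, end) followed by an identical copy
    snp_pos = np.concatenate([pos[upstream], pos[interior], pos[interior] + L, pos[downstream] + L])
    snp_idx = np.concatenate([idx[upstream], idx[interior], idx[interior], idx[downstream]])
    return snp_pos, snp_idx, region.start, region.end + L


def _expand_ranges(lo: np.ndarray, hi: np.ndarray):
    """Vectorized ragged expansion: for each i emit lo[i]..hi[i]-1.

    Returns (owner_index, value) arrays.
    """
    counts = hi - lo
    total = int(counts.sum())
    if total == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    owner = np.repeat(np.arange(len(lo), dtype=np.int64), counts)
    offsets = np.arange(total, dtype=np.int64) - np.repeat(np.cumsum(counts) - counts, counts)
    return owner, np.repeat(lo, counts) + offsets


def simulate_linked_reads(
    diplotype: MaternalDiplotype, params: SimParams, seed: int | None = None
) -> BarcodedReadSet:
    """Simulate barcoded allele observations at het SNPs.

    Molecules are drawn per haplotype with exponential lengths (mean
    ``molecule_mean_len``), placed uniformly over the haplotype's own
    coordinate space, and sequenced sparsely: at each covered SNP the number
    of read observations is Poisson(``molecule_read_depth``), carrying the
    molecule's haplotype allele flipped with probability ``seq_error_rate``.
    Molecules are then shuffled into gems of ``molecules_per_gem`` (gems may
    mix haplotypes). A point mutation additionally emits mutant/wild-type
    observations at its own site.
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    region = diplotype.region
    mean_len = params.molecule_mean_len
    depth = params.molecule_read_depth

    all_snp = []  # per-observation snp index
    all_allele = []
    all_mol = []
    mol_hap_l, mol_start_l, mol_end_l = [], [], []
    mut_mol, mut_allele = [], []
    n_mol_total = 0

    for hap in (1, 2):
        snp_pos, snp_idx, hs, he = _hap_space(diplotype, hap)
        hap_len = he - hs
        n_mol = int(round(params.target_coverage * hap_len / (2.0 * mean_len * depth)))
        if n_mol == 0:
            continue
        hap_alleles = diplotype.hap(hap)
        lengths = rng.exponential(mean_len, n_mol)
        starts = hs - lengths + rng.random(n_mol) * (hap_len + lengths)
        ends = starts + lengths
        lo = np.searchsorted(snp_pos, starts)
        hi = np.searchsorted(snp_pos, ends)
        mol_of_pair, cover_idx = _expand_ranges(lo, hi)
        k = rng.poisson(depth, size=len(cover_idx))
        keep = k > 0
        mol_of_obs = np.repeat(mol_of_pair[keep], k[keep])
        snp_of_obs = np.repeat(snp_idx[cover_idx[keep]], k[keep])
        allele = hap_alleles[snp_of_obs].astype(np.int8)
        if params.seq_error_rate > 0:
            flip = rng.random(len(allele)) < params.seq_error_rate
            allele = np.where(flip, 1 - allele, allele).astype(np.int8)
        all_snp.append(snp_of_obs.astype(np.int32))
        all_allele.append(allele)
        all_mol.append(mol_of_obs + n_mol_total)

        # point-mutation site reads
        mut = diplotype.mutation
        if mut.kind == "point":
            covers = (starts <= mut.start) & (ends > mut.start)
            km = rng.poisson(depth, size=int(covers.sum()))
            mols = np.flatnonzero(covers)
            m_of_obs = np.repeat(mols, km) + n_mol_total
            a = np.full(len(m_of_obs), 1 if hap == diplotype.mutation_hap else 0, dtype=np.int8)
            if params.seq_error_rate > 0:
                flip = rng.random(len(a)) < params.seq_error_rate
                a = np.where(flip, 1 - a, a).astype(np.int8)
            mut_mol.append(m_of_obs)
            mut_allele.append(a)

        mol_hap_l.append(np.full(n_mol, hap, dtype=np.int8))
        mol_start_l.append(starts)
        mol_end_l.append(ends)
        n_mol_total += n_mol

    if n_mol_total == 0 or sum(len(s) for s in all_snp) == 0:
        warnings.warn("simulate_linked_reads: zero coverage, returning an empty read set")
        return BarcodedReadSet(
            snp_positions=diplotype.positions,
            barcode=np.empty(0, dtype=np.int64),
            snp_index=np.empty(0, dtype=np.int32),
            allele=np.empty(0, dtype=np.int8),
        )

    # shuffle molecules into gems; gems may mix haplotypes
    perm = rng.permutation(n_mol_total)
    gem_of_mol = np.empty(n_mol_total, dtype=np.int64)
    gem_of_mol[perm] = np.arange(n_mol_total, dtype=np.int64) // params.molecules_per_gem

    mol = np.concatenate(all_mol)
    snp = np.concatenate(all_snp)
    allele = np.concatenate(all_allele)
    order = np.argsort(mol, kind="stable")
    mm = np.concatenate(mut_mol) if mut_mol else np.empty(0, dtype=np.int64)
    ma = np.concatenate(mut_allele) if mut_allele else np.empty(0, dtype=np.int8)
    return BarcodedReadSet(
        snp_positions=diplotype.positions,
        barcode=gem_of_mol[mol[order]],
        snp_index=snp[order],
        allele=allele[order],
        molecule_id=mol[order],
        mut_obs_barcode=gem_of_mol[mm],
        mut_obs_allele=ma,
        mol_barcode=gem_of_mol,
        mol_hap=np.concatenate(mol_hap_l),
        mol_start=np.concatenate(mol_start_l),
        mol_end=np.concatenate(mol_end_l),
    )


def fetal_alleles(diplotype: MaternalDiplotype, spec: PlasmaSpec) -> np.ndarray:
    """Allele (0/1) the fetus carries at each SNP: the transmitted haplotype,
    flipped across each recombination breakpoint."""
    n = diplotype.n_snps
    for b in spec.fetal_recomb_breakpoints:
        if not 0 < b < n:
            raise ValueError(f"simulate_plasma: breakpoint index {b} out of range (0, {n})")
    flips = np.zeros(n, dtype=np.int64)
    for b in spec.fetal_recomb_breakpoints:
        flips[b:] += 1
    hap_t = diplotype.hap(spec.transmitted_hap)
    return np.where(flips % 2 == 0, hap_t, 1 - hap_t).astype(np.int8)


def simulate_plasma(diplotype: MaternalDiplotype, spec: PlasmaSpec, seed: int) -> PlasmaCounts:
    """Draw per-SNP plasma allelic depths.

    The fetal share of chrX reads is phi = f/(2-f) (mother contributes two X
    copies per genome equivalent, the male fetus one). The expected fraction
    of the haplotype-1 allele at SNP i is (1-phi)/2 + phi*[fetal allele ==
    hap1 allele]; depths are Binomial(depth_per_snp, p_i).
    """
    rng = np.random.default_rng(seed)
    fa = fetal_alleles(diplotype, spec)
    phi = spec.chrx_fetal_share
    p_hap1 = (1.0 - phi) / 2.0 + phi * (fa == diplotype.hap1)
    a = rng.binomial(spec.depth_per_snp, p_hap1)
    b = spec.depth_per_snp - a
    # map hap1-allele counts onto ref/alt labels
    alt_depth = np.where(diplotype.hap1 == 1, a, b).astype(np.int64)
    ref_depth = np.where(diplotype.hap1 == 1, b, a).astype(np.int64)
    return PlasmaCounts(
        positions=diplotype.positions.copy(), ref_depth=ref_depth, alt_depth=alt_depth
    )


@dataclass(frozen=True)
class DrawSpec:
    """One plasma draw of a family: fetal fraction plus an optional label."""

    fetal_fraction: float
    label: str = ""


@dataclass(frozen=True)
class FamilyConfig:
    """Study-condition description of one carrier family.

    ``transmitted`` states which maternal haplotype the fetus inherited *at
    the mutation locus* ("mutant" or "wildtype"); with recombination the
    transmitted haplotype differs elsewhere. ``recomb_breakpoints`` are SNP
    indices at which fetal transmission flips (a property of the fetus, so
    shared by all draws).
    """

    name: str
    mutation: SVMutation
    transmitted: str
    draws: tuple
    recomb_breakpoints: tuple = ()
    region: RegionSpec = DMD_REGION
    depth_per_snp: int = 200

    def __post_init__(self) -> None:
        if self.transmitted not in ("mutant", "wildtype"):
            raise ValueError(
                f"FamilyConfig({self.name}): transmitted must be 'mutant' or 'wildtype', "
                f"got {self.transmitted!r}"
            )
        if not self.draws:
            pass  # zero plasma draws is legal: diplotype + reads only
        for d in self.draws:
            if not isinstance(d, DrawSpec):
                raise ValueError(f"FamilyConfig({self.name}): draws must be DrawSpec instances")
        try:
            RegionSpec(self.region.chrom, self.region.start, self.region.end, self.region.n_snps)
        except ValueError as exc:
            raise ValueError(f"FamilyConfig({self.name}): region invalid: {exc}") from exc
        if not (self.mutation.start >= self.region.start and self.mutation.end <= self.region.end):
            raise ValueError(f"FamilyConfig({self.name}): mutation outside region")


def _transmitted_hap_at_first_snp(
    diplo: MaternalDiplotype, cfg: FamilyConfig
) -> int:
    """Convert mutation-locus transmission into the haplotype at SNP 0,
    accounting for breakpoints left of the mutation."""
    hap_at_mut = (
        diplo.mutation_hap if cfg.transmitted == "mutant" else 3 - diplo.mutation_hap
    )
    mut_mid = (cfg.mutation.start + cfg.mutation.end) // 2
    n_flips_before = sum(
        1 for b in cfg.recomb_breakpoints if diplo.positions[b] <= mut_mid
    )
    return hap_at_mut if n_flips_before % 2 == 0 else 3 - hap_at_mut


def simulate_family(
    config: FamilyConfig, params: SimParams, seed: int
) -> FamilyDataset:
    """Simulate a complete family dataset: diplotype, linked reads, one
    PlasmaCounts per draw, and a truth record for scoring. Deterministic
    under ``seed``."""
    rng = np.random.default_rng(seed)
    sub = rng.integers(0, 2**31 - 1, size=2 + max(len(config.draws), 1))
    diplo = simulate_diplotype(config.region, config.mutation, int(sub[0]))
    reads = simulate_linked_reads(diplo, params, seed=int(sub[1]))
    t_hap0 = _transmitted_hap_at_first_snp(diplo, config)
    plasma = []
    for i, d in enumerate(config.draws):
        spec = PlasmaSpec(
            fetal_fraction=d.fetal_fraction,
            transmitted_hap=t_hap0,
            fetal_recomb_breakpoints=tuple(config.recomb_breakpoints),
            depth_per_snp=config.depth_per_snp,
        )
        plasma.append(simulate_plasma(diplo, spec, int(sub[2 + i])))
    truth = {
        "family": config.name,
        "mutation_kind": config.mutation.kind,
        "mutation_hap": diplo.mutation_hap,
        "transmitted": config.transmitted,
        "transmitted_hap_at_first_snp": t_hap0,
        "recomb_breakpoints": list(config.recomb_breakpoints),
        "has_recombination": bool(config.recomb_breakpoints),
        "fetal_fractions": [d.fetal_fraction for d in config.draws],
        "draw_labels": [d.label for d in config.draws],
        "expected_call": (
            "mutant_inherited" if config.transmitted == "mutant" else "wildtype_inherited"
        ),
        "seed": seed,
    }
    return FamilyDataset(name=config.name, diplotype=diplo, reads=reads, plasma=plasma, truth=truth)
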