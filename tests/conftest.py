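"""Shared fixtures: toy observation builders and scaled simulation regimes."""

from __future__ import annotations

import numpy as np
import pytest

from hapdose.model import BarcodedReadSet, RegionSpec, SimParams, SVMutation
from hapdose.simulate import simulate_diplotype, simulate_linked_reads


def make_reads(obs, n_snps, positions=None, mut_obs=()):
    """Build a BarcodedReadSet from a list of (barcode, snp_index, allele)
    observation tuples; ``mut_obs`` is a list of (barcode, allele) at a
    point-mutation site."""
    obs = list(obs)
    if positions is None:
        positions = 1000 * (1 + np.arange(n_snps, dtype=np.int64))
    b = np.asarray([o[0] for o in obs], dtype=np.int64)
    s = np.asarray([o[1] for o in obs], dtype=np.int32)
    a = np.asarray([o[2] for o in obs], dtype=np.int8)
    mb = np.asarray([m[0] for m in mut_obs], dtype=np.int64)
    ma = np.asarray([m[1] for m in mut_obs], dtype=np.int8)
    return BarcodedReadSet(
        snp_positions=np.asarray(positions, dtype=np.int64),
        barcode=b,
        snp_index=s,
        allele=a,
        mut_obs_barcode=mb,
        mut_obs_allele=ma,
    )


SMALL_REGION = RegionSpec("chrX", 1_000_000, 1_500_000, 120)
SMALL_DELETION = SVMutation("deletion", 1_200_000, 1_280_000, "toy deletion")
SMALL_DUPLICATION = SVMutation("duplication", 1_200_000, 1_280_000, "toy duplication")
SMALL_POINT = SVMutation("point", 1_250_000, 1_250_001, "toy point")


def small_params(error=0.0, coverage=120.0, seed=0, gems=10):
    return SimParams(
        target_coverage=coverage,
        seq_error_rate=error,
        molecules_per_gem=gems,
        seed=seed,
    )


@pytest.fixture(scope="session")
def small_point_sample():
    """Error-free small maternal sample with a point mutation."""
    diplo = simulate_diplotype(SMALL_REGION, SMALL_POINT, seed=11)
    reads = simulate_linked_reads(diplo, small_params(seed=12))
    return diplo, reads
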