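"""Phasing: barcode matrix, phase graph, block calling, anchoring, metrics."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hapdose.model import SVMutation
from hapdose.phasing import (
    PhaseGraph,
    anchor_hapA,
    build_barcode_matrix,
    build_phase_graph,
    call_phase_blocks,
    n50_phase_block,
    pair_from_truth,
    phasing_concordance,
)
from hapdose.simulate import simulate_diplotype, simulate_linked_reads

from conftest import SMALL_POINT, SMALL_REGION, make_reads, small_params


class TestBarcodeMatrix:
    def test_counts_aggregate(self):
        reads = make_reads([(1, 1, 1), (1, 1, 1), (1, 2, 0)], n_snps=4)
        m = build_barcode_matrix(reads)
        assert m.as_dict() == {1: {1: (0, 2), 2: (1, 0)}}

    def test_single_snp_barcode_dropped(self):
        reads = make_reads([(1, 3, 1), (2, 0, 0), (2, 1, 1)], n_snps=4)
        m = build_barcode_matrix(reads)
        assert set(m.as_dict()) == {2}

    def test_hand_tally_three_barcodes(self):
        obs = [
            (1, 0, 0), (1, 1, 0), (1, 2, 1),
            (2, 0, 1), (2, 1, 1), (2, 1, 1),
            (3, 0, 0), (3, 2, 1), (3, 2, 0),
        ]
        m = build_barcode_matrix(make_reads(obs, n_snps=3))
        assert m.as_dict() == {
            1: {0: (1, 0), 1: (1, 0), 2: (0, 1)},
            2: {0: (0, 1), 1: (0, 2)},
            3: {0: (1, 0), 2: (1, 1)},
        }


def _edges_dict(g: PhaseGraph):
    return {
        (int(i), int(j)): (int(c), int(t))
        for i, j, c, t in zip(g.edge_i, g.edge_j, g.cis, g.trans)
    }


class TestPhaseGraph:
    def test_cis_support(self):
        m = build_barcode_matrix(make_reads([(1, 1, 1), (1, 2, 1)], n_snps=3))
        assert _edges_dict(build_phase_graph(m)) == {(1, 2): (1, 0)}

    def test_trans_support_accumulates(self):
        obs = [(1, 1, 1), (1, 2, 0), (2, 1, 0), (2, 2, 1)]
        m = build_barcode_matrix(make_reads(obs, n_snps=3))
        assert _edges_dict(build_phase_graph(m)) == {(1, 2): (0, 2)}

    def test_tie_contributes_no_pairs(self):
        obs = [(1, 1, 1), (1, 1, 0), (1, 2, 1), (1, 3, 1)]
        m = build_barcode_matrix(make_reads(obs, n_snps=4))
        assert _edges_dict(build_phase_graph(m)) == {(2, 3): (1, 0)}

    def test_distance_window_filters_pairs(self):
        obs = [(1, 0, 1), (1, 1, 1), (1, 2, 1)]
        positions = np.array([1_000, 2_000, 500_000])
        m = build_barcode_matrix(make_reads(obs, n_snps=3, positions=positions))
        g = build_phase_graph(m, max_pair_bp=10_000)
        assert set(_edges_dict(g)) == {(0, 1)}


class TestPhaseBlocks:
    def test_all_cis_chain_single_block(self):
        g = PhaseGraph.from_edge_list(4, [(0, 1, 5, 0), (1, 2, 5, 0), (2, 3, 5, 0)])
        blocks = call_phase_blocks(g, min_support=2, min_ratio=0.75)
        assert len(blocks) == 1
        b = blocks[0]
        assert np.array_equal(b.snps, [0, 1, 2, 3])
        assert len(set(b.strand0_allele.tolist())) == 1  # all same strand

    def test_trans_edge_flips_strand(self):
        g = PhaseGraph.from_edge_list(3, [(0, 1, 5, 0), (1, 2, 0, 5)])
        (b,) = call_phase_blocks(g)
        s = {int(i): int(a) for i, a in zip(b.snps, b.strand0_allele)}
        assert s[0] == s[1] and s[2] == 1 - s[1]

    def test_two_components_two_blocks(self):
        g = PhaseGraph.from_edge_list(6, [(1, 2, 5, 0), (4, 5, 0, 5)])
        blocks = call_phase_blocks(g)
        assert [b.snps.tolist() for b in blocks] == [[1, 2], [4, 5]]

    def test_noisy_edge_dropped_splits_block(self):
        """An edge at ratio 0.56 < 0.75 is removed; remaining topology
        dictates the split."""
        edges = [(0, 1, 5, 0), (1, 2, 5, 0), (2, 3, 5, 4), (3, 4, 5, 0), (4, 5, 5, 0)]
        blocks = call_phase_blocks(PhaseGraph.from_edge_list(6, edges))
        assert [b.snps.tolist() for b in blocks] == [[0, 1, 2], [3, 4, 5]]

    def test_min_support_threshold(self):
        g = PhaseGraph.from_edge_list(3, [(0, 1, 1, 0), (1, 2, 5, 0)])
        blocks = call_phase_blocks(g, min_support=2)
        assert [b.snps.tolist() for b in blocks] == [[1, 2]]

    def test_conflicting_nontree_edge_counted(self):
        # triangle: 0-1 cis, 1-2 cis, 0-2 trans (conflict)
        g = PhaseGraph.from_edge_list(3, [(0, 1, 9, 0), (1, 2, 8, 0), (0, 2, 0, 7)])
        (b,) = call_phase_blocks(g, min_support=2, min_ratio=0.75)
        assert b.conflicts == 1 and b.n_nontree_edges == 1
        assert b.low_confidence

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_monotonicity_min_support_only_splits(self, seed):
        """Raising min_support never merges blocks."""
        rng = np.random.default_rng(seed)
        n = 8
        edges = []
        for i, j in itertools.combinations(range(n), 2):
            if rng.random() < 0.4:
                c, t = int(rng.integers(0, 6)), int(rng.integers(0, 6))
                if c or t:
                    edges.append((i, j, c, t))
        g = PhaseGraph.from_edge_list(n, edges)
        lo = call_phase_blocks(g, min_support=1, min_ratio=0.75)
        hi = call_phase_blocks(g, min_support=3, min_ratio=0.75)
        comp_lo = {int(s): k for k, b in enumerate(lo) for s in b.snps}
        for b in hi:
            owners = {comp_lo[int(s)] for s in b.snps}
            assert len(owners) == 1  # every high-threshold block nests in one low-threshold block


def _exhaustive_best_score(matrix, n_snps):
    """Maximum-agreement phasing by enumeration: assignment s in {0,1}^n of
    the strand-0 allele; each barcode scores its best strand."""
    d = matrix.as_dict()
    best = -1
    for bits in itertools.product((0, 1), repeat=n_snps - 1):
        s = np.array((1,) + bits, dtype=np.int8)
        score = 0
        for calls in d.values():
            maj = {snp: (1 if a > r else 0) for snp, (r, a) in calls.items() if a != r}
            agree = sum(1 for snp, m in maj.items() if m == s[snp])
            score += max(agree, len(maj) - agree)
        best = max(best, score)
    return best


def _score_assignment(matrix, s):
    d = matrix.as_dict()
    score = 0
    for calls in d.values():
        maj = {snp: (1 if a > r else 0) for snp, (r, a) in calls.items() if a != r}
        agree = sum(1 for snp, m in maj.items() if m == s[snp])
        score += max(agree, len(maj) - agree)
    return score


class TestOracleEquivalence:
    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_matches_exhaustive_maximum_agreement(self, seed):
        """On <=8-SNP instances the called phasing achieves the exhaustive
        maximum-agreement score."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        truth = rng.integers(0, 2, n).astype(np.int8)
        obs = []
        for bc in range(12):
            start = int(rng.integers(0, n - 1))
            length = int(rng.integers(2, n - start + 1))
            hap = int(rng.integers(0, 2))
            for s in range(start, start + length):
                a = truth[s] if hap == 0 else 1 - truth[s]
                if rng.random() < 0.05:  # sparse noise
                    a = 1 - a
                obs.append((bc, s, int(a)))
        matrix = build_barcode_matrix(make_reads(obs, n_snps=n))
        if matrix.n_rows == 0:
            return
        blocks = call_phase_blocks(
            build_phase_graph(matrix), min_support=1, min_ratio=0.51, matrix=matrix
        )
        if len(blocks) != 1 or blocks[0].n_snps != n:
            return  # oracle comparison defined for fully connected instances
        s = np.zeros(n, dtype=np.int8)
        s[blocks[0].snps] = blocks[0].strand0_allele
        assert _score_assignment(matrix, s) == _exhaustive_best_score(matrix, n)


class TestAnchoring:
    def _toy(self):
        # truth: strand X carries alt everywhere; 3 barcodes per haplotype
        obs = []
        for bc in (0, 1, 2):
            obs += [(bc, s, 1) for s in range(5)]
        for bc in (3, 4, 5):
            obs += [(bc, s, 0) for s in range(5)]
        mut_obs = [(0, 1), (1, 1), (3, 0)]
        reads = make_reads(obs, n_snps=5, mut_obs=mut_obs)
        matrix = build_barcode_matrix(reads)
        blocks = call_phase_blocks(build_phase_graph(matrix))
        return reads, matrix, blocks

    def test_point_mutation_anchors_hapA(self):
        reads, matrix, blocks = self._toy()
        mutation = SVMutation("point", 3000, 3001)
        pair = anchor_hapA(blocks, mutation, matrix, reads)
        assert np.all(pair.hapA == 1)  # mutant barcodes carried alt everywhere
        assert np.all(pair.hapA != pair.hapB)
        assert pair.anchor_evidence == 2

    def test_allele_flip_swaps_hapA_and_hapB(self):
        reads, matrix, blocks = self._toy()
        mutation = SVMutation("point", 3000, 3001)
        pair = anchor_hapA(blocks, mutation, matrix, reads)
        flipped = make_reads(
            [(int(b), int(s), int(1 - a)) for b, s, a in zip(reads.barcode, reads.snp_index, reads.allele)],
            n_snps=5,
            mut_obs=list(zip(reads.mut_obs_barcode.tolist(), reads.mut_obs_allele.tolist())),
        )
        fm = build_barcode_matrix(flipped)
        fb = call_phase_blocks(build_phase_graph(fm))
        fpair = anchor_hapA(fb, mutation, fm, flipped)
        assert np.array_equal(fpair.hapA, pair.hapB)

    def test_barcode_relabeling_invariant(self):
        reads, matrix, blocks = self._toy()
        mutation = SVMutation("point", 3000, 3001)
        pair = anchor_hapA(blocks, mutation, matrix, reads)
        perm = {0: 10, 1: 21, 2: 32, 3: 43, 4: 54, 5: 65}
        relab = make_reads(
            [(perm[int(b)], int(s), int(a)) for b, s, a in zip(reads.barcode, reads.snp_index, reads.allele)],
            n_snps=5,
            mut_obs=[(perm[int(b)], int(a)) for b, a in zip(reads.mut_obs_barcode, reads.mut_obs_allele)],
        )
        rm = build_barcode_matrix(relab)
        rb = call_phase_blocks(build_phase_graph(rm))
        rpair = anchor_hapA(rb, mutation, rm, relab)
        assert np.array_equal(rpair.hapA, pair.hapA)

    def test_transitive_anchoring_through_shared_barcodes(self):
        """A block with no direct mutation evidence is anchored through
        barcodes shared with an anchored block."""
        obs = []
        for bc in (0, 1, 2):  # block 1: SNPs 0-2, alt strand
            obs += [(bc, s, 1) for s in range(3)]
        for bc in (3, 4, 5):
            obs += [(bc, s, 0) for s in range(3)]
        for bc in (6, 7, 8):  # block 2: SNPs 4-6, ref strand carries the same haplotype
            obs += [(bc, s, 0) for s in range(4, 7)]
        for bc in (9, 10, 11):
            obs += [(bc, s, 1) for s in range(4, 7)]
        # three bridge barcodes on distinct SNP pairs: each edge support 1 < min_support
        for bc, (s1, s2) in ((20, (2, 4)), (21, (1, 5)), (22, (0, 6))):
            obs += [(bc, s1, 1), (bc, s2, 0)]
        reads = make_reads(obs, n_snps=7, mut_obs=[(0, 1), (1, 1)])
        matrix = build_barcode_matrix(reads)
        blocks = call_phase_blocks(build_phase_graph(matrix), min_support=2)
        assert len(blocks) == 2
        pair = anchor_hapA(blocks, SVMutation("point", 1500, 1501), matrix, reads)
        assert pair.n_phased == 6
        full = pair.hapA_full()
        assert np.all(full[[0, 1, 2]] == 1)
        assert np.all(full[[4, 5, 6]] == 0)  # same haplotype, carried by ref alleles there

    def test_no_mutation_evidence_errors(self):
        reads, matrix, blocks = self._toy()
        bare = make_reads(
            [(int(b), int(s), int(a)) for b, s, a in zip(reads.barcode, reads.snp_index, reads.allele)],
            n_snps=5,
        )
        with pytest.raises(ValueError, match="not linkable"):
            anchor_hapA(blocks, SVMutation("point", 3000, 3001), build_barcode_matrix(bare), bare)


class TestMetrics:
    def test_n50_sorted_cumulative(self):
        class B:
            def __init__(self, s):
                self.span_bp = s

        assert n50_phase_block([B(10_000), B(20_000), B(30_000), B(40_000)]) == 30_000
        assert n50_phase_block([B(42_700)]) == 42_700
        assert n50_phase_block([B(5_000)] * 7) == 5_000
        with pytest.raises(ValueError):
            n50_phase_block([])

    def test_concordance_cases(self):
        diplo = simulate_diplotype(SMALL_REGION, SMALL_POINT, seed=1)
        pair = pair_from_truth(diplo)
        truth = diplo.mutant_hap_alleles
        r = phasing_concordance(pair, truth)
        assert r.concordance == 1.0 and r.switch_errors == 0
        r = phasing_concordance(pair, 1 - truth)
        assert r.concordance == 0.0 and r.switch_errors == 0

    def test_concordance_single_switch(self):
        diplo = simulate_diplotype(SMALL_REGION, SMALL_POINT, seed=1)
        pair = pair_from_truth(diplo)
        truth = diplo.mutant_hap_alleles.copy()
        n = len(truth)
        truth[n // 2:] = 1 - truth[n // 2:]
        r = phasing_concordance(pair, truth)
        assert r.concordance == pytest.approx(0.5)
        assert r.switch_errors == 1


class TestEndToEndRecovery:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_error_free_phasing_recovers_truth(self, seed):
        """Error-free, fully connected input: recovered haplotypes equal
        truth exactly (up to the HapA/HapB labeling fixed by the anchor)."""
        diplo = simulate_diplotype(SMALL_REGION, SMALL_POINT, seed=seed)
        reads = simulate_linked_reads(diplo, small_params(seed=seed + 100))
        matrix = build_barcode_matrix(reads)
        blocks = call_phase_blocks(build_phase_graph(matrix, max_pair_bp=210_000), matrix=matrix)
        pair = anchor_hapA(blocks, SMALL_POINT, matrix, reads, vote_window_bp=80_000)
        r = phasing_concordance(pair, diplo.mutant_hap_alleles)
        assert pair.n_phased == diplo.n_snps
        assert r.concordance == 1.0
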