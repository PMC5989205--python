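"""Barcode-based maternal haplotype phasing.

Reads sharing a gem barcode come from the same long input molecules, so
co-barcoded allele observations at pairs of het SNPs carry phase signal:
equal alleles (ref/ref or alt/alt majorities) support the *cis* pairing,
opposite alleles the *trans* pairing. Filtered pairwise support is assembled
into phase blocks; the block strand sharing barcodes with the
mutation-supporting reads is designated HapA (mutant-linked), its
complement HapB (wild-type linked).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np

from .model import BarcodedReadSet, SVMutation

__all__ = [
    "BarcodeMatrix",
    "PhaseGraph",
    "PhaseBlock",
    "HaplotypePair",
    "ConcordanceResult",
    "build_barcode_matrix",
    "build_phase_graph",
    "call_phase_blocks",
    "anchor_hapA",
    "pair_from_truth",
    "n50_phase_block",
    "phasing_concordance",
]


class BarcodeMatrix:
    """Per-barcode allele counts at het SNPs, as flat sorted arrays.

    Rows are unique (barcode, snp) pairs sorted lexicographically, each with
    ref/alt observation counts. Barcodes observing fewer than two distinct
    SNPs are dropped at construction (uninformative for linking).
    """

    def __init__(self, barcode, snp, ref_count, alt_count, positions, n_snps):
        self.barcode = barcode
        self.snp = snp
        self.ref_count = ref_count
        self.alt_count = alt_count
        self.positions = positions
        self.n_snps = n_snps
        self._majority = None

    @classmethod
    def from_reads(cls, reads: BarcodedReadSet, min_snps_per_barcode: int = 2) -> "BarcodeMatrix":
        n_snps = reads.n_snps
        if reads.n_obs == 0:
            empty = np.empty(0, dtype=np.int64)
            return cls(empty, empty.astype(np.int32), empty, empty, reads.snp_positions, n_snps)
        keys = reads.barcode.astype(np.int64) * n_snps + reads.snp_index
        ukeys, inverse = np.unique(keys, return_inverse=True)
        alt = np.bincount(inverse, weights=reads.allele).astype(np.int64)
        tot = np.bincount(inverse).astype(np.int64)
        barcode = ukeys // n_snps
        snp = (ukeys % n_snps).astype(np.int32)
        # drop barcodes seeing < min_snps_per_barcode distinct SNPs
        ub, counts = np.unique(barcode, return_counts=True)
        bad = ub[counts < min_snps_per_barcode]
        if len(bad):
            keep = ~np.isin(barcode, bad)
            barcode, snp, alt, tot = barcode[keep], snp[keep], alt[keep], tot[keep]
        return cls(barcode, snp, tot - alt, alt, reads.snp_positions, n_snps)

    @property
    def n_rows(self) -> int:
        return len(self.barcode)

    def majority(self):
        """(barcode, snp, majority_allele) rows; per-barcode ties dropped."""
        if self._majority is None:
            keep = self.ref_count != self.alt_count
            maj = (self.alt_count > self.ref_count).astype(np.int8)
            self._majority = (self.barcode[keep], self.snp[keep], maj[keep])
        return self._majority

    def as_dict(self) -> dict:
        """Nested {barcode: {snp: (ref_count, alt_count)}} view (small data)."""
        out: dict = {}
        for b, s, r, a in zip(self.barcode, self.snp, self.ref_count, self.alt_count):
            out.setdefault(int(b), {})[int(s)] = (int(r), int(a))
        return out


def build_barcode_matrix(reads: BarcodedReadSet, min_snps_per_barcode: int = 2) -> BarcodeMatrix:
    """Aggregate observations into per-barcode allele counts."""
    return BarcodeMatrix.from_reads(reads, min_snps_per_barcode=min_snps_per_barcode)


@dataclass
class PhaseGraph:
    """Pairwise phase evidence between SNPs.

    Edge (i, j) with i < j carries ``cis`` support (barcodes whose majority
    alleles at i and j are equal) and ``trans`` support (opposite alleles).
    """

    n_snps: int
    positions: np.ndarray
    edge_i: np.ndarray
    edge_j: np.ndarray
    cis: np.ndarray
    trans: np.ndarray

    @property
    def n_edges(self) -> int:
        return len(self.edge_i)

    @classmethod
    def from_edge_list(cls, n_snps, edges, positions=None):
        """Build from [(i, j, cis, trans), ...] (test/toy convenience)."""
        if positions is None:
            positions = np.arange(n_snps, dtype=np.int64)
        if not edges:
            e = np.empty(0, dtype=np.int64)
            return cls(n_snps, positions, e, e, e, e)
        arr = np.asarray(edges, dtype=np.int64)
        i, j = np.minimum(arr[:, 0], arr[:, 1]), np.maximum(arr[:, 0], arr[:, 1])
        if np.any(i == j):
            raise ValueError("PhaseGraph: self-edges are not allowed")
        return cls(n_snps, positions, i, j, arr[:, 2], arr[:, 3])


def _group_starts(sorted_ids: np.ndarray):
    """Start offsets and lengths of runs of equal values in a sorted array."""
    if len(sorted_ids) == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    change = np.flatnonzero(np.diff(sorted_ids)) + 1
    starts = np.concatenate([[0], change])
    lengths = np.diff(np.concatenate([starts, [len(sorted_ids)]]))
    return starts, lengths


def _pairs_within_groups(starts: np.ndarray, lengths: np.ndarray):
    """All within-group index pairs (absolute indices, first < second)."""
    out_i, out_j = [], []
    cache: dict = {}
    for s, L in zip(starts, lengths):
        if L < 2:
            continue
        tri = cache.get(L)
        if tri is None:
            tri = np.triu_indices(int(L), 1)
            cache[L] = tri
        out_i.append(tri[0] + s)
        out_j.append(tri[1] + s)
    if not out_i:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    return np.concatenate(out_i), np.concatenate(out_j)


def build_phase_graph(matrix: BarcodeMatrix, max_pair_bp: Optional[int] = None) -> PhaseGraph:
    """Accumulate cis/trans support over all co-barcoded SNP pairs.

    Each barcode contributes one vote per pair of its majority-called SNPs.
    ``max_pair_bp`` (typically a few molecule lengths) drops pairs farther
    apart than linked molecules can reach: co-barcoded observations at that
    range come from different molecules of the gem and carry no phase signal.
    """
    barcode, snp, maj = matrix.majority()
    starts, lengths = _group_starts(barcode)
    pi, pj = _pairs_within_groups(starts, lengths)
    n = matrix.n_snps
    if len(pi) == 0:
        e = np.empty(0, dtype=np.int64)
        return PhaseGraph(n, matrix.positions, e, e, e, e)
    si, sj = snp[pi].astype(np.int64), snp[pj].astype(np.int64)
    ci, cj = maj[pi], maj[pj]
    if max_pair_bp is not None:
        keep = np.abs(matrix.positions[sj] - matrix.positions[si]) <= max_pair_bp
        si, sj, ci, cj = si[keep], sj[keep], ci[keep], cj[keep]
    is_cis = ci == cj
    keys = si * n + sj
    ukeys = np.unique(keys)
    cis_keys, cis_counts = np.unique(keys[is_cis], return_counts=True)
    trans_keys, trans_counts = np.unique(keys[~is_cis], return_counts=True)
    cis = np.zeros(len(ukeys), dtype=np.int64)
    trans = np.zeros(len(ukeys), dtype=np.int64)
    cis[np.searchsorted(ukeys, cis_keys)] = cis_counts
    trans[np.searchsorted(ukeys, trans_keys)] = trans_counts
    return PhaseGraph(n, matrix.positions, ukeys // n, ukeys % n, cis, trans)


@dataclass
class PhaseBlock:
    """A set of SNPs with jointly determined relative phase.

    ``strand0_allele[k]`` is the allele block-strand 0 carries at member SNP
    ``snps[k]``; strand 1 carries the complement. The labeling of strands is
    arbitrary until anchoring.
    """

    block_id: int
    snps: np.ndarray  # sorted SNP indices
    strand0_allele: np.ndarray  # int8, aligned with snps
    span_bp: int
    conflicts: int = 0
    n_nontree_edges: int = 0
    low_confidence: bool = False

    @property
    def n_snps(self) -> int:
        return len(self.snps)


class _UnionFind:
    def __init__(self, n):
        self.parent = list(range(n))

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def _refine_assignment(matrix: BarcodeMatrix, snps: np.ndarray, strand0: np.ndarray, max_sweeps: int = 20):
    """Greedy per-SNP refinement of a block's strand assignment.

    Maximizes the maximum-agreement objective sum_b max(m_b, k_b - m_b),
    where m_b counts matches between barcode b's majority calls and the
    assignment, by deterministic ascending-index sweeps of single-SNP flips
    with positive gain. Error-free consistent input is already optimal and
    is left untouched.
    """
    barcode, snp, maj = matrix.majority()
    in_block = np.isin(snp, snps)
    b, s, m = barcode[in_block], snp[in_block], maj[in_block]
    if len(b) == 0:
        return strand0
    ub, binv = np.unique(b, return_inverse=True)
    assign = np.zeros(matrix.n_snps, dtype=np.int8)
    assign[snps] = strand0
    match = (m == assign[s]).astype(np.int64)
    m_b = np.bincount(binv, weights=match).astype(np.int64)
    k_b = np.bincount(binv).astype(np.int64)
    # per-SNP row lists
    order = np.argsort(s, kind="stable")
    s_sorted = s[order]
    starts, lengths = _group_starts(s_sorted)
    row_of_snp = {int(s_sorted[st]): order[st : st + ln] for st, ln in zip(starts, lengths)}

    def score(mb, kb):
        return np.maximum(mb, kb - mb)

    for _ in range(max_sweeps):
        improved = False
        for snp_i in snps.tolist():
            rows = row_of_snp.get(int(snp_i))
            if rows is None:
                continue
            rb = binv[rows]
            delta = np.where(m[rows] == assign[snp_i], -1, 1)
            gain = int(np.sum(score(m_b[rb] + delta, k_b[rb]) - score(m_b[rb], k_b[rb])))
            if gain > 0:
                assign[snp_i] = 1 - assign[snp_i]
                np.add.at(m_b, rb, delta)
                improved = True
        if not improved:
            break
    return assign[snps].astype(np.int8)


def call_phase_blocks(
    graph: PhaseGraph,
    min_support: int = 2,
    min_ratio: float = 0.75,
    matrix: Optional[BarcodeMatrix] = None,
) -> list[PhaseBlock]:
    """Filter edges, form connected components, assign relative phases.

    An edge survives iff max(cis, trans) >= min_support and the majority
    orientation wins at least ``min_ratio`` of its votes (a single chimeric
    gem can then never set an edge on its own at the defaults). Phases are
    propagated over a maximum-support spanning tree (Kruskal, ties broken by
    lower SNP indices for determinism); when ``matrix`` is given, the tree
    assignment is then refined by deterministic single-SNP flips toward the
    per-barcode maximum-agreement optimum. Surviving non-tree edges that
    contradict the final assignment are counted as conflicts.
    """
    if min_support < 1:
        raise ValueError("call_phase_blocks: min_support must be >= 1")
    if not 0.5 < min_ratio <= 1.0:
        raise ValueError("call_phase_blocks: min_ratio must lie in (0.5, 1]")
    support = np.maximum(graph.cis, graph.trans)
    total = graph.cis + graph.trans
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(total > 0, support / total, 0.0)
    keep = (support >= min_support) & (ratio >= min_ratio)
    ei, ej = graph.edge_i[keep], graph.edge_j[keep]
    orient = (graph.trans[keep] > graph.cis[keep]).astype(np.int8)  # 0 cis, 1 trans
    w = support[keep]

    if len(ei) == 0:
        return []

    nodes = np.unique(np.concatenate([ei, ej]))
    node_ix = {int(s): k for k, s in enumerate(nodes)}
    uf = _UnionFind(len(nodes))
    order = np.lexsort((ej, ei, -w))  # weight desc, then (i, j) asc
    tree_adj: dict[int, list] = {int(s): [] for s in nodes}
    nontree = []
    for e in order:
        a, b = node_ix[int(ei[e])], node_ix[int(ej[e])]
        if uf.union(a, b):
            tree_adj[int(ei[e])].append((int(ej[e]), int(orient[e])))
            tree_adj[int(ej[e])].append((int(ei[e]), int(orient[e])))
        else:
            nontree.append(e)

    # BFS phase propagation per component, rooted at the lowest SNP index
    comp_of: dict[int, int] = {}
    strand0: dict[int, int] = {}
    blocks_members: list[list[int]] = []
    for s in nodes.tolist():
        if s in comp_of:
            continue
        cid = len(blocks_members)
        members = []
        strand0[s] = 1  # root convention: strand 0 carries alt at the root
        stack = [s]
        comp_of[s] = cid
        while stack:
            u = stack.pop()
            members.append(u)
            for v, o in tree_adj[u]:
                if v not in comp_of:
                    comp_of[v] = cid
                    strand0[v] = strand0[u] if o == 0 else 1 - strand0[u]
                    stack.append(v)
        blocks_members.append(sorted(members))

    refined: dict[int, np.ndarray] = {}
    if matrix is not None:
        for cid, members in enumerate(blocks_members):
            snps = np.asarray(members, dtype=np.int64)
            s0 = np.asarray([strand0[m] for m in members], dtype=np.int8)
            new = _refine_assignment(matrix, snps, s0)
            refined[cid] = new
            for m, a in zip(members, new):
                strand0[m] = int(a)

    conflicts = np.zeros(len(blocks_members), dtype=np.int64)
    n_nontree = np.zeros(len(blocks_members), dtype=np.int64)
    for e in nontree:
        i, j = int(ei[e]), int(ej[e])
        cid = comp_of[i]
        n_nontree[cid] += 1
        expected = 0 if strand0[i] == strand0[j] else 1
        if expected != int(orient[e]):
            conflicts[cid] += 1

    blocks = []
    for cid, members in enumerate(blocks_members):
        snps = np.asarray(members, dtype=np.int64)
        s0 = refined.get(cid, np.asarray([strand0[m] for m in members], dtype=np.int8))
        span = int(graph.positions[snps[-1]] - graph.positions[snps[0]])
        low = n_nontree[cid] > 0 and conflicts[cid] > 0.05 * n_nontree[cid]
        blocks.append(
            PhaseBlock(
                block_id=cid,
                snps=snps,
                strand0_allele=s0,
                span_bp=span,
                conflicts=int(conflicts[cid]),
                n_nontree_edges=int(n_nontree[cid]),
                low_confidence=bool(low),
            )
        )
    blocks.sort(key=lambda b: int(b.snps[0]))
    for k, b in enumerate(blocks):
        b.block_id = k
    return blocks


@dataclass
class HaplotypePair:
    """Anchored maternal haplotypes: HapA carries the mutation, HapB is the
    wild-type complement. Only anchored, phased SNPs are included."""

    snp_indices: np.ndarray
    positions: np.ndarray
    hapA: np.ndarray  # int8 alleles, aligned with snp_indices
    n_snps_total: int
    unphased_snps: np.ndarray
    anchor_evidence: int
    block_of_snp: Optional[np.ndarray] = None  # block id per included SNP

    @property
    def hapB(self) -> np.ndarray:
        return (1 - self.hapA).astype(np.int8)

    @property
    def n_phased(self) -> int:
        return len(self.snp_indices)

    def hapA_full(self, fill: int = -1) -> np.ndarray:
        out = np.full(self.n_snps_total, fill, dtype=np.int8)
        out[self.snp_indices] = self.hapA
        return out


def pair_from_truth(diplotype) -> HaplotypePair:
    """HaplotypePair from simulator truth (HapA = the mutant haplotype).
    Used by oracles and by dosage analyses that bypass phasing."""
    n = diplotype.n_snps
    return HaplotypePair(
        snp_indices=np.arange(n, dtype=np.int64),
        positions=diplotype.positions.copy(),
        hapA=diplotype.mutant_hap_alleles.astype(np.int8).copy(),
        n_snps_total=n,
        unphased_snps=np.empty(0, dtype=np.int64),
        anchor_evidence=0,
    )


def _mutation_barcodes_from_point_obs(reads: BarcodedReadSet):
    """Barcodes whose majority observation at a point-mutation site is the
    mutant allele (and, separately, the wild-type allele)."""
    if len(reads.mut_obs_barcode) == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    ub, inverse = np.unique(reads.mut_obs_barcode, return_inverse=True)
    mut = np.bincount(inverse, weights=reads.mut_obs_allele)
    tot = np.bincount(inverse)
    return ub[mut * 2 > tot], ub[mut * 2 < tot]


def anchor_hapA(
    blocks: Sequence[PhaseBlock],
    mutation: SVMutation,
    matrix: BarcodeMatrix,
    reads: BarcodedReadSet,
    mutant_barcodes: Optional[np.ndarray] = None,
    vote_window_bp: Optional[float] = None,
) -> HaplotypePair:
    """Designate the mutant-linked strand of each block HapA.

    Mutation-supporting barcodes are taken from point-mutation site reads,
    or passed in (deletions/duplications: from :mod:`hapdose.sv_linkage`
    support finders). Each such barcode votes, via its majority alleles, for
    the block strand it matches; ``vote_window_bp`` restricts votes to SNPs
    near the mutation, where the mutation-bearing molecule (rather than
    unrelated molecules of the same gem) is the evidence. Blocks without
    direct votes are chained to anchored neighbours through shared barcodes;
    blocks that remain unanchored are excluded and reported.
    """
    if mutant_barcodes is None:
        if mutation.kind == "point":
            mutant_barcodes, _ = _mutation_barcodes_from_point_obs(reads)
        else:
            raise ValueError(
                "anchor_hapA: mutation not linkable — deletion/duplication anchoring requires "
                "mutation-supporting barcodes from the SV linkage support finders"
            )
    mutant_barcodes = np.asarray(mutant_barcodes, dtype=np.int64)
    if len(mutant_barcodes) == 0:
        raise ValueError("anchor_hapA: mutation not linkable — zero mutation-supporting barcodes")
    if not blocks:
        raise ValueError("anchor_hapA: no phase blocks to anchor")

    n = matrix.n_snps
    block_of = np.full(n, -1, dtype=np.int64)
    s0_of = np.zeros(n, dtype=np.int8)
    for b in blocks:
        block_of[b.snps] = b.block_id
        s0_of[b.snps] = b.strand0_allele

    barcode, snp, maj = matrix.majority()
    in_block = block_of[snp] >= 0

    # --- direct votes from mutation-supporting barcodes ---
    vote_mask = in_block & np.isin(barcode, mutant_barcodes)
    if vote_window_bp is not None:
        near = (matrix.positions[snp] >= mutation.start - vote_window_bp) & (
            matrix.positions[snp] <= mutation.end + vote_window_bp
        )
        vote_mask &= near
    vb, vs, vm = barcode[vote_mask], snp[vote_mask], maj[vote_mask]
    agree = (vm == s0_of[vs]).astype(np.int64)
    nblocks = len(blocks)
    votes0 = np.bincount(block_of[vs], weights=agree, minlength=nblocks)
    votes1 = np.bincount(block_of[vs], weights=1 - agree, minlength=nblocks)
    n_vote_barcodes = len(np.unique(vb))

    hapA_strand = np.full(nblocks, -1, dtype=np.int64)  # -1 unanchored
    direct = votes0 != votes1
    hapA_strand[direct] = (votes1[direct] > votes0[direct]).astype(np.int64)

    # --- chain unanchored blocks through shared barcodes ---
    if np.any(hapA_strand < 0):
        bk = barcode[in_block] * np.int64(nblocks) + block_of[snp[in_block]]
        agree_all = (maj[in_block] == s0_of[snp[in_block]]).astype(np.int64)
        ukeys, inverse = np.unique(bk, return_inverse=True)
        a0 = np.bincount(inverse, weights=agree_all)
        at = np.bincount(inverse)
        decided = a0 * 2 != at
        side = (a0 * 2 < at).astype(np.int8)  # 0: matches strand0, 1: matches strand1
        ub = ukeys // nblocks
        ublock = ukeys % nblocks
        chain = nx.Graph()
        # accumulate relative-orientation votes between block pairs
        rel_votes: dict = {}
        starts, lengths = _group_starts(ub[decided])
        db, dblock, dside = ub[decided], ublock[decided], side[decided]
        for s, L in zip(starts, lengths):
            if L < 2:
                continue
            for x in range(s, s + L):
                for y in range(x + 1, s + L):
                    key = (int(dblock[x]), int(dblock[y]))
                    rel = int(dside[x] ^ dside[y])
                    cnt = rel_votes.setdefault(key, [0, 0])
                    cnt[rel] += 1
        for (b1, b2), (same, diff) in rel_votes.items():
            if same == diff:
                continue
            chain.add_edge(b1, b2, rel=0 if same > diff else 1)
        anchored = [int(b) for b in np.flatnonzero(hapA_strand >= 0)]
        seen = set(anchored)
        queue = list(anchored)
        while queue:
            u = queue.pop(0)
            if u not in chain:
                continue
            for v in sorted(chain.neighbors(u)):
                if v in seen:
                    continue
                hapA_strand[v] = hapA_strand[u] ^ chain.edges[u, v]["rel"]
                seen.add(v)
                queue.append(v)

    idx_parts, hapA_parts, blk_parts = [], [], []
    unanchored = []
    for b in blocks:
        if hapA_strand[b.block_id] < 0:
            unanchored.append(b.snps)
            continue
        allele = b.strand0_allele if hapA_strand[b.block_id] == 0 else 1 - b.strand0_allele
        idx_parts.append(b.snps)
        hapA_parts.append(allele.astype(np.int8))
        blk_parts.append(np.full(len(b.snps), b.block_id, dtype=np.int64))
    if not idx_parts:
        raise ValueError("anchor_hapA: mutation not linkable — no block could be anchored")
    snp_indices = np.concatenate(idx_parts)
    order = np.argsort(snp_indices)
    snp_indices = snp_indices[order]
    hapA = np.concatenate(hapA_parts)[order]
    block_of_snp = np.concatenate(blk_parts)[order]
    phased_mask = np.zeros(n, dtype=bool)
    phased_mask[snp_indices] = True
    return HaplotypePair(
        snp_indices=snp_indices,
        positions=matrix.positions[snp_indices],
        hapA=hapA,
        n_snps_total=n,
        unphased_snps=np.flatnonzero(~phased_mask),
        anchor_evidence=int(n_vote_barcodes),
        block_of_snp=block_of_snp,
    )


def n50_phase_block(blocks: Sequence[PhaseBlock]) -> float:
    """Standard N50 of block spans: the span L such that blocks of span >= L
    cover at least half the total phased span."""
    if not blocks:
        raise ValueError("n50_phase_block: no blocks")
    spans = np.sort(np.asarray([b.span_bp for b in blocks], dtype=np.float64))[::-1]
    half = spans.sum() / 2.0
    cum = np.cumsum(spans)
    return float(spans[np.searchsorted(cum, half)])


@dataclass(frozen=True)
class ConcordanceResult:
    concordance: float
    switch_errors: int
    n_compared: int


def phasing_concordance(pair: HaplotypePair, truth_hap: np.ndarray) -> ConcordanceResult:
    """Fraction of phased SNPs at which HapA matches a truth allele vector,
    plus the switch-error count between consecutive phased SNPs."""
    truth_hap = np.asarray(truth_hap)
    if len(truth_hap) != pair.n_snps_total:
        raise ValueError("phasing_concordance: truth vector length mismatch")
    if pair.n_phased == 0:
        raise ValueError("phasing_concordance: no phased SNPs to compare")
    match = pair.hapA == truth_hap[pair.snp_indices]
    switches = int(np.sum(match[1:] != match[:-1]))
    return ConcordanceResult(
        concordance=float(np.mean(match)), switch_errors=switches, n_compared=int(len(match))
    )
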