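"""Linking a large deletion or duplication to one phased haplotype.

A large deletion hides het SNPs on the mutant haplotype, so barcodes with
observations *inside* the deleted interval are wild-type evidence, while
barcodes whose molecules span the locus (observations on both flanks, none
inside) are mutant evidence; their flanking alleles must phase to a single
haplotype across the gap — the allele-space equivalent of re-aligning the
mutant reads to a reference from which the deletion has been excised. A
tandem duplication shifts interior allele fractions to roughly 2:1 (two
mutant copies vs one wild-type copy), so SNPs with divergent pooled allele
fractions identify the duplicated haplotype, and the gems carrying the
over-represented allele are mutant evidence.

The ``*_support`` finders are phasing-free (they feed HapA anchoring); the
``link_*`` operations confirm the linkage against an anchored pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .model import BarcodedReadSet, SVMutation
from .phasing import HaplotypePair

__all__ = [
    "SVLinkageResult",
    "deletion_support",
    "duplication_support",
    "link_deletion",
    "link_duplication",
]


@dataclass
class SVLinkageResult:
    """Outcome of linking an SV mutation to a haplotype.

    ``mutant_hap_label`` is "HapA" when the mutant-supporting evidence sits
    on the anchored HapA strand (the expected, self-consistent outcome).
    ``flank_check`` (deletions only) records whether the 5' and 3' flanking
    het SNPs of the mutant barcodes phase to one haplotype.
    """

    kind: str
    mutant_hap_label: str  # "HapA" or "HapB"
    supporting_mutant_barcodes: np.ndarray
    supporting_wildtype_barcodes: np.ndarray
    confidence: float
    votes: dict = field(default_factory=dict)
    flank_check: Optional[bool] = None
    divergent_snps: Optional[np.ndarray] = None
    low_confidence: bool = False

    def __post_init__(self) -> None:
        overlap = np.intersect1d(self.supporting_mutant_barcodes, self.supporting_wildtype_barcodes)
        if len(overlap):
            raise ValueError("SVLinkageResult: supporting barcode sets must be disjoint")

    @property
    def hapA_is_mutant(self) -> bool:
        return self.mutant_hap_label == "HapA"


def _barcode_flags(reads: BarcodedReadSet, snp_mask: np.ndarray) -> np.ndarray:
    """Barcodes (sorted, unique) with >=1 observation at a masked SNP."""
    hit = snp_mask[reads.snp_index]
    return np.unique(reads.barcode[hit])


def _interval_snp_masks(reads: BarcodedReadSet, sv: SVMutation, flank_bp: float):
    pos = reads.snp_positions
    interior = (pos >= sv.start) & (pos < sv.end)
    left = (pos >= sv.start - flank_bp) & (pos < sv.start)
    right = (pos >= sv.end) & (pos < sv.end + flank_bp)
    return interior, left, right


def deletion_support(
    reads: BarcodedReadSet,
    deletion: SVMutation,
    flank_bp: float = 1.5 * 52_700.0,
):
    """Phasing-free deletion evidence.

    Returns (mutant_barcodes, wildtype_barcodes): wild-type barcodes observe
    SNPs inside the deletion; mutant candidates observe both flanks within
    ``flank_bp`` of the breakpoints and nothing inside.
    """
    if deletion.kind != "deletion":
        raise ValueError("deletion_support: mutation kind must be 'deletion'")
    interior, left, right = _interval_snp_masks(reads, deletion, flank_bp)
    if not interior.any():
        raise ValueError("deletion_support: deletion interval contains no het SNP")
    if not left.any() or not right.any():
        raise ValueError("deletion_support: no het SNP in a flank window")
    wt = _barcode_flags(reads, interior)
    has_left = _barcode_flags(reads, left)
    has_right = _barcode_flags(reads, right)
    spanning = np.intersect1d(has_left, has_right)
    mut = np.setdiff1d(spanning, wt)
    if len(mut) == 0:
        raise ValueError("deletion not linkable: no spanning barcodes without interior reads")
    return mut, wt


def _barcode_side_votes(
    reads: BarcodedReadSet,
    pair: HaplotypePair,
    barcodes: np.ndarray,
    snp_mask: np.ndarray,
):
    """Per-barcode majority side vs the anchored pair over masked SNPs.

    Returns (barcodes_decided, side) with side 0 = matches HapA alleles,
    1 = matches HapB; barcodes tying are dropped.
    """
    hapA_full = pair.hapA_full()
    phased = hapA_full >= 0
    use = snp_mask[reads.snp_index] & phased[reads.snp_index] & np.isin(reads.barcode, barcodes)
    b, s, a = reads.barcode[use], reads.snp_index[use], reads.allele[use]
    if len(b) == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int8)
    agree = (a == hapA_full[s]).astype(np.int64)
    ub, inverse = np.unique(b, return_inverse=True)
    n_agree = np.bincount(inverse, weights=agree)
    n_tot = np.bincount(inverse)
    decided = n_agree * 2 != n_tot
    side = (n_agree * 2 < n_tot).astype(np.int8)
    return ub[decided], side[decided]


def link_deletion(
    reads: BarcodedReadSet,
    deletion: SVMutation,
    pair: HaplotypePair,
    flank_scale: float = 1.5,
    molecule_mean_len: float = 52_700.0,
) -> SVLinkageResult:
    """Confirm the deletion-to-haplotype linkage against the anchored pair.

    Mutant-supporting barcodes must be phase-consistent across the excised
    gap: their 5'-flank and 3'-flank majority alleles must sit on the same
    haplotype (the allele-space form of the deletion-reference re-alignment
    check), and the flanking het SNPs must jointly phase to one haplotype.
    """
    flank_bp = flank_scale * molecule_mean_len
    mut_cand, wt = deletion_support(reads, deletion, flank_bp=flank_bp)
    interior, left, right = _interval_snp_masks(reads, deletion, flank_bp)

    lb, lside = _barcode_side_votes(reads, pair, mut_cand, left)
    rb, rside = _barcode_side_votes(reads, pair, mut_cand, right)
    both, li, ri = np.intersect1d(lb, rb, return_indices=True)
    consistent = lside[li] == rside[ri]
    mut = both[consistent]
    sides = lside[li][consistent]
    if len(mut) == 0:
        raise ValueError("deletion not linkable: no cross-gap phase-consistent spanning barcodes")
    nA = int(np.sum(sides == 0))
    nB = int(np.sum(sides == 1))
    label = "HapA" if nA >= nB else "HapB"
    confidence = max(nA, nB) / (nA + nB)
    # the aggregated 5' and 3' flanks must each favour the same haplotype
    votes_5p = np.bincount(lside[li][consistent], minlength=2)
    votes_3p = np.bincount(rside[ri][consistent], minlength=2)
    flank_check = bool(np.argmax(votes_5p) == np.argmax(votes_3p)) and confidence > 0.5
    return SVLinkageResult(
        kind="deletion",
        mutant_hap_label=label,
        supporting_mutant_barcodes=mut,
        supporting_wildtype_barcodes=np.setdiff1d(wt, mut),
        confidence=float(confidence),
        votes={
            "hapA": nA,
            "hapB": nB,
            "spanning_candidates": int(len(mut_cand)),
            "cross_gap_inconsistent": int(np.sum(~consistent)),
            "flank5": votes_5p.tolist(),
            "flank3": votes_3p.tolist(),
        },
        flank_check=flank_check,
    )


def duplication_support(
    reads: BarcodedReadSet,
    duplication: SVMutation,
    af_low: float = 0.4,
    af_high: float = 0.6,
):
    """Phasing-free duplication evidence.

    Pools per-SNP allele fractions inside the interval; SNPs whose alt
    fraction falls outside [af_low, af_high] are divergent (the 2:1 copy
    imbalance pulls the duplicated allele toward 2/3). Returns
    (mutant_barcodes, divergent_snp_indices, overrepresented_alleles).
    """
    if duplication.kind != "duplication":
        raise ValueError("duplication_support: mutation kind must be 'duplication'")
    if not 0.0 < af_low < af_high < 1.0:
        raise ValueError("duplication_support: need 0 < af_low < af_high < 1")
    pos = reads.snp_positions
    interior = (pos >= duplication.start) & (pos < duplication.end)
    if not interior.any():
        raise ValueError("duplication_support: interval contains no het SNP")
    in_obs = interior[reads.snp_index]
    s, a = reads.snp_index[in_obs], reads.allele[in_obs]
    n_snps = reads.n_snps
    alt = np.bincount(s, weights=a, minlength=n_snps)
    tot = np.bincount(s, minlength=n_snps)
    seen = interior & (tot > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        af = np.where(tot > 0, alt / np.maximum(tot, 1), 0.5)
    divergent = seen & ((af < af_low) | (af > af_high))
    div_idx = np.flatnonzero(divergent)
    if len(div_idx) == 0:
        raise ValueError("duplication not linkable: no SNP with divergent allele fraction")
    over = (af[div_idx] > af_high).astype(np.int8)  # over-represented allele per divergent SNP
    # gems carrying the over-represented allele at any divergent SNP
    over_full = np.full(n_snps, -1, dtype=np.int8)
    over_full[div_idx] = over
    carries = in_obs & (over_full[reads.snp_index] == reads.allele)
    mut = np.unique(reads.barcode[carries])
    if len(mut) == 0:
        raise ValueError("duplication not linkable: no gem carries the over-represented alleles")
    return mut, div_idx, over


def link_duplication(
    reads: BarcodedReadSet,
    duplication: SVMutation,
    pair: HaplotypePair,
    af_low: float = 0.4,
    af_high: float = 0.6,
) -> SVLinkageResult:
    """Confirm the duplication-to-haplotype linkage against the anchored
    pair by majority vote of the divergent SNPs: at each one, the haplotype
    carrying the over-represented allele is the duplicated one. A split vote
    below 75% flags the result low-confidence."""
    mut, div_idx, over = duplication_support(reads, duplication, af_low=af_low, af_high=af_high)
    hapA_full = pair.hapA_full()
    usable = hapA_full[div_idx] >= 0
    if not usable.any():
        raise ValueError("duplication not linkable: no divergent SNP is phased")
    votes_A = int(np.sum(hapA_full[div_idx[usable]] == over[usable]))
    votes_B = int(np.sum(usable)) - votes_A
    label = "HapA" if votes_A >= votes_B else "HapB"
    confidence = max(votes_A, votes_B) / (votes_A + votes_B)
    # wild-type evidence: gems whose interior majority is the complementary allele
    interior = np.zeros(reads.n_snps, dtype=bool)
    interior[div_idx] = True
    under_full = np.full(reads.n_snps, -1, dtype=np.int8)
    under_full[div_idx] = 1 - over
    carries_wt = (under_full[reads.snp_index] == reads.allele) & interior[reads.snp_index]
    wt = np.setdiff1d(np.unique(reads.barcode[carries_wt]), mut)
    return SVLinkageResult(
        kind="duplication",
        mutant_hap_label=label,
        supporting_mutant_barcodes=mut,
        supporting_wildtype_barcodes=wt,
        confidence=float(confidence),
        votes={"hapA": votes_A, "hapB": votes_B},
        divergent_snps=div_idx,
        low_confidence=bool(confidence < 0.75),
    )
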