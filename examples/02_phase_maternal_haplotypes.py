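"""Phase a maternal sample from barcoded reads and anchor HapA.

Runs the barcode matrix → phase graph → phase blocks → anchoring chain on
an error-free simulated sample with a point mutation and compares the
reconstruction with simulator truth.
"""

from hapdose import (
    RegionSpec,
    SimParams,
    SVMutation,
    anchor_hapA,
    build_barcode_matrix,
    build_phase_graph,
    call_phase_blocks,
    n50_phase_block,
    phasing_concordance,
    simulate_diplotype,
    simulate_linked_reads,
)

region = RegionSpec("chrX", 31_100_000, 33_300_000, 850)
mutation = SVMutation("point", 32_000_000, 32_000_001, "splice-site point mutation")
diplo = simulate_diplotype(region, mutation, seed=7)
reads = simulate_linked_reads(diplo, SimParams(seq_error_rate=0.001), seed=8)

matrix = build_barcode_matrix(reads)
graph = build_phase_graph(matrix, max_pair_bp=210_000)
blocks = call_phase_blocks(graph, min_support=2, min_ratio=0.75, matrix=matrix)
pair = anchor_hapA(blocks, mutation, matrix, reads, vote_window_bp=80_000)

conc = phasing_concordance(pair, diplo.mutant_hap_alleles)
print(f"phase blocks: {len(blocks)}, N50 {n50_phase_block(blocks)/1e3:.1f} kb")
print(f"phased SNPs: {pair.n_phased}/{diplo.n_snps}; "
      f"mutation-supporting gems used for anchoring: {pair.anchor_evidence}")
print(f"concordance of HapA with the true mutant haplotype: {conc.concordance:.2%} "
      f"({conc.switch_errors} switch errors)")
# Concordance near 100% means the mutant-linked allele at essentially every
# SNP was recovered, the prerequisite for dosage analysis in plasma.
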