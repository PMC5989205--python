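"""End-to-end orchestration: simulate → phase → sv-link → dosage → report.

Reproduces the five-family carrier study design: per family, maternal
linked reads are phased and anchored, the mutation is linked to HapA, and
each plasma draw receives an independent dosage call. One master seed fans
out to per-stage seeds by stable hashing so every stage is independently
reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from . import io as hio
from .model import BarcodedReadSet, PlasmaCounts, RegionSpec, SimParams, SVMutation
from .phasing import (
    HaplotypePair,
    anchor_hapA,
    build_barcode_matrix,
    build_phase_graph,
    call_phase_blocks,
    n50_phase_block,
    phasing_concordance,
)
from .rhdo import (
    NIPDReport,
    adjust_recombination,
    call_fetal_genotype,
    detect_changepoints,
    fraction_series,
    remove_outliers,
)
from .simulate import DMD_REGION, DrawSpec, FamilyConfig, simulate_family
from .sv_linkage import deletion_support, duplication_support, link_deletion, link_duplication

__all__ = [
    "PipelineParams",
    "RunConfig",
    "derive_seed",
    "study_families",
    "phase_sample",
    "analyze_draw",
    "run_family",
    "run_pipeline",
    "load_run_config",
]

logger = logging.getLogger("hapdose")

__version__ = "0.1.0"


def derive_seed(master: int, label: str) -> int:
    """Stable per-stage seed below 2^31, derived from a master seed."""
    digest = hashlib.blake2b(f"{master}:{label}".encode(), digest_size=8).digest()
    return int.from_bytes(digest, "little") % (2**31 - 1)


@dataclass(frozen=True)
class PipelineParams:
    """All analysis tunables in one validated bundle."""

    min_support: int = 2
    min_ratio: float = 0.75
    af_low: float = 0.4
    af_high: float = 0.6
    n_sigma: float = 3.0
    penalty: object = "mbic"
    min_seg: int = 10
    alpha: float = 0.01
    flank_scale: float = 1.5
    max_pair_molecules: float = 4.0  # phase-graph pair window, in molecule lengths

    def __post_init__(self) -> None:
        if self.min_support < 1:
            raise ValueError("PipelineParams: min_support must be >= 1")
        if not 0.5 < self.min_ratio <= 1.0:
            raise ValueError("PipelineParams: min_ratio must lie in (0.5, 1]")
        if not 0.0 < self.af_low < self.af_high < 1.0:
            raise ValueError("PipelineParams: need 0 < af_low < af_high < 1")
        if self.n_sigma <= 0 or self.min_seg < 1 or self.flank_scale <= 0:
            raise ValueError("PipelineParams: n_sigma, min_seg, flank_scale must be positive")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("PipelineParams: alpha must lie in (0, 1)")


#: Synthetic stand-ins for the five study families: mutation intervals are
#: plausible coordinates for the quoted exon ranges inside a 2.2 Mb
#: chrX:31.1-33.3 Mb dystrophin-like target (the gene runs 3'→5' on the
#: minus strand, so early exons sit at high coordinates). Fetal fractions
#: per draw are the printed values; only family 5 has a fetal crossover.
def study_families(region: RegionSpec = DMD_REGION) -> list[FamilyConfig]:
    mid_snp = region.n_snps // 2
    return [
        FamilyConfig(
            name="DMD-01",
            mutation=SVMutation("deletion", 31_950_000, 32_090_000, "exons 49-52 deletion"),
            transmitted="wildtype",
            draws=(DrawSpec(0.0566, "6wk"), DrawSpec(0.0774, "17wk")),
            region=region,
        ),
        FamilyConfig(
            name="DMD-02",
            mutation=SVMutation("duplication", 33_140_000, 33_180_000, "exon 2 duplication"),
            transmitted="mutant",
            draws=(DrawSpec(0.0925, "9wk"), DrawSpec(0.0685, "12wk")),
            region=region,
        ),
        FamilyConfig(
            name="DMD-03",
            mutation=SVMutation("deletion", 32_950_000, 33_050_000, "exons 3-7 deletion"),
            transmitted="mutant",
            draws=(DrawSpec(0.0634, "8wk"), DrawSpec(0.0880, "11wk")),
            region=region,
        ),
        FamilyConfig(
            name="DMD-04",
            mutation=SVMutation("point", 32_941_000, 32_941_001, "c.649+2T>C"),
            transmitted="mutant",
            draws=(DrawSpec(0.0624, "7wk"),),
            region=region,
        ),
        FamilyConfig(
            name="DMD-05",
            mutation=SVMutation("deletion", 31_790_000, 31_990_000, "exons 52-62 deletion"),
            transmitted="mutant",
            draws=(DrawSpec(0.0410, "8wk"), DrawSpec(0.0507, "12wk")),
            recomb_breakpoints=(mid_snp,),
            region=region,
        ),
    ]


@dataclass
class PhasedSample:
    pair: HaplotypePair
    blocks: list
    matrix: object
    sv_result: Optional[object]
    n50_bp: float


def phase_sample(
    reads: BarcodedReadSet,
    mutation: SVMutation,
    params: PipelineParams = PipelineParams(),
    sim_params: SimParams = SimParams(),
) -> PhasedSample:
    """Phase one maternal sample and anchor HapA to the mutation."""
    matrix = build_barcode_matrix(reads)
    graph = build_phase_graph(
        matrix, max_pair_bp=int(params.max_pair_molecules * sim_params.molecule_mean_len)
    )
    blocks = call_phase_blocks(
        graph, min_support=params.min_support, min_ratio=params.min_ratio, matrix=matrix
    )
    flank_bp = params.flank_scale * sim_params.molecule_mean_len
    if mutation.kind == "deletion":
        mut_bcs, _ = deletion_support(reads, mutation, flank_bp=flank_bp)
    elif mutation.kind == "duplication":
        mut_bcs, _, _ = duplication_support(
            reads, mutation, af_low=params.af_low, af_high=params.af_high
        )
    else:
        mut_bcs = None
    pair = anchor_hapA(
        blocks, mutation, matrix, reads, mutant_barcodes=mut_bcs, vote_window_bp=flank_bp
    )
    if mutation.kind == "deletion":
        sv_result = link_deletion(
            reads,
            mutation,
            pair,
            flank_scale=params.flank_scale,
            molecule_mean_len=sim_params.molecule_mean_len,
        )
    elif mutation.kind == "duplication":
        sv_result = link_duplication(reads, mutation, pair, af_low=params.af_low, af_high=params.af_high)
    else:
        sv_result = None
    return PhasedSample(
        pair=pair,
        blocks=blocks,
        matrix=matrix,
        sv_result=sv_result,
        n50_bp=n50_phase_block(blocks) if blocks else 0.0,
    )


def analyze_draw(
    counts: PlasmaCounts,
    pair: HaplotypePair,
    mutation: Optional[SVMutation] = None,
    params: PipelineParams = PipelineParams(),
    ff_seed: int = 0,
) -> NIPDReport:
    """Full dosage analysis of one plasma draw.

    Outlier screen → changepoint detection → recombination adjustment
    (anchored at the SNP nearest the mutation, so the call refers to the
    mutation locus) → pooled exact-binomial genotype call.
    """
    series = fraction_series(counts, pair)
    n0 = series.n_retained
    series = remove_outliers(series, n_sigma=params.n_sigma)
    n_removed = n0 - series.n_retained
    cps = detect_changepoints(series, penalty=params.penalty, min_seg=params.min_seg)
    anchor = 0
    if mutation is not None:
        pos_r, _, _, _ = series.retained()
        mut_mid = (mutation.start + mutation.end) // 2
        anchor = int(np.argmin(np.abs(pos_r - mut_mid)))
    adjusted, adj = adjust_recombination(series, cps, alpha=params.alpha, anchor=anchor)
    return call_fetal_genotype(
        adjusted,
        alpha=params.alpha,
        adjustment=adj,
        cps=cps,
        n_outliers_removed=n_removed,
        ff_seed=ff_seed,
    )


def run_family(
    config: FamilyConfig,
    sim_params: SimParams,
    params: PipelineParams,
    seed: int,
) -> dict:
    """Simulate one family, run the full analysis, score against truth."""
    dataset = simulate_family(config, sim_params, derive_seed(seed, f"sim:{config.name}"))
    diplo = dataset.diplotype
    phased = phase_sample(dataset.reads, config.mutation, params, sim_params)
    conc = phasing_concordance(phased.pair, diplo.mutant_hap_alleles)
    draws = []
    for i, counts in enumerate(dataset.plasma):
        report = analyze_draw(
            counts,
            phased.pair,
            mutation=config.mutation,
            params=params,
            ff_seed=derive_seed(seed, f"ff:{config.name}:{i}"),
        )
        draws.append(
            {
                "label": dataset.truth["draw_labels"][i],
                "true_fetal_fraction": dataset.truth["fetal_fractions"][i],
                "report": report.to_dict(),
                "correct": report.call == dataset.truth["expected_call"],
            }
        )
    sv = phased.sv_result
    return {
        "family": config.name,
        "truth": dataset.truth,
        "phasing": {
            "n_blocks": len(phased.blocks),
            "n50_bp": phased.n50_bp,
            "n_phased_snps": phased.pair.n_phased,
            "n_unphased_snps": int(len(phased.pair.unphased_snps)),
            "anchor_evidence": phased.pair.anchor_evidence,
            "concordance_vs_truth": conc.concordance,
            "switch_errors": conc.switch_errors,
        },
        "sv_linkage": None
        if sv is None
        else {
            "kind": sv.kind,
            "mutant_hap_label": sv.mutant_hap_label,
            "confidence": sv.confidence,
            "flank_check": sv.flank_check,
            "low_confidence": sv.low_confidence,
            "n_mutant_barcodes": int(len(sv.supporting_mutant_barcodes)),
            "n_wildtype_barcodes": int(len(sv.supporting_wildtype_barcodes)),
        },
        "recombination_flagged": any(d["report"]["recombination_detected"] for d in draws),
        "all_draws_correct": all(d["correct"] for d in draws) if draws else None,
        "draws": draws,
    }


@dataclass
class RunConfig:
    """Validated end-to-end run description."""

    families: Sequence[FamilyConfig]
    sim_params: SimParams = SimParams()
    params: PipelineParams = PipelineParams()
    seed: int = 0

    def config_hash(self) -> str:
        def enc(o):
            if isinstance(o, (FamilyConfig, SimParams, PipelineParams, SVMutation, RegionSpec, DrawSpec)):
                return {"__type__": type(o).__name__, **asdict(o)}
            if isinstance(o, tuple):
                return list(o)
            raise TypeError(str(type(o)))

        blob = json.dumps(
            {
                "families": [enc(f) for f in self.families],
                "sim_params": enc(self.sim_params),
                "params": enc(self.params),
                "seed": self.seed,
            },
            sort_keys=True,
            default=enc,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Run every family, write one JSON report per family plus a summary.

    Identical config + seed reproduce byte-identical reports.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    provenance = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
    }
    if not config.families:
        logger.warning("run_pipeline: no families configured; empty run")
    results = []
    for fam in config.families:
        logger.info("running family %s", fam.name)
        try:
            res = run_family(fam, config.sim_params, config.params, config.seed)
        except Exception as exc:  # halt with a stage-tagged message
            raise RuntimeError(f"pipeline failed in family {fam.name}: {exc}") from exc
        res["provenance"] = provenance
        hio.write_json(outdir / f"{fam.name}.report.json", res)
        results.append(res)
    summary = {
        "provenance": provenance,
        "n_families": len(results),
        "n_draws": sum(len(r["draws"]) for r in results),
        "families_all_correct": sum(1 for r in results if r["all_draws_correct"]),
        "families_recombination_flagged": [
            r["family"] for r in results if r["recombination_flagged"]
        ],
        "min_phasing_concordance": min(
            (r["phasing"]["concordance_vs_truth"] for r in results), default=None
        ),
    }
    hio.write_json(outdir / "summary.json", summary)
    return {"summary": summary, "families": results}


def load_run_config(path) -> RunConfig:
    """Build a RunConfig from a YAML file.

    Schema: top-level keys ``seed``, ``sim_params``, ``params`` (both
    optional dicts of the dataclass fields) and ``families``: a list of
    {name, mutation: {kind, start, end, description}, transmitted,
    fetal_fractions: [..], labels: [..], recomb_breakpoints: [..],
    region: {chrom, start, end, n_snps}, depth_per_snp}.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sim = SimParams(**raw.get("sim_params", {}))
    params = PipelineParams(**raw.get("params", {}))
    fams = []
    for f in raw.get("families", []):
        try:
            mut = SVMutation(**f["mutation"])
            region = RegionSpec(**f["region"]) if "region" in f else DMD_REGION
            ffs = f.get("fetal_fractions", [])
            labels = f.get("labels", [""] * len(ffs))
            fams.append(
                FamilyConfig(
                    name=f["name"],
                    mutation=mut,
                    transmitted=f["transmitted"],
                    draws=tuple(DrawSpec(float(x), str(l)) for x, l in zip(ffs, labels)),
                    recomb_breakpoints=tuple(f.get("recomb_breakpoints", [])),
                    region=region,
                    depth_per_snp=int(f.get("depth_per_snp", 200)),
                )
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ValueError(f"malformed family config {f.get('name', '?')!r}: {exc}") from exc
    return RunConfig(families=fams, sim_params=sim, params=params, seed=int(raw.get("seed", 0)))
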