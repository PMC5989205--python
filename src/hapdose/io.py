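"""Format adapters: VCF 4.2 (pysam), TSV dialects, BED, BX-tagged SAM, JSON.

Internal coordinates are 0-based half-open; VCF output is 1-based per the
standard. The conversions live here and nowhere else. The custom TSV
dialects are documented next to their writers; malformed records raise
``ValueError`` naming the offending line.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pysam

from .model import BarcodedReadSet, MaternalDiplotype, PlasmaCounts, SVMutation
from .phasing import HaplotypePair

__all__ = [
    "write_phased_vcf",
    "read_phased_vcf",
    "pair_to_vcf",
    "pair_from_vcf",
    "write_plasma_tsv",
    "read_plasma_tsv",
    "write_reads_tsv",
    "read_reads_tsv",
    "write_sv_bed",
    "read_sv_bed",
    "write_json",
    "read_json",
    "write_barcoded_sam",
    "read_barcoded_sam",
]

_CONTIG_PAD = 10_000


def _vcf_header(chrom: str, contig_len: int) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    header.add_line(f"##contig=<ID={chrom},length={contig_len}>")
    header.add_line(
        '##INFO=<ID=HAPA,Number=1,Type=Integer,Description='
        '"Allele index carried by HapA, the mutant-linked maternal haplotype; '
        'GT is written HapA|HapB">'
    )
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line('##FORMAT=<ID=PS,Number=1,Type=Integer,Description="Phase block ID">')
    header.add_sample("MOTHER")
    return header


def write_phased_vcf(
    path,
    chrom: str,
    positions: np.ndarray,
    ref: np.ndarray,
    alt: np.ndarray,
    hapA: np.ndarray,
    phase_set: np.ndarray | None = None,
) -> None:
    """Write maternal het SNPs as a phased VCF, GT ordered HapA|HapB.

    ``hapA`` holds 0/1 allele indices; SNPs with hapA < 0 (unphased) are
    written unphased (0/1) without a PS tag.
    """
    contig_len = int(positions[-1]) + _CONTIG_PAD if len(positions) else _CONTIG_PAD
    header = _vcf_header(chrom, contig_len)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for k in range(len(positions)):
            rec = vcf.new_record(
                contig=chrom,
                start=int(positions[k]),
                stop=int(positions[k]) + 1,
                alleles=(str(ref[k]), str(alt[k])),
            )
            a = int(hapA[k])
            if a >= 0:
                rec.info["HAPA"] = a
                rec.samples["MOTHER"]["GT"] = (a, 1 - a)
                rec.samples["MOTHER"].phased = True
                if phase_set is not None:
                    rec.samples["MOTHER"]["PS"] = int(phase_set[k])
            else:
                rec.samples["MOTHER"]["GT"] = (0, 1)
                rec.samples["MOTHER"].phased = False
            vcf.write(rec)


def read_phased_vcf(path) -> dict:
    """Read a VCF written by :func:`write_phased_vcf`.

    Returns dict with chrom, positions (0-based), ref, alt, hapA (-1 where
    unphased) and phase_set (-1 where absent).
    """
    chrom = None
    positions, ref, alt, hapA, ps = [], [], [], [], []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            chrom = rec.chrom
            positions.append(rec.start)
            ref.append(rec.ref)
            alt.append(rec.alts[0])
            sample = rec.samples[0]
            if sample.phased:
                hapA.append(int(sample["GT"][0]))
                ps.append(int(sample.get("PS") or -1))
            else:
                hapA.append(-1)
                ps.append(-1)
    return {
        "chrom": chrom,
        "positions": np.asarray(positions, dtype=np.int64),
        "ref": np.asarray(ref),
        "alt": np.asarray(alt),
        "hapA": np.asarray(hapA, dtype=np.int8),
        "phase_set": np.asarray(ps, dtype=np.int64),
    }


def pair_to_vcf(path, diplotype: MaternalDiplotype, pair: HaplotypePair) -> None:
    """Convenience: write an anchored pair over a diplotype's SNP table."""
    hapA = pair.hapA_full(fill=-1)
    ps = np.full(diplotype.n_snps, -1, dtype=np.int64)
    if pair.block_of_snp is not None:
        ps[pair.snp_indices] = pair.block_of_snp
    else:
        ps[pair.snp_indices] = 0
    write_phased_vcf(
        path,
        diplotype.region.chrom,
        diplotype.positions,
        diplotype.ref,
        diplotype.alt,
        hapA,
        phase_set=ps,
    )


def pair_from_vcf(path) -> HaplotypePair:
    """Rebuild a HaplotypePair from a phased VCF (phased records only)."""
    d = read_phased_vcf(path)
    phased = d["hapA"] >= 0
    idx = np.flatnonzero(phased)
    return HaplotypePair(
        snp_indices=idx,
        positions=d["positions"][idx],
        hapA=d["hapA"][idx],
        n_snps_total=len(d["positions"]),
        unphased_snps=np.flatnonzero(~phased),
        anchor_evidence=0,
        block_of_snp=d["phase_set"][idx],
    )


# --- plasma counts TSV: "pos<TAB>ref<TAB>alt", 0-based positions ---


def write_plasma_tsv(path, counts: PlasmaCounts) -> None:
    with open(path, "w") as fh:
        fh.write("#pos\tref\talt\n")
        for p, r, a in zip(counts.positions, counts.ref_depth, counts.alt_depth):
            fh.write(f"{p}\t{r}\t{a}\n")


def read_plasma_tsv(path) -> PlasmaCounts:
    positions, ref, alt = [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}: line {lineno}: expected 3 tab-separated fields")
            try:
                positions.append(int(parts[0]))
                ref.append(int(parts[1]))
                alt.append(int(parts[2]))
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-integer field") from exc
    return PlasmaCounts(
        positions=np.asarray(positions, dtype=np.int64),
        ref_depth=np.asarray(ref, dtype=np.int64),
        alt_depth=np.asarray(alt, dtype=np.int64),
    )


# --- barcoded observations TSV: "barcode<TAB>snp_index<TAB>pos<TAB>allele" ---
# allele is the observed base; lines with snp_index == -1 carry point-mutation
# site observations, with allele "M" (mutant) or "W" (wild type).


def write_reads_tsv(path, reads: BarcodedReadSet, ref: np.ndarray, alt: np.ndarray) -> None:
    with open(path, "w") as fh:
        fh.write("#barcode\tsnp_index\tpos\tallele\n")
        for b, s, a in zip(reads.barcode, reads.snp_index, reads.allele):
            base = alt[s] if a == 1 else ref[s]
            fh.write(f"{b}\t{s}\t{reads.snp_positions[s]}\t{base}\n")
        for b, a in zip(reads.mut_obs_barcode, reads.mut_obs_allele):
            fh.write(f"{b}\t-1\t-1\t{'M' if a == 1 else 'W'}\n")


def read_reads_tsv(path, snp_positions: np.ndarray, ref: np.ndarray, alt: np.ndarray) -> BarcodedReadSet:
    barcode, snp, allele = [], [], []
    mub, mua = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}: line {lineno}: expected 4 tab-separated fields")
            try:
                b, s = int(parts[0]), int(parts[1])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-integer field") from exc
            base = parts[3]
            if s == -1:
                if base not in ("M", "W"):
                    raise ValueError(f"{path}: line {lineno}: mutation allele must be M or W")
                mub.append(b)
                mua.append(1 if base == "M" else 0)
                continue
            if not 0 <= s < len(snp_positions):
                raise ValueError(f"{path}: line {lineno}: snp_index {s} out of range")
            if base == ref[s]:
                a = 0
            elif base == alt[s]:
                a = 1
            else:
                raise ValueError(
                    f"{path}: line {lineno}: allele {base!r} is neither ref nor alt at SNP {s}"
                )
            barcode.append(b)
            snp.append(s)
            allele.append(a)
    return BarcodedReadSet(
        snp_positions=np.asarray(snp_positions, dtype=np.int64),
        barcode=np.asarray(barcode, dtype=np.int64),
        snp_index=np.asarray(snp, dtype=np.int32),
        allele=np.asarray(allele, dtype=np.int8),
        mut_obs_barcode=np.asarray(mub, dtype=np.int64),
        mut_obs_allele=np.asarray(mua, dtype=np.int8),
    )


# --- SV BED: chrom, start, end, kind, description (0-based half-open) ---


def write_sv_bed(path, chrom: str, sv: SVMutation) -> None:
    with open(path, "w") as fh:
        fh.write(f"{chrom}\t{sv.start}\t{sv.end}\t{sv.kind}\t{sv.description}\n")


def read_sv_bed(path) -> tuple[str, SVMutation]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}: line {lineno}: expected >=4 tab-separated fields")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-integer coordinate") from exc
            desc = parts[4] if len(parts) > 4 else ""
            return parts[0], SVMutation(kind=parts[3], start=start, end=end, description=desc)
    raise ValueError(f"{path}: no SV record found")


def write_json(path, obj: dict) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def read_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


# --- optional BX-tagged SAM (observation-level, one 1 bp record per read) ---


def write_barcoded_sam(path, reads: BarcodedReadSet, chrom: str, ref: np.ndarray, alt: np.ndarray) -> None:
    """Write observations as minimal BX-tagged SAM records (1 bp alignments
    at the SNP positions; the observation model carries no other bases)."""
    contig_len = int(reads.snp_positions[-1]) + _CONTIG_PAD
    header = {"HD": {"VN": "1.6", "SO": "coordinate"}, "SQ": [{"SN": chrom, "LN": contig_len}]}
    order = np.argsort(reads.snp_index, kind="stable")
    with pysam.AlignmentFile(str(path), "w", header=header) as sam:
        for n, k in enumerate(order):
            s = int(reads.snp_index[k])
            rec = pysam.AlignedSegment(sam.header)
            rec.query_name = f"obs{n}"
            rec.reference_id = 0
            rec.reference_start = int(reads.snp_positions[s])
            rec.mapping_quality = 60
            rec.cigarstring = "1M"
            rec.query_sequence = str(alt[s] if reads.allele[k] == 1 else ref[s])
            rec.query_qualities = pysam.qualitystring_to_array("I")
            rec.set_tag("BX", f"BC{int(reads.barcode[k])}")
            sam.write(rec)


def read_barcoded_sam(path, snp_positions: np.ndarray, ref: np.ndarray, alt: np.ndarray) -> BarcodedReadSet:
    """Extract barcoded allele observations from a BX-tagged SAM/BAM.

    For every aligned read carrying a BX tag, the aligned base at each SNP
    position it covers is mapped to ref/alt; other bases are ignored.
    """
    pos_to_idx = {int(p): i for i, p in enumerate(snp_positions)}
    barcode, snp, allele = [], [], []
    bx_ids: dict[str, int] = {}
    with pysam.AlignmentFile(str(path), "r") as sam:
        for rec in sam:
            if rec.is_unmapped or not rec.has_tag("BX"):
                continue
            bx = rec.get_tag("BX")
            bid = bx_ids.setdefault(bx, len(bx_ids))
            seq = rec.query_sequence
            for qpos, rpos in rec.get_aligned_pairs(matches_only=True):
                i = pos_to_idx.get(rpos)
                if i is None:
                    continue
                base = seq[qpos]
                if base == ref[i]:
                    a = 0
                elif base == alt[i]:
                    a = 1
                else:
                    continue
                barcode.append(bid)
                snp.append(i)
                allele.append(a)
    return BarcodedReadSet(
        snp_positions=np.asarray(snp_positions, dtype=np.int64),
        barcode=np.asarray(barcode, dtype=np.int64),
        snp_index=np.asarray(snp, dtype=np.int32),
        allele=np.asarray(allele, dtype=np.int8),
    )
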