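"""Relative haplotype dosage analysis of maternal plasma cfDNA.

Given the anchored maternal haplotypes and per-SNP plasma allelic depths,
the HapA (mutant-allele) read-fraction series is screened for outliers,
segmented for mean shifts, corrected for fetal recombination by reflecting
the series across confirmed crossovers, and pooled into a single dosage
test: a fraction significantly above 0.5 means the fetus inherited the
mutant haplotype, below 0.5 the wild-type one. The same pooled imbalance
yields a fetal-fraction estimate via the male-fetus chrX dosage relation
phi = f/(2-f).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .changepoint import Segmentation, mbic_penalty, optimal_partition_mean, pelt_mean
from .model import PlasmaCounts
from .phasing import HaplotypePair

__all__ = [
    "FractionSeries",
    "ChangepointResult",
    "RecombinationAdjustment",
    "NIPDReport",
    "fraction_series",
    "remove_outliers",
    "detect_changepoints",
    "adjust_recombination",
    "call_fetal_genotype",
    "estimate_fetal_fraction",
]


@dataclass
class FractionSeries:
    """Ordered per-SNP HapA/HapB depths with a retained-mask.

    ``a`` counts reads carrying the HapA allele, ``b`` the HapB allele;
    ``mask`` marks SNPs retained after outlier screening.
    """

    positions: np.ndarray
    a: np.ndarray
    b: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.positions)
        if not (len(self.a) == len(self.b) == len(self.mask) == n):
            raise ValueError("FractionSeries: array lengths differ")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("FractionSeries: positions must be strictly increasing")

    @property
    def fraction(self) -> np.ndarray:
        return self.a / (self.a + self.b)

    @property
    def n_retained(self) -> int:
        return int(self.mask.sum())

    def retained(self):
        """(positions, a, b, fraction) restricted to retained SNPs."""
        m = self.mask
        return self.positions[m], self.a[m], self.b[m], self.fraction[m]

    def flipped(self) -> "FractionSeries":
        """HapA/HapB label swap: a and b exchanged everywhere."""
        return FractionSeries(self.positions.copy(), self.b.copy(), self.a.copy(), self.mask.copy())


def fraction_series(counts: PlasmaCounts, pair: HaplotypePair) -> FractionSeries:
    """Map plasma ref/alt depths onto HapA/HapB depths at phased SNPs.

    SNPs that are unphased, absent from the plasma table, or have zero depth
    are dropped.
    """
    common, ci, pi = np.intersect1d(counts.positions, pair.positions, return_indices=True)
    if len(common) == 0:
        raise ValueError("fraction_series: plasma SNPs do not intersect phased SNPs")
    hapA = pair.hapA[pi]
    a = np.where(hapA == 1, counts.alt_depth[ci], counts.ref_depth[ci]).astype(np.int64)
    b = np.where(hapA == 1, counts.ref_depth[ci], counts.alt_depth[ci]).astype(np.int64)
    keep = (a + b) > 0
    return FractionSeries(
        positions=common[keep], a=a[keep], b=b[keep], mask=np.ones(int(keep.sum()), dtype=bool)
    )


def remove_outliers(series: FractionSeries, n_sigma: float = 3.0) -> FractionSeries:
    """Single-pass Shewhart individuals-chart screen.

    SNPs whose fraction deviates from the retained-set mean by more than
    ``n_sigma`` sample standard deviations are masked; guards the changepoint
    stage against spikes from duplicated or repetitive sequence.
    """
    if series.n_retained < 10:
        raise ValueError("remove_outliers: need at least 10 retained points")
    f = series.fraction
    m = series.mask
    mean = float(np.mean(f[m]))
    sd = float(np.std(f[m], ddof=1))
    new_mask = m & ~(np.abs(f - mean) > n_sigma * sd)
    return FractionSeries(series.positions.copy(), series.a.copy(), series.b.copy(), new_mask)


@dataclass
class ChangepointResult:
    """Breakpoints over the retained series (indices into the retained
    order), with per-segment mean fractions and sizes."""

    breakpoints: tuple
    segment_means: tuple
    segment_sizes: tuple
    penalty: float

    @property
    def n_breakpoints(self) -> int:
        return len(self.breakpoints)


def detect_changepoints(
    series: FractionSeries,
    penalty: float | str | None = "mbic",
    min_seg: int = 10,
    exhaustive: bool = False,
) -> ChangepointResult:
    """Mean-shift segmentation of the retained fraction series via PELT
    (``exhaustive=True`` runs the unpruned DP instead; both share one
    objective). Zero breakpoints is a legal result."""
    _, _, _, f = series.retained()
    if len(f) < 2 * min_seg:
        raise ValueError("detect_changepoints: retained series shorter than 2*min_seg")
    pen = mbic_penalty(len(f)) if (penalty is None or penalty == "mbic") else float(penalty)
    solver = optimal_partition_mean if exhaustive else pelt_mean
    seg: Segmentation = solver(f, penalty=pen, min_seg=min_seg)
    return ChangepointResult(
        breakpoints=seg.breakpoints,
        segment_means=seg.segment_means,
        segment_sizes=seg.segment_sizes,
        penalty=pen,
    )


@dataclass
class RecombinationAdjustment:
    detected: bool
    confirmed_breakpoints: tuple  # retained-order indices
    confirmed_positions: tuple  # genomic positions (first SNP right of the crossover)
    p_values: tuple


def _two_proportion_z(a1: int, n1: int, a2: int, n2: int) -> float:
    """Two-sided two-sample z-test for equality of proportions."""
    if n1 == 0 or n2 == 0:
        return 1.0
    p1, p2 = a1 / n1, a2 / n2
    pooled = (a1 + a2) / (n1 + n2)
    se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    if se == 0:
        return 1.0
    z = (p1 - p2) / se
    return float(2.0 * stats.norm.sf(abs(z)))


def adjust_recombination(
    series: FractionSeries,
    cps: ChangepointResult,
    alpha: float = 0.01,
    anchor: int = 0,
) -> tuple[FractionSeries, RecombinationAdjustment]:
    """Confirm changepoints as fetal crossovers and reflect across them.

    A breakpoint is a recombination iff its two flanking segment means lie on
    opposite sides of 0.5 *and* a two-sample z-test on the pooled flanking
    counts rejects equality at ``alpha`` (mean drift fails the first rule,
    noise the second). Fractions are reflected (a and b swapped) on every
    segment an odd number of confirmed crossovers away from the segment
    containing retained index ``anchor`` — reconstructing the haplotype the
    fetus carries at the anchor (the mutation locus in the pipeline; the
    default anchors at the first SNP).
    """
    pos_r, a_r, b_r, _ = series.retained()
    n = len(pos_r)
    edges = [0, *cps.breakpoints, n]
    means = cps.segment_means
    confirmed, pvals, conf_pos = [], [], []
    for k, bp in enumerate(cps.breakpoints):
        left = (means[k] - 0.5, means[k + 1] - 0.5)
        if left[0] * left[1] >= 0:
            continue  # same side of 0.5: drift, not recombination
        s0, s1, s2 = edges[k], edges[k + 1], edges[k + 2]
        p = _two_proportion_z(
            int(a_r[s0:s1].sum()),
            int((a_r[s0:s1] + b_r[s0:s1]).sum()),
            int(a_r[s1:s2].sum()),
            int((a_r[s1:s2] + b_r[s1:s2]).sum()),
        )
        if p < alpha:
            confirmed.append(int(bp))
            pvals.append(p)
            conf_pos.append(int(pos_r[bp]))
    if not confirmed:
        return series, RecombinationAdjustment(False, (), (), ())

    # crossover parity relative to the anchor's segment
    anchor = int(np.clip(anchor, 0, n - 1))
    parity_r = np.zeros(n, dtype=np.int64)
    for bp in confirmed:
        parity_r[bp:] += 1
    parity_r = (parity_r - parity_r[anchor]) % 2
    flip_r = parity_r == 1
    # scatter the retained-order flip back onto the full series
    flip_full = np.zeros(len(series.positions), dtype=bool)
    flip_full[np.flatnonzero(series.mask)] = flip_r
    new_a = np.where(flip_full, series.b, series.a).astype(np.int64)
    new_b = np.where(flip_full, series.a, series.b).astype(np.int64)
    adjusted = FractionSeries(series.positions.copy(), new_a, new_b, series.mask.copy())
    return adjusted, RecombinationAdjustment(
        True, tuple(confirmed), tuple(conf_pos), tuple(pvals)
    )


@dataclass
class NIPDReport:
    """Final dosage call for one plasma draw."""

    call: str  # mutant_inherited / wildtype_inherited / inconclusive
    mean_hapA_fraction: float
    p_value: float
    alpha: float
    recombination_detected: bool
    recombination_positions: tuple
    fetal_fraction: float
    fetal_fraction_ci: tuple
    n_snps_used: int
    n_outliers_removed: int
    mean_depth: float
    changepoints: tuple = ()
    segment_means: tuple = ()

    def __post_init__(self) -> None:
        if self.call == "mutant_inherited" and not self.mean_hapA_fraction > 0.5:
            raise ValueError("NIPDReport: mutant_inherited requires mean fraction > 0.5")
        if self.call == "wildtype_inherited" and not self.mean_hapA_fraction < 0.5:
            raise ValueError("NIPDReport: wildtype_inherited requires mean fraction < 0.5")

    def to_dict(self) -> dict:
        return {
            "call": self.call,
            "mean_hapA_fraction": self.mean_hapA_fraction,
            "p_value": self.p_value,
            "alpha": self.alpha,
            "recombination_detected": self.recombination_detected,
            "recombination_positions": list(self.recombination_positions),
            "fetal_fraction": self.fetal_fraction,
            "fetal_fraction_ci": list(self.fetal_fraction_ci),
            "qc": {
                "n_snps_used": self.n_snps_used,
                "n_outliers_removed": self.n_outliers_removed,
                "mean_depth": self.mean_depth,
            },
            "changepoints": list(self.changepoints),
            "segment_means": list(self.segment_means),
        }


def estimate_fetal_fraction(
    series: FractionSeries, n_boot: int = 200, seed: int = 0
) -> tuple[float, tuple]:
    """Fetal fraction from the pooled chrX dosage imbalance.

    With a male fetus, the pooled HapA fraction is 0.5 +/- phi/2 where phi is
    the fetal share of chrX reads, so phi_hat = |2*F - 1| and, inverting
    phi = f/(2-f), f_hat = 2*phi_hat/(1+phi_hat). A percentile bootstrap over
    SNPs gives the confidence interval.
    """
    _, a_r, b_r, _ = series.retained()
    A, B = int(a_r.sum()), int(b_r.sum())
    if A + B == 0:
        raise ValueError("estimate_fetal_fraction: zero pooled depth")

    def f_hat(a: np.ndarray, b: np.ndarray) -> float:
        phi = abs(2.0 * a.sum() / (a.sum() + b.sum()) - 1.0)
        return 2.0 * phi / (1.0 + phi)

    est = f_hat(a_r, b_r)
    rng = np.random.default_rng(seed)
    n = len(a_r)
    boots = np.empty(n_boot)
    for k in range(n_boot):
        idx = rng.integers(0, n, size=n)
        boots[k] = f_hat(a_r[idx], b_r[idx])
    ci = (float(np.percentile(boots, 2.5)), float(np.percentile(boots, 97.5)))
    return float(est), ci


def call_fetal_genotype(
    series: FractionSeries,
    alpha: float = 0.01,
    adjustment: Optional[RecombinationAdjustment] = None,
    cps: Optional[ChangepointResult] = None,
    n_outliers_removed: int = 0,
    ff_seed: int = 0,
) -> NIPDReport:
    """Pooled dosage call on a (post-adjustment) fraction series.

    All retained counts are pooled and tested against 0.5 with a two-sided
    exact binomial test; a rejection at ``alpha`` calls the haplotype on the
    heavy side, otherwise the draw is inconclusive.
    """
    _, a_r, b_r, _ = series.retained()
    A, B = int(a_r.sum()), int(b_r.sum())
    if A + B == 0:
        raise ValueError("call_fetal_genotype: zero pooled depth")
    frac = A / (A + B)
    p = float(stats.binomtest(A, A + B, 0.5).pvalue)
    if p < alpha and frac > 0.5:
        call = "mutant_inherited"
    elif p < alpha and frac < 0.5:
        call = "wildtype_inherited"
    else:
        call = "inconclusive"
    ff, ff_ci = estimate_fetal_fraction(series, seed=ff_seed)
    return NIPDReport(
        call=call,
        mean_hapA_fraction=float(frac),
        p_value=p,
        alpha=alpha,
        recombination_detected=bool(adjustment.detected) if adjustment else False,
        recombination_positions=tuple(adjustment.confirmed_positions) if adjustment else (),
        fetal_fraction=ff,
        fetal_fraction_ci=ff_ci,
        n_snps_used=int(len(a_r)),
        n_outliers_removed=int(n_outliers_removed),
        mean_depth=float(np.mean(a_r + b_r)),
        changepoints=tuple(cps.breakpoints) if cps else (),
        segment_means=tuple(cps.segment_means) if cps else (),
    )
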