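"""Dosage analysis: fraction series, outlier screen, recombination
adjustment, genotype call, fetal-fraction estimation."""

import numpy as np
import pytest
from scipy import stats

from hapdose.model import PlasmaCounts, PlasmaSpec, RegionSpec, SVMutation
from hapdose.phasing import HaplotypePair, pair_from_truth
from hapdose.rhdo import (
    FractionSeries,
    adjust_recombination,
    call_fetal_genotype,
    detect_changepoints,
    estimate_fetal_fraction,
    fraction_series,
    remove_outliers,
)
from hapdose.simulate import simulate_diplotype, simulate_plasma


@pytest.fixture(scope="module")
def diplo850():
    return simulate_diplotype(
        RegionSpec("chrX", 0, 2_200_000, 850), SVMutation("point", 1_100_000, 1_100_001), seed=21
    )


def _series(a, b, positions=None):
    a = np.asarray(a, dtype=np.int64)
    b = np.asarray(b, dtype=np.int64)
    if positions is None:
        positions = 100 * (1 + np.arange(len(a), dtype=np.int64))
    return FractionSeries(positions, a, b, np.ones(len(a), dtype=bool))


class TestFractionSeries:
    def test_simple_fraction(self):
        s = _series([6], [4] )
        assert s.fraction[0] == pytest.approx(0.6)

    def test_label_swap_mirrors_fractions(self, diplo850):
        counts = simulate_plasma(diplo850, PlasmaSpec(0.06, diplo850.mutation_hap), seed=1)
        pair = pair_from_truth(diplo850)
        s = fraction_series(counts, pair)
        flipped_pair = HaplotypePair(
            snp_indices=pair.snp_indices, positions=pair.positions, hapA=pair.hapB,
            n_snps_total=pair.n_snps_total, unphased_snps=pair.unphased_snps, anchor_evidence=0,
        )
        s2 = fraction_series(counts, flipped_pair)
        assert np.allclose(s2.fraction, 1 - s.fraction)

    def test_simulated_mean_matches_mixture_accounting(self, diplo850):
        """f = 9.25%, HapA transmitted: mean fraction within 3 SE of 0.5242."""
        counts = simulate_plasma(diplo850, PlasmaSpec(0.0925, diplo850.mutation_hap), seed=2)
        s = fraction_series(counts, pair_from_truth(diplo850))
        se = np.sqrt(0.25 / (850 * 200))
        assert np.mean(s.fraction) == pytest.approx(0.52424, abs=3 * se)

    def test_unphased_snps_dropped(self, diplo850):
        counts = simulate_plasma(diplo850, PlasmaSpec(0.05, 1), seed=3)
        pair = pair_from_truth(diplo850)
        half = HaplotypePair(
            snp_indices=pair.snp_indices[:400], positions=pair.positions[:400],
            hapA=pair.hapA[:400], n_snps_total=pair.n_snps_total,
            unphased_snps=pair.snp_indices[400:], anchor_evidence=0,
        )
        s = fraction_series(counts, half)
        assert len(s.positions) == 400

    def test_empty_intersection_errors(self, diplo850):
        pair = pair_from_truth(diplo850)
        counts = PlasmaCounts(
            positions=np.array([1, 2, 3], dtype=np.int64),
            ref_depth=np.array([5, 5, 5]), alt_depth=np.array([5, 5, 5]),
        )
        with pytest.raises(ValueError, match="intersect"):
            fraction_series(counts, pair)


class TestOutlierScreen:
    def test_single_spike_masked(self):
        rng = np.random.default_rng(0)
        f = rng.normal(0.52, 0.02, 100).clip(0, 1)
        depth = 1000
        a = np.round(f * depth).astype(np.int64)
        a[40] = 950  # spike at 0.95
        s = _series(a, depth - a)
        out = remove_outliers(s, n_sigma=3.0)
        assert not out.mask[40]
        assert out.mask.sum() >= 98

    def test_constant_series_nothing_masked(self):
        s = _series([52] * 20, [48] * 20)
        out = remove_outliers(s)
        assert out.mask.all()

    def test_infinite_sigma_is_identity(self):
        rng = np.random.default_rng(1)
        a = rng.integers(80, 120, 50)
        s = _series(a, 200 - a)
        out = remove_outliers(s, n_sigma=np.inf)
        assert out.mask.all()

    def test_too_few_points_rejected(self):
        s = _series([5] * 9, [5] * 9)
        with pytest.raises(ValueError, match="at least 10"):
            remove_outliers(s)


class TestChangepoints:
    def test_short_series_rejected(self):
        s = _series([5] * 15, [5] * 15)
        with pytest.raises(ValueError, match="min_seg"):
            detect_changepoints(s, min_seg=10)

    def test_exhaustive_matches_pelt_on_series(self):
        rng = np.random.default_rng(5)
        depth = 200
        f = np.concatenate([np.full(100, 0.524), np.full(100, 0.476)])
        a = rng.binomial(depth, f)
        s = _series(a, depth - a)
        r_pelt = detect_changepoints(s, min_seg=10)
        r_dp = detect_changepoints(s, min_seg=10, exhaustive=True)
        assert r_pelt.breakpoints == r_dp.breakpoints

    def test_crossover_localized_in_most_seeds(self, diplo850):
        """DMD-05-like regime (f = 4.1%, one mid-region crossover): the
        changepoint lands within +/-25 SNPs of truth in >=90% of seeds."""
        hits = 0
        n_seeds = 50
        for seed in range(n_seeds):
            spec = PlasmaSpec(0.041, diplo850.mutation_hap, fetal_recomb_breakpoints=(425,))
            counts = simulate_plasma(diplo850, spec, seed=1000 + seed)
            s = fraction_series(counts, pair_from_truth(diplo850))
            s = remove_outliers(s)
            r = detect_changepoints(s, min_seg=10)
            if len(r.breakpoints) == 1 and abs(r.breakpoints[0] - 425) <= 25:
                hits += 1
        assert hits >= 0.9 * n_seeds


class TestRecombinationAdjustment:
    def _two_segment_series(self, f1, f2, n1=100, n2=100, depth=5000):
        a = np.concatenate([
            np.full(n1, int(f1 * depth), dtype=np.int64),
            np.full(n2, int(f2 * depth), dtype=np.int64),
        ])
        return _series(a, depth - a)

    def test_opposite_side_breakpoint_reflected(self):
        s = self._two_segment_series(0.524, 0.476)
        cps = detect_changepoints(s, min_seg=10)
        assert cps.breakpoints == (100,)
        adj, r = adjust_recombination(s, cps, alpha=0.01)
        assert r.detected
        assert np.allclose(adj.fraction, 0.524, atol=1e-9)

    def test_same_side_shift_is_drift_not_recombination(self):
        s = self._two_segment_series(0.53, 0.51)
        cps = detect_changepoints(s, min_seg=10)
        adj, r = adjust_recombination(s, cps, alpha=0.01)
        assert not r.detected
        assert np.array_equal(adj.a, s.a)

    def test_double_crossover_flips_middle_once(self):
        depth = 5000
        a = np.concatenate([
            np.full(80, int(0.524 * depth)), np.full(80, int(0.476 * depth)),
            np.full(80, int(0.524 * depth)),
        ]).astype(np.int64)
        s = _series(a, depth - a)
        cps = detect_changepoints(s, min_seg=10)
        assert cps.breakpoints == (80, 160)
        adj, r = adjust_recombination(s, cps, alpha=0.01)
        assert r.detected and len(r.confirmed_breakpoints) == 2
        assert np.allclose(adj.fraction, 0.524, atol=1e-9)

    def test_anchor_in_second_segment_orients_series_there(self):
        s = self._two_segment_series(0.524, 0.476)
        cps = detect_changepoints(s, min_seg=10)
        adj, r = adjust_recombination(s, cps, alpha=0.01, anchor=150)
        assert np.allclose(adj.fraction, 0.476, atol=1e-9)

    def test_idempotent(self):
        s = self._two_segment_series(0.524, 0.476)
        cps = detect_changepoints(s, min_seg=10)
        adj, _ = adjust_recombination(s, cps, alpha=0.01)
        cps2 = detect_changepoints(adj, min_seg=10)
        adj2, r2 = adjust_recombination(adj, cps2, alpha=0.01)
        assert not r2.detected
        assert np.array_equal(adj2.a, adj.a)


class TestGenotypeCall:
    def test_clear_imbalance_calls_mutant(self):
        s = _series([9000], [8000])
        rep = call_fetal_genotype(s, alpha=0.01)
        assert rep.call == "mutant_inherited"
        assert rep.p_value == pytest.approx(
            float(stats.binomtest(9000, 17000, 0.5).pvalue)
        )
        assert rep.p_value < 1e-10

    def test_balance_is_inconclusive(self):
        s = _series([500] * 20, [500] * 20)
        rep = call_fetal_genotype(s, alpha=0.01)
        assert rep.call == "inconclusive"
        assert rep.p_value == pytest.approx(1.0)

    def test_zero_depth_rejected(self):
        s = FractionSeries(
            np.array([1, 2]), np.array([1, 1]), np.array([1, 1]), np.zeros(2, dtype=bool)
        )
        with pytest.raises(ValueError, match="zero pooled depth"):
            call_fetal_genotype(s)


class TestFetalFraction:
    def test_balanced_counts_give_zero(self):
        s = _series([100] * 50, [100] * 50)
        est, _ = estimate_fetal_fraction(s)
        assert est == 0.0

    def test_pure_fetal_boundary(self):
        s = _series([100] * 10, [0] * 10)
        est, _ = estimate_fetal_fraction(s)
        assert est == 1.0

    def test_recovery_at_low_fraction(self, diplo850):
        ests = []
        for seed in range(5):
            counts = simulate_plasma(diplo850, PlasmaSpec(0.041, diplo850.mutation_hap), seed=seed)
            s = fraction_series(counts, pair_from_truth(diplo850))
            ests.append(estimate_fetal_fraction(s)[0])
        assert np.mean(ests) == pytest.approx(0.041, abs=0.01)

    def test_ci_covers_estimate(self, diplo850):
        counts = simulate_plasma(diplo850, PlasmaSpec(0.06, 1), seed=9)
        s = fraction_series(counts, pair_from_truth(diplo850))
        est, (lo, hi) = estimate_fetal_fraction(s, seed=4)
        assert lo <= est <= hi


class TestLabelFlipAntisymmetry:
    def test_whole_stage_antisymmetry(self, diplo850):
        """Relabeling HapA<->HapB mirrors every fraction, flips the call,
        and leaves the fetal-fraction estimate and breakpoints unchanged."""
        spec = PlasmaSpec(0.0507, diplo850.mutation_hap, fetal_recomb_breakpoints=(425,))
        counts = simulate_plasma(diplo850, spec, seed=77)
        pair = pair_from_truth(diplo850)
        flipped = HaplotypePair(
            snp_indices=pair.snp_indices, positions=pair.positions, hapA=pair.hapB,
            n_snps_total=pair.n_snps_total, unphased_snps=pair.unphased_snps, anchor_evidence=0,
        )
        reports = []
        for p in (pair, flipped):
            s = fraction_series(counts, p)
            s = remove_outliers(s)
            cps = detect_changepoints(s)
            adj, r = adjust_recombination(s, cps, alpha=0.01)
            reports.append((s, cps, call_fetal_genotype(adj, alpha=0.01, adjustment=r, cps=cps)))
        (s1, c1, r1), (s2, c2, r2) = reports
        assert np.allclose(s1.fraction, 1 - s2.fraction)
        assert c1.breakpoints == c2.breakpoints
        assert {r1.call, r2.call} == {"mutant_inherited", "wildtype_inherited"}
        assert r1.fetal_fraction == pytest.approx(r2.fetal_fraction)
        assert r1.p_value == pytest.approx(r2.p_value)
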