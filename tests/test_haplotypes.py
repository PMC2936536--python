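from itertools import combinations

import numpy as np
import pytest
from scipy.stats import gamma as gamma_dist

from sweepscan.data_model import MISSING
from sweepscan.haplotypes import (CoreHaplotype, WglrhConfig, bh_fdr,
                                  cnp_rehh_at_boundary, define_cores,
                                  derived_allele_frequency, ehh, ehh_curve,
                                  fit_gamma_mle, gamma_tail_p,
                                  passes_derived_filter, rehh, wglrh_scan)
from conftest import make_hap_panel, make_markers


def ehh_pair_oracle(core_rows, extension):
    """EHH by exhaustive enumeration of carrier pairs."""
    rows = [tuple(extension[i]) for i in core_rows]
    n = len(rows)
    if n < 2:
        return float("nan")
    same = sum(1 for a, b in combinations(rows, 2) if a == b)
    return same / (n * (n - 1) / 2)


class TestDerivedAlleleFrequency:
    def test_strictly_above_threshold_passes(self):
        assert passes_derived_filter(0.86)

    def test_exactly_at_threshold_fails(self):
        assert not passes_derived_filter(0.85)

    def test_unknown_ancestral_excluded(self):
        markers = make_markers([100], ancestral=["unknown"])
        panel = make_hap_panel("a", [[1], [1], [0], [1]])
        assert np.isnan(derived_allele_frequency(panel, 0, markers))

    def test_ancestral_alt_flips_frequency(self):
        markers = make_markers([100], ancestral=["alt"])
        panel = make_hap_panel("a", [[1], [1], [0], [1]])
        assert derived_allele_frequency(panel, 0, markers) \
            == pytest.approx(0.25)


class TestDefineCores:
    def test_identical_haplotypes_single_core(self):
        markers = make_markers(range(100, 800, 100))
        panel = make_hap_panel("a", np.zeros((4, 7), dtype=np.int8))
        cores = define_cores(panel, markers, core_size=7)
        assert len(cores) == 1
        assert cores[0].frequency == pytest.approx(1.0)

    def test_min_carriers_drops_rare_strings(self):
        markers = make_markers(range(100, 800, 100))
        haps = np.zeros((4, 7), dtype=np.int8)
        haps[3, 0] = 1  # one divergent row
        panel = make_hap_panel("a", haps)
        cores = define_cores(panel, markers, core_size=7, min_carriers=3)
        assert len(cores) == 1
        assert cores[0].n_carriers == 3

    def test_too_few_markers_empty(self):
        markers = make_markers(range(100, 700, 100))  # 6 markers
        panel = make_hap_panel("a", np.zeros((4, 6), dtype=np.int8))
        assert define_cores(panel, markers, core_size=7) == []

    def test_frequencies_sum_to_one_per_span(self):
        rng = np.random.default_rng(0)
        markers = make_markers(range(100, 1500, 100))
        haps = rng.integers(0, 2, size=(20, 14)).astype(np.int8)
        cores = define_cores(make_hap_panel("a", haps), markers,
                             core_size=7, min_carriers=1)
        spans = {}
        for c in cores:
            spans.setdefault((c.start_index, c.end_index), []).append(c)
        for span_cores in spans.values():
            assert sum(c.frequency for c in span_cores) \
                == pytest.approx(1.0)
            carriers = [set(c.carriers.tolist()) for c in span_cores]
            for a, b in combinations(carriers, 2):
                assert not (a & b)

    def test_spans_do_not_cross_chromosomes(self):
        markers = make_markers(range(100, 1500, 100))
        markers.chrom = np.asarray(["chr1"] * 7 + ["chr2"] * 7, dtype=object)
        panel = make_hap_panel("a", np.zeros((4, 14), dtype=np.int8))
        cores = define_cores(panel, markers, core_size=7)
        assert len(cores) == 2
        assert {c.chrom for c in cores} == {"chr1", "chr2"}


class TestEhh:
    def _core(self, carriers, start=3, end=3):
        return CoreHaplotype("chr1", start, end, (0,),
                             np.asarray(carriers), 1.0)

    def test_identical_carriers_ehh_one(self):
        markers = make_markers(range(100, 800, 100))
        panel = make_hap_panel("a", np.zeros((4, 7), dtype=np.int8))
        assert ehh(self._core([0, 1, 2, 3]), panel, markers, 300) == 1.0

    def test_immediate_split_ehh_zero(self):
        markers = make_markers(range(100, 800, 100))
        haps = np.zeros((2, 7), dtype=np.int8)
        haps[1, 4] = 1  # first flanking marker differs
        panel = make_hap_panel("a", haps)
        assert ehh(self._core([0, 1]), panel, markers, 300) == 0.0

    def test_two_plus_two_split(self):
        markers = make_markers(range(100, 800, 100))
        haps = np.zeros((4, 7), dtype=np.int8)
        haps[2:, 4] = 1
        panel = make_hap_panel("a", haps)
        assert ehh(self._core([0, 1, 2, 3]), panel, markers, 300) \
            == pytest.approx(2 / 6)

    def test_distance_zero_is_one(self):
        markers = make_markers(range(100, 800, 100))
        rng = np.random.default_rng(1)
        haps = rng.integers(0, 2, (6, 7)).astype(np.int8)
        haps[:, 3] = 0
        panel = make_hap_panel("a", haps)
        assert ehh(self._core(list(range(6))), panel, markers, 0) == 1.0

    def test_single_carrier_undefined(self):
        markers = make_markers(range(100, 800, 100))
        panel = make_hap_panel("a", np.zeros((2, 7), dtype=np.int8))
        assert np.isnan(ehh(self._core([0]), panel, markers, 100))

    def test_monotone_non_increasing(self):
        rng = np.random.default_rng(3)
        markers = make_markers(range(100, 5000, 100))
        haps = rng.integers(0, 2, (12, 49)).astype(np.int8)
        haps[:, 24] = 0
        panel = make_hap_panel("a", haps)
        core = CoreHaplotype("chr1", 24, 24, (0,), np.arange(12), 1.0)
        curve = ehh_curve(core, panel, markers, range(0, 2500, 100))
        vals = curve.values[np.isfinite(curve.values)]
        assert np.all(np.diff(vals) <= 1e-12)

    def test_pair_enumeration_oracle(self):
        rng = np.random.default_rng(5)
        markers = make_markers(range(100, 2200, 100))
        for _ in range(500):
            n_hap = int(rng.integers(4, 13)) // 2 * 2
            haps = rng.integers(0, 2, (n_hap, 21)).astype(np.int8)
            haps[:, 10] = 0
            panel = make_hap_panel("a", haps)
            carriers = np.arange(n_hap)
            core = CoreHaplotype("chr1", 10, 10, (0,), carriers, 1.0)
            dist = int(rng.integers(0, 1200))
            got = ehh(core, panel, markers, dist)
            lo = 100 * 11 - dist
            hi = 100 * 11 + dist
            cols = [j for j in range(21)
                    if j != 10 and lo <= 100 * (j + 1) <= hi]
            expected = ehh_pair_oracle(carriers, haps[:, cols])
            assert got == pytest.approx(expected, abs=1e-12)

    def test_missing_rows_dropped(self):
        markers = make_markers(range(100, 800, 100))
        haps = np.zeros((4, 7), dtype=np.int8)
        haps[0, 5] = MISSING
        panel = make_hap_panel("a", haps)
        # row 0 dropped in the extension; remaining 3 identical
        assert ehh(self._core([0, 1, 2, 3]), panel, markers, 300) == 1.0


class TestRehh:
    def _setup(self):
        markers = make_markers(range(100, 800, 100))
        haps = np.zeros((8, 7), dtype=np.int8)
        haps[4:, 3] = 1      # two core classes at the central marker
        haps[4:6, 5] = 1     # the 1-class splits downstream
        panel = make_hap_panel("a", haps)
        c0 = CoreHaplotype("chr1", 3, 3, (0,), np.arange(4), 0.5)
        c1 = CoreHaplotype("chr1", 3, 3, (1,), np.arange(4, 8), 0.5)
        return markers, panel, c0, c1

    def test_arithmetic(self):
        markers, panel, c0, c1 = self._setup()
        e0 = ehh(c0, panel, markers, 300)
        e1 = ehh(c1, panel, markers, 300)
        assert e0 == 1.0
        assert e1 == pytest.approx(2 / 6)
        assert rehh(c0, [c0, c1], panel, markers, 300) \
            == pytest.approx(e0 / e1)

    def test_equal_ehh_gives_one(self):
        markers = make_markers(range(100, 800, 100))
        haps = np.zeros((8, 7), dtype=np.int8)
        haps[4:, 3] = 1
        panel = make_hap_panel("a", haps)
        c0 = CoreHaplotype("chr1", 3, 3, (0,), np.arange(4), 0.5)
        c1 = CoreHaplotype("chr1", 3, 3, (1,), np.arange(4, 8), 0.5)
        assert rehh(c0, [c0, c1], panel, markers, 300) == pytest.approx(1.0)

    def test_single_core_undefined(self):
        markers, panel, c0, _ = self._setup()
        assert np.isnan(rehh(c0, [c0], panel, markers, 300))

    def test_zero_competitor_ehh_undefined(self):
        markers = make_markers(range(100, 800, 100))
        haps = np.zeros((6, 7), dtype=np.int8)
        haps[2:, 3] = 1
        haps[2, 4] = 1
        haps[3, 5] = 1  # the four 1-carriers are pairwise distinct
        haps[4, 6] = 1
        panel = make_hap_panel("a", haps)
        c0 = CoreHaplotype("chr1", 3, 3, (0,), np.arange(2), 1 / 3)
        c1 = CoreHaplotype("chr1", 3, 3, (1,), np.arange(2, 6), 2 / 3)
        assert np.isnan(rehh(c0, [c0, c1], panel, markers, 300))


class TestGammaMle:
    @pytest.mark.parametrize("seed", range(10))
    def test_parameter_recovery(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.gamma(shape=2.0, scale=3.0, size=10_000)
        shape, scale = fit_gamma_mle(x)
        assert shape == pytest.approx(2.0, rel=0.05)
        assert scale == pytest.approx(3.0, rel=0.05)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            fit_gamma_mle(np.full(100, 2.5))

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            fit_gamma_mle(np.array([1.0, 0.0, 2.0]))

    def test_mle_is_local_optimum(self):
        rng = np.random.default_rng(42)
        x = rng.gamma(shape=1.3, scale=0.7, size=2_000)
        shape, scale = fit_gamma_mle(x)

        def loglik(k, th):
            return gamma_dist.logpdf(x, k, scale=th).sum()

        best = loglik(shape, scale)
        for dk in (0.9, 1.1):
            for dt in (0.9, 1.1):
                assert best >= loglik(shape * dk, scale * dt)

    def test_tail_p_in_unit_interval(self):
        p = gamma_tail_p(1e9, 2.0, 1.0)
        assert 0 < p <= 1


def bh_oracle(p, q):
    """Direct step-up transcription: find the largest i with
    p_(i) <= i*q/m and reject everything at or below p_(i)."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    k = 0
    for rank, i in enumerate(order, 1):
        if p[i] <= rank * q / m:
            k = rank
    if k == 0:
        return [False] * m
    threshold = p[order[k - 1]]
    return [pi <= threshold for pi in p]


class TestBhFdr:
    def test_worked_example(self):
        flags = bh_fdr([0.01, 0.02, 0.04, 0.5], q=0.05)
        assert flags.tolist() == [True, True, False, False]

    def test_all_ones_nothing_rejected(self):
        assert not bh_fdr([1.0, 1.0, 1.0]).any()

    def test_boundary_single_rejection(self):
        m = 10
        p = [0.05 / m] + [1.0] * (m - 1)
        assert bh_fdr(p, q=0.05)[0]

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 0.0])
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    def test_step_up_oracle_random_vectors(self):
        rng = np.random.default_rng(13)
        for _ in range(1000):
            m = int(rng.integers(1, 51))
            p = rng.random(m).clip(1e-12, 1.0)
            if rng.random() < 0.3:
                p[: m // 2] /= 100  # seed some small p-values
            got = bh_fdr(p, q=0.05)
            assert got.tolist() == bh_oracle(p.tolist(), 0.05)


class TestCnpBoundary:
    def _markers(self):
        return make_markers(range(1000, 22000, 1000))

    def test_fixed_cnp_single_core_undefined_rehh(self):
        markers = self._markers()
        haps = np.zeros((6, 21), dtype=np.int8)
        panel = make_hap_panel("a", haps)
        out = cnp_rehh_at_boundary(10, panel, markers, distance=5000)
        assert len(out) == 1
        assert np.isnan(out[0].rehh)

    def test_balanced_cnp_identical_flanks(self):
        markers = self._markers()
        haps = np.zeros((8, 21), dtype=np.int8)
        haps[4:, 10] = 1
        panel = make_hap_panel("a", haps)
        out = cnp_rehh_at_boundary(10, panel, markers, distance=5000)
        assert len(out) == 2
        for r in out:
            assert r.ehh == 1.0
            assert r.rehh == pytest.approx(1.0)

    def test_markers_inside_cnp_span_excluded(self):
        markers = self._markers()
        haps = np.zeros((8, 21), dtype=np.int8)
        haps[4:, 10] = 1
        # marker index 11 (pos 12,000) differs among carriers of allele 1
        haps[4:6, 11] = 1
        panel = make_hap_panel("a", haps)
        with_span = cnp_rehh_at_boundary(10, panel, markers, distance=5000,
                                         cnp_span=(11_500, 13_500))
        without = cnp_rehh_at_boundary(10, panel, markers, distance=5000)
        one_with = [r for r in with_span if r.core.alleles == (1,)][0]
        one_without = [r for r in without if r.core.alleles == (1,)][0]
        assert one_with.ehh == 1.0
        assert one_without.ehh < 1.0


class TestWglrhScan:
    def test_no_ancestral_states_empty_significant(self):
        rng = np.random.default_rng(2)
        markers = make_markers(range(1000, 43000, 1000),
                               ancestral=["unknown"] * 42)
        haps = rng.integers(0, 2, (20, 42)).astype(np.int8)
        panel = make_hap_panel("a", haps)
        with pytest.warns(UserWarning, match="ancestral"):
            res = wglrh_scan(panel, markers, WglrhConfig(distance=5000))
        assert not any(r.significant for r in res)


class TestWglrhStochastic:
    """End-to-end scan behavior on simulated panels.

    The scan settings mirror the synthetic data scale: the evaluation
    distance, frequency-bin width and bin occupancy are matched to the
    simulated extent of linkage disequilibrium rather than the defaults
    used for dense real-genome panels.
    """

    SCAN = WglrhConfig(distance=100_000, bin_width=0.2, min_per_bin=15)

    def test_neutral_rejection_fraction_calibrated(self):
        from sweepscan.simulate import (SimulationConfig,
                                        simulate_three_populations)
        tested = rejected = 0
        for seed in range(10):
            cfg = SimulationConfig(seed=seed, s=0.0, chrom_length=2_000_000,
                                   missing_rate=0.0, split_highland=60,
                                   split_outgroup=80, mutation_rate=1e-5,
                                   recomb_rate=1e-7)
            markers, _, hap, _ = simulate_three_populations(cfg)
            res = wglrh_scan(hap[0], markers, self.SCAN)
            cores = [r for r in res if np.isfinite(r.p) and r.derived_pass]
            tested += len(cores)
            rejected += sum(r.fdr_flag for r in cores)
        assert tested > 100
        assert rejected / tested <= 2 * self.SCAN.fdr_q

    def test_hard_sweep_cores_in_extreme_tail(self):
        # A de-novo sweep held between the derived filter (0.85) and
        # fixation; sweep-region cores must dominate the small-p tail.
        from sweepscan.simulate import (SimulationConfig,
                                        simulate_three_populations)
        n = 5
        enriched = strong = 0
        for seed in range(n):
            cfg = SimulationConfig(
                seed=seed, s=0.3, chrom_length=8_000_000, missing_rate=0.0,
                split_highland=60, split_outgroup=80,
                sweep_origin="de_novo", sweep_duration=40,
                sweep_min_final=0.86, sweep_max_final=0.95,
                max_retries=300, mutation_rate=1e-5, recomb_rate=1e-7)
            markers, _, hap, truth = simulate_three_populations(cfg)
            res = wglrh_scan(hap[0], markers, self.SCAN)
            cores = [r for r in res if np.isfinite(r.p) and r.derived_pass]
            near = [r for r in cores if abs(
                (markers.pos[r.core.start_index]
                 + markers.pos[r.core.end_index]) / 2
                - truth.focal_position) < 300_000]
            assert cores and near
            p_near = min(r.p for r in near)
            enriched += p_near <= np.quantile([r.p for r in cores], 0.10)
            strong += p_near < 0.05
        assert enriched >= n - 1
        assert strong >= n - 1
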