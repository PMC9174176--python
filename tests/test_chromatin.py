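import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pluroadmap import (
    AccessibilityCalls,
    CadParams,
    DynamicsLabel,
    GenomeModel,
    OpenThreshold,
    OpenThresholdCalibrator,
    Region,
    RegionSet,
    StageMap,
    ValueMatrix,
    assign_promoters,
    binarize_accessibility,
    calibrate_open_threshold,
    classify_dynamics,
    compute_rpkm,
    merge_replicates,
    shuffle_background,
    simulate_cad_dataset,
    toy_genome,
)
from pluroadmap.simulate import replicate_stage_map
from conftest import brute_force_overlaps, brute_force_threshold


def _vm(arr, scale="RPKM", prefix="f"):
    arr = np.atleast_2d(np.asarray(arr, float))
    return ValueMatrix(
        pd.DataFrame(arr, index=[f"{prefix}{i}" for i in range(arr.shape[0])],
                     columns=[f"s{j}" for j in range(arr.shape[1])]),
        scale,
    )


class TestRpkm:
    def test_direct_arithmetic(self):
        counts = _vm([[100.0]], "COUNT")
        out = compute_rpkm(counts, {"f0": 1000}, {"s0": 1e7})
        assert out.values[0, 0] == pytest.approx(10.0)

    def test_zero_count_is_zero(self):
        out = compute_rpkm(_vm([[0.0]], "COUNT"), {"f0": 500}, {"s0": 1e6})
        assert out.values[0, 0] == 0.0

    def test_doubling_library_halves_rpkm(self):
        counts = _vm([[10.0, 10.0], [3.0, 3.0]], "COUNT")
        a = compute_rpkm(counts, {"f0": 100, "f1": 700}, {"s0": 1e6, "s1": 1e6})
        b = compute_rpkm(counts, {"f0": 100, "f1": 700}, {"s0": 2e6, "s1": 2e6})
        assert np.allclose(b.values, a.values / 2)

    def test_zero_library_errors(self):
        with pytest.raises(ValueError, match="library size"):
            compute_rpkm(_vm([[1.0]], "COUNT"), {"f0": 100}, {"s0": 0.0})


class TestShuffleBackground:
    def test_single_peak_small_chromosome(self):
        genome = GenomeModel((("chr1", 10_000),))
        peaks = RegionSet([Region("chr1", 4000, 4100, "p1")], genome)
        bg = shuffle_background(peaks, genome, seed=0)
        assert len(bg) == 1
        assert bg[0].length == 100
        assert not bg[0].overlaps(peaks[0])

    def test_counts_lengths_and_chromosomes_conserved(self, genome):
        rng = np.random.default_rng(5)
        peaks = []
        cursor = 0
        for i in range(100):
            cursor += int(rng.integers(500, 2000))
            peaks.append(Region("chr1", cursor, cursor + int(rng.integers(50, 400)), f"p{i}"))
            cursor = peaks[-1].end
        rs = RegionSet(peaks, genome)
        bg = shuffle_background(rs, genome, seed=1)
        assert len(bg) == len(rs)
        assert [r.length for r in bg] == [r.length for r in rs]
        assert all(b.chrom == p.chrom for b, p in zip(bg, rs))

    def test_zero_overlaps_vs_brute_force(self, genome):
        rng = np.random.default_rng(7)
        peaks, cursor = [], 0
        for i in range(200):
            cursor += int(rng.integers(200, 1500))
            peaks.append(Region("chr1", cursor, cursor + 200, f"p{i}"))
            cursor = peaks[-1].end
        rs = RegionSet(peaks, genome)
        bg = shuffle_background(rs, genome, seed=3)
        assert brute_force_overlaps(bg, rs) == 0
        assert brute_force_overlaps(bg, bg) == len(bg)  # self-overlaps only

    def test_deterministic_under_seed(self, genome):
        peaks = RegionSet([Region("chr1", 1000, 1200, "p1"),
                           Region("chr2", 5000, 5100, "p2")], genome)
        a = shuffle_background(peaks, genome, seed=11)
        b = shuffle_background(peaks, genome, seed=11)
        assert [(r.chrom, r.start, r.end) for r in a] == [(r.chrom, r.start, r.end) for r in b]

    def test_impossible_placement_errors(self):
        genome = GenomeModel((("chr1", 300),))
        peaks = RegionSet([Region("chr1", 0, 280, "p1")], genome)
        with pytest.raises(RuntimeError, match="p1"):
            shuffle_background(peaks, genome, seed=0, max_attempts=50)


class TestCalibration:
    def test_worked_example(self):
        peaks = _vm([[20.0, 30.0], [40.0, 50.0]])
        bg = _vm([[1.0, 2.0], [3.0, 1.5]])
        t = calibrate_open_threshold(peaks, bg, alpha=0.01)
        assert t.t_star == 20.0
        assert t.efdr_at_t == 0.0

    def test_zero_background_gives_min_peak(self):
        peaks = _vm([[7.0, 3.0]])
        bg = _vm([[0.0, 0.0]])
        t = calibrate_open_threshold(peaks, bg, alpha=0.01)
        assert t.t_star == 3.0

    def test_matches_brute_force_sweep(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            n = int(rng.integers(20, 400))
            peaks = rng.normal(30, 8, n).clip(min=0)
            bg = rng.exponential(2.0, int(rng.integers(20, 400)))
            alpha = float(rng.choice([0.01, 0.05, 0.1]))
            expected = brute_force_threshold(peaks, bg, alpha)
            got = calibrate_open_threshold(
                _vm(peaks.reshape(1, -1)), _vm(bg.reshape(1, -1)), alpha)
            assert (got.t_star, got.efdr_at_t) == expected
            assert got.efdr_at_t <= alpha

    def test_inseparable_signal_errors(self):
        same = _vm([[1.0, 2.0, 3.0, 4.0]])
        with pytest.raises(ValueError, match="eFDR"):
            calibrate_open_threshold(same, same, alpha=0.01)

    def test_estimator_params_round_trip(self):
        est = OpenThresholdCalibrator(alpha=0.05)
        assert est.get_params() == {"alpha": 0.05}
        est.set_params(alpha=0.2)
        assert est.alpha == 0.2


class TestMergeAndBinarize:
    def test_replicate_mean(self):
        vm = _vm([[10.0, 20.0, 1.0], [1.0, 2.0, 6.0]])
        sm = StageMap(("A", "B"), {"s0": "A", "s1": "A", "s2": "B"})
        merged = merge_replicates(vm, sm)
        assert merged.sample_ids == ["A", "B"]
        assert merged.values[0, 0] == pytest.approx(15.0)
        assert merged.values[1, 0] == pytest.approx(1.5)

    def test_three_replicates_mean(self):
        vm = _vm([[1.0, 2.0, 6.0]])
        sm = StageMap(("A",), {"s0": "A", "s1": "A", "s2": "A"})
        assert merge_replicates(vm, sm).values[0, 0] == pytest.approx(3.0)

    def test_single_replicate_identity(self):
        vm = _vm([[4.2, 7.7]])
        sm = StageMap(("A", "B"), {"s0": "A", "s1": "B"})
        assert np.array_equal(merge_replicates(vm, sm).values, vm.values)

    def test_threshold_tie_counts_as_open(self):
        thr = OpenThreshold(14.22, 0.01, 0.0, 10, 10)
        eps = 1e-9
        vm = _vm([[14.22, 14.22 - 1e-6, 14.22 + eps]])
        calls = binarize_accessibility(vm, thr)
        assert calls.calls.tolist() == [[True, False, True]]

    def test_monotone_in_value(self):
        thr = OpenThreshold(5.0, 0.01, 0.0, 10, 10)
        rng = np.random.default_rng(2)
        vals = rng.exponential(5, (30, 4))
        base = binarize_accessibility(_vm(vals), thr).calls
        bumped = binarize_accessibility(_vm(vals + rng.exponential(1, vals.shape)), thr).calls
        assert not (base & ~bumped).any()  # raising values never closes a locus


def _calls(patterns):
    arr = np.array(patterns, bool)
    return AccessibilityCalls(
        region_ids=tuple(f"r{i}" for i in range(arr.shape[0])),
        stages=tuple(f"st{j}" for j in range(arr.shape[1])),
        calls=arr,
    )


class TestClassifyDynamics:
    def test_canonical_patterns(self):
        calls = _calls([[False, False, True, True],
                        [True, True, False, False],
                        [True, True, True, True],
                        [False, False, False, False]])
        labels = classify_dynamics(calls)
        assert [labels[f"r{i}"] for i in range(4)] == [
            DynamicsLabel.CO, DynamicsLabel.OC, DynamicsLabel.PO, DynamicsLabel.PC]

    def test_all_three_stage_patterns_enumerated(self):
        # exhaustive 2^3 enumeration against the single-switch rule
        expected = {
            (0, 0, 0): "PC", (1, 1, 1): "PO",
            (0, 0, 1): "CO", (0, 1, 1): "CO",
            (1, 0, 0): "OC", (1, 1, 0): "OC",
            (0, 1, 0): "COMPLEX", (1, 0, 1): "COMPLEX",
        }
        pats = list(itertools.product([0, 1], repeat=3))
        labels = classify_dynamics(_calls([[bool(b) for b in p] for p in pats]))
        for i, p in enumerate(pats):
            assert labels[f"r{i}"].value == expected[p], p

    @settings(derandomize=True, max_examples=200)
    @given(st.lists(st.booleans(), min_size=2, max_size=8))
    def test_stage_reversal_swaps_co_oc(self, pattern):
        fwd = classify_dynamics(_calls([pattern]))["r0"]
        rev = classify_dynamics(_calls([pattern[::-1]]))["r0"]
        swap = {DynamicsLabel.CO: DynamicsLabel.OC, DynamicsLabel.OC: DynamicsLabel.CO}
        assert rev == swap.get(fwd, fwd)

    def test_single_stage_rejected(self):
        with pytest.raises(ValueError):
            classify_dynamics(_calls([[True]]))


class TestPromoters:
    def test_overlapping_window_assigned(self, genome):
        regions = RegionSet([Region("chr1", 6500, 7200, "pk")], genome)
        pa = assign_promoters(regions, [("GENE", "chr1", 10_000, "+")], halfwidth=3000)
        assert pa.assignment["pk"] == ("GENE",)

    def test_half_open_boundary_not_assigned(self, genome):
        # window [7000, 13000); a peak starting exactly at 13000 misses it
        regions = RegionSet([Region("chr1", 13_000, 14_000, "pk")], genome)
        pa = assign_promoters(regions, [("GENE", "chr1", 10_000, "+")], halfwidth=3000)
        assert pa.assignment["pk"] == ()

    def test_zero_halfwidth_requires_containment(self, genome):
        regions = RegionSet([Region("chr1", 9_000, 10_001, "hit"),
                             Region("chr1", 10_001, 11_000, "miss")], genome)
        pa = assign_promoters(regions, [("GENE", "chr1", 10_000, "+")], halfwidth=0)
        assert pa.assignment["hit"] == ("GENE",)
        assert pa.assignment["miss"] == ()

    def test_window_clipped_at_chromosome_start(self, genome):
        regions = RegionSet([Region("chr1", 0, 100, "pk")], genome)
        pa = assign_promoters(regions, [("G", "chr1", 500, "+")], halfwidth=3000,
                              genome=genome)
        assert pa.assignment["pk"] == ("G",)


class TestCadRecovery:
    def test_planted_labels_recovered(self):
        # three replicates per stage, merged before binarization
        sm = replicate_stage_map(("pESC", "day6", "day8", "day10", "naive"))
        regions, peaks, bg, truth = simulate_cad_dataset(
            toy_genome(), 500, {"CO": 0.25, "OC": 0.25, "PO": 0.25, "PC": 0.25},
            sm, CadParams(), seed=9)
        thr = calibrate_open_threshold(peaks, bg, 0.01)
        merged = merge_replicates(peaks, sm)
        labels = classify_dynamics(binarize_accessibility(merged, thr))
        acc = np.mean([labels[r].value == truth.labels[r] for r in truth.labels])
        assert acc >= 0.99

    def test_noiseless_construction_perfect(self):
        sm = replicate_stage_map(("pESC", "day6", "day8", "day10", "naive"))
        regions, peaks, bg, truth = simulate_cad_dataset(
            toy_genome(), 300, {"CO": 0.5, "OC": 0.5},
            sm, CadParams(sigma_open=0.0), seed=4)
        thr = calibrate_open_threshold(peaks, bg, 0.01)
        merged = merge_replicates(peaks, sm)
        labels = classify_dynamics(binarize_accessibility(merged, thr))
        assert all(labels[r].value == truth.labels[r] for r in truth.labels)
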