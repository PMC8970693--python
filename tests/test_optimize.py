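import itertools

import numpy as np
import pytest

import msfakit as mk
from msfakit.filters import channel_signals
from msfakit.merit import spatial_merit


def _cfg(**kw):
    base = dict(
        n_channels=2,
        wavelength_range=(400, 700),
        bandwidth_range=(30, 30),
        n_random_starts=20,
        seed=3,
    )
    base.update(kw)
    return mk.SpectralSearchConfig(**base)


class TestGradientDescent:
    def test_deterministic_for_fixed_seed(self, recovery_scene):
        cube, amap, lib = recovery_scene
        a = mk.gradient_descent_spectral(_cfg(), cube, amap, lib)
        b = mk.gradient_descent_spectral(_cfg(), cube, amap, lib)
        np.testing.assert_array_equal(a[0].centers, b[0].centers)
        np.testing.assert_array_equal(a[0].bandwidths, b[0].bandwidths)

    def test_refinement_never_worse_than_best_random_start(self, recovery_scene):
        cube, amap, lib = recovery_scene
        bank, trace = mk.gradient_descent_spectral(_cfg(), cube, amap, lib)
        starts = [r.merit for r in trace.records if r.phase == "random-start"]
        assert trace.best().merit <= min(starts)

    def test_descent_trace_is_non_increasing(self, recovery_scene):
        cube, amap, lib = recovery_scene
        _, trace = mk.gradient_descent_spectral(_cfg(), cube, amap, lib)
        for rank in range(5):
            merits = [r.merit for r in trace.records if r.phase == f"descent-{rank}"]
            assert all(a >= b for a, b in zip(merits, merits[1:]))

    def test_too_many_channels_rejected(self, recovery_scene):
        cube, amap, lib = recovery_scene
        cfg = _cfg(n_channels=200)
        with pytest.raises(ValueError, match="grid"):
            mk.gradient_descent_spectral(cfg, cube, amap, lib)


class TestSimulatedAnnealing:
    def test_cold_start_acts_as_hill_climb(self, recovery_scene):
        # with T ~ 0 no worsening move is ever accepted, so the state's
        # merit is non-increasing along the whole trace
        cube, amap, lib = recovery_scene
        anneal = mk.AnnealConfig(
            T_initial=1e-12, T_final=1e-13, T_step=1e-13, seed=5, max_steps=1000
        )
        _, trace = mk.simulated_annealing_spectral(_cfg(), anneal, cube, amap, lib)
        merits = [r.merit for r in trace.records]
        assert len(merits) > 900  # worsening moves were all rejected
        assert all(a >= b - 1e-15 for a, b in zip(merits, merits[1:]))

    def test_flat_landscape_accepts_everything_and_cools(self, vis_axis):
        # a zero scene makes every candidate score identically; equal-merit
        # neighbors are accepted with probability exp(0) = 1, each cooling
        # the system by one step until T_final is reached
        lib = mk.EndmemberLibrary(np.ones((vis_axis.n_bands, 1)), ["x"], vis_axis)
        amap = mk.AbundanceMap(np.ones((3, 3, 1)))
        cube = mk.Hypercube(np.zeros((3, 3, vis_axis.n_bands)), vis_axis)
        anneal = mk.AnnealConfig(T_initial=0.01, T_final=0.0, T_step=0.001, seed=1)
        _, trace = mk.simulated_annealing_spectral(
            _cfg(n_channels=1), anneal, cube, amap, lib
        )
        assert len(trace) == 11  # init + exactly (T_initial/T_step) + 1 moves

    def test_deterministic_for_fixed_seed(self, recovery_scene):
        cube, amap, lib = recovery_scene
        anneal = mk.AnnealConfig(T_initial=0.05, T_final=1e-4, T_step=1e-3, seed=7)
        a = mk.simulated_annealing_spectral(_cfg(), anneal, cube, amap, lib)
        b = mk.simulated_annealing_spectral(_cfg(), anneal, cube, amap, lib)
        np.testing.assert_array_equal(a[0].centers, b[0].centers)

    def test_schedule_validation(self):
        with pytest.raises(ValueError):
            mk.AnnealConfig(T_initial=0.1, T_final=0.2, T_step=0.01)
        with pytest.raises(ValueError):
            mk.AnnealConfig(T_initial=0.1, T_final=0.0, T_step=-1.0)


class TestExhaustiveSpatial:
    def test_matches_brute_force_without_deduplication(self, vis_scene, rgyb_bank):
        cube = vis_scene[0]
        best_pat, best = mk.exhaustive_spatial(rgyb_bank, (2, 2), cube, "wbi")
        planes = channel_signals(cube, rgyb_bank)
        brute = []
        for perm in itertools.permutations(range(4)):
            pattern = mk.MosaicPattern.from_array(np.array(perm).reshape(2, 2), 4)
            sig = mk.apply_mosaic(planes, pattern)
            brute.append(spatial_merit(sig, planes, "wbi").value)
        assert best.value == pytest.approx(min(brute), rel=1e-12)

    def test_identical_channels_tie_to_first_pattern(self, vis_scene, vis_axis):
        cube = vis_scene[0]
        bank = mk.FilterBank.gaussian([550] * 4, [30] * 4, vis_axis)
        pattern, _ = mk.exhaustive_spatial(bank, (2, 2), cube, "wbi")
        first = next(mk.enumerate_patterns(4, (2, 2)))
        assert pattern.cell == first.cell

    def test_returned_merit_is_the_minimum(self, vis_scene, rgyb_bank):
        cube = vis_scene[0]
        _, best = mk.exhaustive_spatial(rgyb_bank, (2, 2), cube, "wbi")
        planes = channel_signals(cube, rgyb_bank)
        for pattern in mk.enumerate_patterns(4, (2, 2)):
            sig = mk.apply_mosaic(planes, pattern)
            assert best.value <= spatial_merit(sig, planes, "wbi").value + 1e-12

    def test_budget_guard(self, vis_scene, vis_axis):
        cube = vis_scene[0]
        bank = mk.FilterBank.gaussian(np.linspace(420, 680, 9), [10] * 9, vis_axis)
        with pytest.raises(ValueError, match="budget"):
            mk.exhaustive_spatial(bank, (3, 3), cube, "wbi", budget=100)


class TestJointOptimize:
    def test_single_channel_total_equals_spectral(self, toy_scene):
        cube, amap, lib = toy_scene
        cfg = mk.SpectralSearchConfig(
            n_channels=1,
            wavelength_range=(500, 530),
            bandwidth_range=(10, 14),
            n_random_starts=5,
            seed=2,
        )
        result = mk.joint_optimize(cfg, None, (1, 1), cube, amap, lib, "wbi")
        assert result["total"].value == pytest.approx(result["spectral"].value, abs=1e-12)
        assert result["spatial"].value == 0.0

    def test_report_contains_all_three_merits(self, recovery_scene):
        cube, amap, lib = recovery_scene
        result = mk.joint_optimize(_cfg(), None, (1, 2), cube, amap, lib, "wbi")
        for kind in ("spectral", "spatial", "total"):
            assert result[kind].kind == kind
            assert result[kind].value >= 0.0
        assert result["pattern"].n_channels == 2


class TestNearDuplicates:
    def test_overlapping_passbands_flagged(self, vis_axis):
        bank = mk.FilterBank.gaussian([500, 504, 600], [10, 10, 10], vis_axis)
        assert mk.near_duplicate_pairs(bank) == [(0, 1)]

    def test_fixed_tolerance_override(self, vis_axis):
        bank = mk.FilterBank.gaussian([500, 520, 600], [10, 10, 10], vis_axis)
        assert mk.near_duplicate_pairs(bank) == []
        assert mk.near_duplicate_pairs(bank, tol_nm=25) == [(0, 1)]
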