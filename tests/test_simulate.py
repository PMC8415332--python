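"""Synthetic-data generator: occupancy statistics, the Ewald forward model
against a brute-force oracle, frame rendering, and run determinism."""

import math

import numpy as np
import pytest
from scipy import stats

from dropsfx import (ReflectionSet, SimConfig, UnitCell,
                     draw_crystal_count, predict_reflections,
                     random_orientation, render_frame, simulate_run)


class TestCrystalOccupancy:
    def test_zero_concentration_never_yields_crystals(self, rng):
        assert all(draw_crystal_count(0.0, 1.0, rng) == 0 for _ in range(200))

    def test_sample_mean_matches_poisson_rate(self, rng):
        lam = 0.5
        n = 100_000
        draws = [draw_crystal_count(2.0, 0.25, rng) for _ in range(n)]
        assert abs(np.mean(draws) - lam) < 3 * math.sqrt(lam / n)

    def test_full_drop_at_dense_slurry_averages_100_crystals(self, rng):
        # 400 crystals/nl × 0.25 nl probed → λ = 100
        n = 2000
        draws = [draw_crystal_count(400.0, 0.25, rng) for _ in range(n)]
        assert abs(np.mean(draws) - 100.0) < 3 * math.sqrt(100.0 / n)

    def test_empirical_distribution_is_poisson(self, rng):
        lam = 2.0
        draws = np.array([draw_crystal_count(4.0, 0.5, rng)
                          for _ in range(10_000)])
        kmax = 8
        observed = np.bincount(np.minimum(draws, kmax), minlength=kmax + 1)
        pmf = stats.poisson.pmf(np.arange(kmax), lam)
        expected = np.append(pmf, 1.0 - pmf.sum()) * draws.size
        _, p = stats.chisquare(observed, expected)
        assert p > 0.01


def _brute_force_excited(cell, R, geom, tol, d_min):
    """Scalar triple-loop oracle for the Ewald excitation test."""
    B = cell.reciprocal_basis()
    lam = geom.wavelength
    hmax = int(math.ceil(cell.a / d_min))
    out = set()
    for h in range(-hmax, hmax + 1):
        for k in range(-hmax, hmax + 1):
            for l in range(-hmax, hmax + 1):
                if h == k == l == 0:
                    continue
                v = R @ (B @ np.array([h, k, l], dtype=float))
                qn = math.sqrt(v[0] ** 2 + v[1] ** 2 + v[2] ** 2)
                if qn == 0 or qn > 1.0 / d_min:
                    continue
                kz = v[2] + 1.0 / lam
                exc = abs(math.sqrt(v[0] ** 2 + v[1] ** 2 + kz ** 2) - 1.0 / lam)
                if exc > tol or kz <= 0:
                    continue
                pitch_mm = geom.pixel_pitch_um * 1e-3
                fast = geom.beam_center[0] + v[0] / kz * geom.detector_distance_mm / pitch_mm
                slow = geom.beam_center[1] + v[1] / kz * geom.detector_distance_mm / pitch_mm
                n_slow, n_fast = geom.frame_shape
                if 0 <= fast <= n_fast - 1 and 0 <= slow <= n_slow - 1:
                    out.add((h, k, l))
    return out


class TestPredictReflections:
    def test_matches_brute_force_enumeration(self, demo_geom, rng):
        cell = UnitCell(20.0, 20.0, 20.0)
        R = random_orientation(rng)
        tol, d_min = 5e-3, 2.5
        refl = predict_reflections(cell, R, demo_geom, tol, d_min)
        got = {tuple(h) for h in refl.hkl}
        assert got == _brute_force_excited(cell, R, demo_geom, tol, d_min)
        assert len(got) > 0

    def test_zero_tolerance_gives_empty_set(self, demo_geom, cubic_cell, rng):
        refl = predict_reflections(cubic_cell, random_orientation(rng),
                                   demo_geom, 0.0, 2.0)
        assert len(refl) <= 1  # measure-zero Ewald intersection

    def test_postconditions_resolution_and_frame_bounds(self, demo_geom, rng):
        cell = UnitCell(57.8, 57.8, 150.1)
        refl = predict_reflections(cell, random_orientation(rng), demo_geom,
                                   5e-4, 2.0)
        assert len(refl) > 0
        assert (refl.d >= 2.0 - 1e-9).all()
        n_slow, n_fast = demo_geom.frame_shape
        assert ((refl.fast >= 0) & (refl.fast <= n_fast - 1)).all()
        assert ((refl.slow >= 0) & (refl.slow <= n_slow - 1)).all()

    def test_rejects_bad_orientation_shape(self, demo_geom, cubic_cell):
        with pytest.raises(ValueError):
            predict_reflections(cubic_cell, np.eye(2), demo_geom, 1e-3, 2.0)


class TestUnitCell:
    def test_degenerate_cell_rejected(self):
        with pytest.raises(ValueError):
            UnitCell(10, 10, 10, alpha=1.0, beta=1.0, gamma=170.0)
        with pytest.raises(ValueError):
            UnitCell(-5, 10, 10)

    def test_cubic_volume_and_reciprocal_basis(self):
        cell = UnitCell(50.0, 50.0, 50.0)
        assert cell.volume == pytest.approx(125_000.0)
        np.testing.assert_allclose(cell.reciprocal_basis(),
                                   np.eye(3) / 50.0, atol=1e-12)

    def test_triclinic_volume_against_closed_form(self):
        a, b, c = 40.0, 50.0, 60.0
        al, be, ga = math.radians(80), math.radians(95), math.radians(100)
        expected = a * b * c * math.sqrt(
            1 - math.cos(al) ** 2 - math.cos(be) ** 2 - math.cos(ga) ** 2
            + 2 * math.cos(al) * math.cos(be) * math.cos(ga))
        cell = UnitCell(a, b, c, 80.0, 95.0, 100.0)
        assert cell.volume == pytest.approx(expected, rel=1e-9)


def _quiet_config(sim: SimConfig, **kw) -> SimConfig:
    return sim.with_(ring_bands=(), background_level=0.0, **kw)


class TestRenderFrame:
    def test_nothing_to_render_gives_zero_frame(self, fast_sim, rng):
        cfg = _quiet_config(fast_sim)
        frame = render_frame([], cfg, rng)
        assert frame.sum() == 0

    def test_noise_free_peak_mass_matches_debye_waller_scaling(self, fast_sim, rng):
        d = 3.0
        refl = ReflectionSet(fast=np.array([100.3]), slow=np.array([131.7]),
                             d=np.array([d]), hkl=np.zeros((1, 3), dtype=int))
        cfg = _quiet_config(fast_sim, noise_model=False)
        frame = render_frame([refl], cfg, rng).astype(float)
        expected = cfg.gain * cfg.sample.peak_scale_i0 * math.exp(
            -cfg.sample.b_factor / (2 * d * d))
        assert frame.sum() == pytest.approx(expected, rel=0.01)

    def test_powder_ring_peaks_at_expected_radius(self, fast_sim, rng):
        cfg = fast_sim.with_(ring_bands=((2.09, 2.0, 6.0),),
                             background_level=0.0, noise_model=False)
        frame = render_frame([], cfg, rng).astype(float)
        r = cfg.geometry.radius_map()
        radii = np.arange(5, 120)
        prof = np.array([frame[(r >= ri - 0.5) & (r < ri + 0.5)].mean()
                         for ri in radii])
        r_peak = radii[np.argmax(prof)]
        assert abs(r_peak - cfg.geometry.d_to_ring_radius(2.09)) <= 1.0


class TestSimulateRun:
    def test_frame_count_follows_duration_and_rate(self, fast_sim):
        stack, truth = simulate_run(fast_sim.with_(duration_s=1.0))
        assert len(stack) == 10
        assert len(truth) == 10
        np.testing.assert_allclose(stack.timestamps, np.arange(10) / 10.0)

    def test_certain_miss_blanks_every_event(self, fast_sim):
        from dropsfx import DropModel
        cfg = fast_sim.with_(drop=DropModel(miss_probability=1.0),
                             duration_s=1.0)
        _, truth = simulate_run(cfg)
        assert all(ev.is_blank for ev in truth)
        assert all(ev.n_crystals == 0 for ev in truth)
        assert all(ev.n_true_peaks == 0 for ev in truth)

    def test_same_seed_reproduces_run_exactly(self, fast_sim):
        cfg = fast_sim.with_(duration_s=1.0)
        stack_a, truth_a = simulate_run(cfg)
        stack_b, truth_b = simulate_run(cfg)
        np.testing.assert_array_equal(stack_a.frames, stack_b.frames)
        assert truth_a.to_dataframe().equals(truth_b.to_dataframe())

    def test_depletion_switches_to_buffer_only(self, fast_sim):
        cfg = fast_sim.with_(duration_s=2.0, depletion_time_s=1.0)
        _, truth = simulate_run(cfg)
        late = [ev for ev in truth if ev.time_s >= 1.0]
        assert late and all(ev.n_crystals == 0 for ev in late)
        early = [ev for ev in truth if ev.time_s < 1.0]
        assert any(ev.n_crystals > 0 for ev in early)

    def test_ground_truth_respects_resolution_cutoff(self, fast_sim):
        _, truth = simulate_run(fast_sim.with_(duration_s=1.0))
        for ev in truth:
            for refl in ev.reflections:
                if len(refl):
                    assert (refl.d >= fast_sim.d_min - 1e-9).all()
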