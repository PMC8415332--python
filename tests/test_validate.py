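"""Cell equivalence, spot integration, prediction matching, and the
cross-contamination audit on simulated ground truth."""

import numpy as np
import pytest

from dropsfx import (IntegrationRadii, MatchParams, PeakFindParams, UnitCell,
                     cells_equivalent, contamination_audit,
                     foreign_only_supported, integrate_spot, match_fraction,
                     predict_reflections, random_orientation, simulate_run)
from dropsfx.peaks import Peak, PeakList, find_peaks, make_ring_mask
from dropsfx.validate import UndefinedIntensityError


class TestCellsEquivalent:
    def test_identical_cells(self, cubic_cell):
        assert cells_equivalent(cubic_cell, cubic_cell)

    @pytest.mark.parametrize("scale,expected", [(1.04, True), (1.06, False)])
    def test_five_percent_length_tolerance(self, cubic_cell, scale, expected):
        other = UnitCell(cubic_cell.a * scale, cubic_cell.b, cubic_cell.c)
        assert cells_equivalent(cubic_cell, other) is expected

    def test_angle_beyond_one_and_a_half_degrees(self):
        a = UnitCell(40, 50, 60, 90, 90, 90)
        b = UnitCell(40, 50, 60, 90, 90, 92.0)
        assert not cells_equivalent(a, b)
        c = UnitCell(40, 50, 60, 90, 90, 91.0)
        assert cells_equivalent(a, c)

    def test_symmetric_and_reflexive(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            base = 30 + 40 * rng.random(3)
            pert = base * (1 + 0.08 * (rng.random(3) - 0.5))
            a = UnitCell(*base)
            b = UnitCell(*pert)
            assert cells_equivalent(a, a) and cells_equivalent(b, b)
            # symmetry is approximate only through the relative tolerance
            # anchor; verify both directions agree on clear cases
            if cells_equivalent(a, b) != cells_equivalent(b, a):
                rel = np.abs(base - pert) / base
                assert np.any(np.abs(rel - 0.05) < 0.01)


class TestIntegrateSpot:
    def test_constant_frame_integrates_to_zero(self):
        frame = np.full((30, 30), 11.0)
        assert integrate_spot(frame, (15.0, 15.0)) == pytest.approx(0.0)

    def test_uniform_disc_on_zero_background(self):
        frame = np.zeros((30, 30))
        r = np.hypot(*np.meshgrid(np.arange(30) - 15.0, np.arange(30) - 15.0))
        disc = r <= 3.0
        frame[disc] = 10.0
        assert integrate_spot(frame, (15.0, 15.0)) == pytest.approx(
            10.0 * disc.sum())

    def test_linearity(self, rng):
        f1 = rng.random((40, 40)) * 100
        f2 = rng.random((40, 40)) * 100
        pos = (20.3, 19.6)
        assert integrate_spot(f1 + f2, pos) == pytest.approx(
            integrate_spot(f1, pos) + integrate_spot(f2, pos), abs=1e-8)

    def test_fully_masked_annulus_rejected(self):
        frame = np.zeros((30, 30))
        mask = np.ones((30, 30), dtype=bool)
        with pytest.raises(UndefinedIntensityError):
            integrate_spot(frame, (15.0, 15.0), mask=mask)

    def test_position_without_full_annulus_rejected(self):
        with pytest.raises(ValueError):
            integrate_spot(np.zeros((30, 30)), (2.0, 15.0))

    def test_radii_ordering_enforced(self):
        with pytest.raises(ValueError):
            IntegrationRadii(4, 4, 5)


def _peaklist(positions):
    return PeakList([Peak(fast=f, slow=s, n_pixels=4, intensity=100.0,
                          snr=10.0, d=3.0) for f, s in positions])


class TestMatchFraction:
    def test_exact_positions_fully_match(self):
        pos = [(10.0, 10.0), (50.0, 60.0), (90.0, 20.0)]
        assert match_fraction(np.array(pos), _peaklist(pos)) == 1.0

    def test_no_observed_peaks(self):
        assert match_fraction(np.array([[10.0, 10.0]]), _peaklist([])) == 0.0

    def test_empty_prediction_scores_zero(self):
        assert match_fraction(np.empty((0, 2)), _peaklist([(1.0, 1.0)])) == 0.0

    def test_each_observed_peak_consumed_once(self):
        predicted = np.array([[10.0, 10.0], [11.0, 10.0]])
        observed = _peaklist([(10.5, 10.0)])
        assert match_fraction(predicted, observed, 3.0) == 0.5

    def test_invariant_under_permutation(self, rng):
        predicted = rng.random((20, 2)) * 200
        observed = _peaklist([tuple(p + rng.normal(0, 1, 2))
                              for p in predicted[:12]])
        base = match_fraction(predicted, observed, 3.0)
        perm = rng.permutation(20)
        assert match_fraction(predicted[perm], observed, 3.0) == base


@pytest.fixture(scope="module")
def bright_run(request):
    """A short simulated run with bright, well-matched peaks."""
    from dropsfx import DropModel, SampleModel, SimConfig, BeamlineGeometry
    geom = BeamlineGeometry(photon_energy_kev=9.28, detector_distance_mm=20.0,
                            pixel_pitch_um=177.0, beam_center=(127.5, 127.5),
                            frame_shape=(256, 256))
    cell = UnitCell(50.0, 50.0, 50.0, label="A")
    sample = SampleModel(name="A", cell=cell, concentration=400.0,
                         b_factor=8.0)
    cfg = SimConfig(geometry=geom, sample=sample, drop=DropModel(),
                    duration_s=3.0, seed=21)
    stack, truth = simulate_run(cfg)
    mask = make_ring_mask(geom, [(d, 2.5) for d, *_ in cfg.ring_bands])
    params = PeakFindParams()
    peak_lists = {ev.event_id: find_peaks(frame, mask, params, geom)
                  for ev, frame in zip(truth, stack.frames)}
    return cfg, truth, peak_lists


class TestAgainstSimulationTruth:
    def test_true_solution_matches_observed_peaks(self, bright_run):
        cfg, truth, peak_lists = bright_run
        checked = 0
        for ev in truth:
            if ev.n_crystals != 1 or len(peak_lists[ev.event_id]) < 15:
                continue
            frac = match_fraction(ev.reflections[0], peak_lists[ev.event_id],
                                  3.0)
            assert frac >= 0.8
            checked += 1
        assert checked >= 3

    def test_wrong_cell_random_orientation_unsupported(self, bright_run):
        cfg, truth, peak_lists = bright_run
        foreign_cell = UnitCell(57.8, 57.8, 150.1, label="B")
        rng = np.random.default_rng(77)
        trials = 0
        below = 0
        for ev in truth:
            pl = peak_lists[ev.event_id]
            if len(pl) < 15:
                continue
            refl = predict_reflections(foreign_cell, random_orientation(rng),
                                       cfg.geometry, cfg.excitation_tol,
                                       cfg.d_min)
            trials += 1
            if match_fraction(refl, pl, 3.0) < MatchParams().support_fraction:
                below += 1
        assert trials >= 10
        assert below / trials >= 0.95

    def test_audit_finds_no_cross_contamination(self, bright_run):
        cfg, truth, peak_lists = bright_run
        cells = {"A": cfg.sample.cell,
                 "B": UnitCell(57.8, 57.8, 150.1, label="B")}
        audit = contamination_audit(truth, peak_lists, cells, "A",
                                    cfg.geometry,
                                    excitation_tol=cfg.excitation_tol,
                                    d_min=cfg.d_min, seed=3)
        assert foreign_only_supported(audit, "A") == 0
        hits = [ev.event_id for ev in truth
                if len(peak_lists[ev.event_id]) >= 15 and ev.n_crystals > 0]
        own = audit[(audit.cell_label == "A")
                    & (audit.event_id.isin(hits))]
        assert own.supported.mean() > 0.9

    def test_empty_run_gives_empty_audit(self, demo_geom, cubic_cell):
        from dropsfx.simulate import GroundTruthTable
        audit = contamination_audit(GroundTruthTable([]), {},
                                    {"A": cubic_cell}, "A", demo_geom)
        assert audit.empty
        assert foreign_only_supported(audit, "A") == 0

    def test_mixed_run_events_supported_by_own_cell(self, bright_run, demo_geom):
        from dropsfx import DropModel, SampleModel, SimConfig
        from dropsfx.simulate import GroundTruthTable
        cfg_a, truth_a, peaks_a = bright_run
        cell_b = UnitCell(36.0, 58.0, 68.0, label="B")
        sample_b = SampleModel(name="B", cell=cell_b, concentration=400.0,
                               b_factor=8.0)
        cfg_b = cfg_a.with_(sample=sample_b, duration_s=1.5, seed=22)
        stack_b, truth_b = simulate_run(cfg_b)
        mask = make_ring_mask(demo_geom, [(d, 2.5) for d, *_ in cfg_b.ring_bands])
        params = PeakFindParams()
        offset = 1000
        labels = {}
        events, peak_lists = [], {}
        for ev in truth_a:
            labels[ev.event_id] = "A"
            events.append(ev)
            peak_lists[ev.event_id] = peaks_a[ev.event_id]
        for ev, frame in zip(truth_b, stack_b.frames):
            ev.event_id += offset
            labels[ev.event_id] = "B"
            events.append(ev)
            peak_lists[ev.event_id] = find_peaks(frame, mask, params, demo_geom)
        cells = {"A": cfg_a.sample.cell, "B": cell_b}
        audit = contamination_audit(GroundTruthTable(events), peak_lists,
                                    cells, labels, demo_geom,
                                    excitation_tol=cfg_a.excitation_tol,
                                    d_min=cfg_a.d_min, seed=9)
        assert foreign_only_supported(audit, labels) == 0
        crystal_hits = [ev.event_id for ev in events
                        if ev.n_crystals > 0 and len(peak_lists[ev.event_id]) >= 15]
        for eid in crystal_hits:
            grp = audit[audit.event_id == eid]
            own = grp[grp.cell_label == labels[eid]]
            assert own.supported.all()
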