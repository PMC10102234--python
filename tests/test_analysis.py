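"""Pattern detectors against synthetic ground truth and simulated runs."""

import numpy as np
import pytest

from somitesim import analysis as ana
from somitesim.fixtures import FixtureSpec, generate_fixture
from somitesim.params import CLOCK_PERIOD


class TestBoundariesOnFixtures:
    def test_step_profile_single_border(self):
        out, truth = generate_fixture(
            FixtureSpec(kind="step", t_end=10.0, params={"edge": 200.0})
        )
        trace = ana.tbx6_border_trace(out, threshold=0.5)
        assert np.all(trace == truth["edge"])
        assert ana.detect_tbx6_boundaries(out, threshold=0.5) == []

    def test_programmed_border_jumps_recovered_exactly(self):
        spec = FixtureSpec(
            kind="sawtooth_border",
            t_end=120.0,
            params={"start": 100.0, "jump": 60.0, "every": 30.0},
        )
        out, truth = generate_fixture(spec)
        events = ana.detect_tbx6_boundaries(out, threshold=0.5)
        assert [e.time for e in events] == truth["jump_times"]
        assert [e.position for e in events] == truth["border_positions"]
        assert all(e.spacing_cells == 6.0 for e in events[1:])
        # borders never recover anteriorly in this fixture
        assert all(
            e.persistence == pytest.approx(120.0 - e.time) for e in events
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_border_detection_robust_to_noise(self, seed):
        rng = np.random.default_rng(seed)
        edge = float(rng.choice([150.0, 200.0, 250.0]))
        out, truth = generate_fixture(
            FixtureSpec(
                kind="step", t_end=10.0, params={"edge": edge}, noise=0.05, seed=seed
            )
        )
        trace = ana.tbx6_border_trace(out, threshold=0.5)
        assert np.all(np.abs(trace - truth["edge"]) <= 10.0)  # within one cell


class TestSpacingArithmetic:
    def _records(self, positions):
        recs = [
            ana.BoundaryRecord(time=float(i), position=float(x), spacing_cells=np.nan,
                               persistence=0.0)
            for i, x in enumerate(positions)
        ]
        for prev, cur in zip(recs, recs[1:]):
            cur.spacing_cells = (cur.position - prev.position) / 10.0
        return recs

    def test_uniform_spacing(self):
        mean, per = ana.somite_spacing(self._records([0.0, 60.0, 120.0]))
        assert mean == 6.0 and list(per) == [6.0, 6.0]

    def test_alternating_spacing(self):
        mean, per = ana.somite_spacing(self._records([0.0, 50.0, 120.0, 170.0]))
        assert mean == pytest.approx(17.0 / 3.0)
        assert list(per) == [5.0, 7.0, 5.0]

    def test_single_boundary_rejected(self):
        with pytest.raises(ValueError):
            ana.somite_spacing(self._records([0.0]))


class TestKymograph:
    def test_constant_field_stays_constant(self):
        out, _ = generate_fixture(FixtureSpec(kind="boxcar", t_end=20.0))
        k = ana.build_kymograph(out, "p_t")
        assert np.all(k.matrix == k.matrix[0])

    def test_unknown_variable_rejected(self, wt_run):
        with pytest.raises(KeyError):
            ana.build_kymograph(wt_run, "p_z")

    def test_lab_round_trip_is_lossless(self, wt_run):
        lab = ana.build_kymograph(wt_run, "p_t", frame="lab")
        back = ana.kymograph_to_tailbud(lab, wt_run.shift_counts, len(wt_run.positions))
        assert np.array_equal(back.matrix, wt_run.data["p_t"])

    def test_traveling_wave_has_programmed_slope(self):
        # equal-phase points move anteriorly: the crest position advances
        # by lambda per period at the posterior end
        out, _ = generate_fixture(
            FixtureSpec(
                kind="traveling_wave",
                t_end=60.0,
                params={
                    "period_anterior": 30.0,
                    "period_posterior": 30.0,
                    "wavelength": 200.0,
                    "amplitude": 1.0,
                },
            )
        )
        k = ana.build_kymograph(out, "p_t")
        lam = 200.0
        crest0 = k.positions[np.argmax(k.matrix[0, :20])]
        crest15 = k.positions[np.argmax(k.matrix[15, :20])]
        # half a period later the crest lies half a wavelength away (mod lam)
        offset = (crest15 - crest0 - lam / 2) % lam
        assert min(offset, lam - offset) <= 10.0


class TestPeriodProfile:
    def test_linear_period_gradient_recovered_within_one_frame(self):
        spec = FixtureSpec(
            kind="traveling_wave",
            t_end=300.0,
            params={
                "period_anterior": 60.0,
                "period_posterior": 30.0,
                "wavelength": 150.0,
                "amplitude": 1.0,
            },
        )
        out, truth = generate_fixture(spec)
        prof = ana.measure_period_profile(ana.build_kymograph(out, "p_t"))
        expected = np.asarray(truth["period_profile"])
        valid = prof.valid()
        assert valid.sum() >= 30
        assert np.all(np.abs(prof.period[valid] - expected[valid]) <= 1.0)

    def test_constant_signal_flagged_nonoscillatory(self):
        out, _ = generate_fixture(FixtureSpec(kind="boxcar", t_end=60.0))
        prof = ana.measure_period_profile(ana.build_kymograph(out, "p_t"))
        assert prof.flagged.all()
        assert np.all(np.isnan(prof.period))


class TestWaveArrest:
    @pytest.mark.parametrize("arrest_x", [100.0, 200.0])
    def test_programmed_amplitude_cutoff_recovered(self, arrest_x):
        out, truth = generate_fixture(
            FixtureSpec(
                kind="traveling_wave",
                t_end=90.0,
                params={
                    "period_anterior": 40.0,
                    "period_posterior": 30.0,
                    "wavelength": 150.0,
                    "amplitude": 1.0,
                    "arrest_x": arrest_x,
                },
            )
        )
        k = ana.build_kymograph(out, "p_t")
        pos = ana.wave_arrest_position(k, window=30.0)
        assert abs(pos - truth["arrest_x"]) <= 10.0

    def test_flat_kymograph_flagged(self):
        out, _ = generate_fixture(FixtureSpec(kind="step", t_end=60.0))
        out.data["p_t"][:] = 0.0
        with pytest.raises(ValueError, match="no oscillation"):
            ana.wave_arrest_position(ana.build_kymograph(out, "p_t"), window=30.0)


class TestDomainExtent:
    def test_boxcar_edges_recovered(self):
        out, truth = generate_fixture(
            FixtureSpec(kind="boxcar", t_end=5.0, params={"left": 120.0, "right": 260.0})
        )
        ext = ana.domain_extent(out.data["p_t"][0], out.positions)
        assert ext == (truth["left"], truth["right"])

    def test_all_zero_snapshot_flags_empty_domain(self):
        assert ana.domain_extent(np.zeros(41), np.arange(41) * 10.0) is None

    def test_negative_snapshot_rejected(self):
        with pytest.raises(ValueError):
            ana.domain_extent(np.array([-1.0, 1.0]), np.array([0.0, 10.0]))


class TestOnWildTypeRun:
    """Closure with the simulator: detectors on the calibrated run."""

    def test_boundary_events_are_periodic(self, wt_run):
        events = ana.detect_tbx6_boundaries(wt_run)
        assert len(events) >= 5
        gaps = np.diff([e.time for e in events])
        assert np.all(np.abs(gaps - CLOCK_PERIOD) <= 3.0)  # within 10%

    def test_ripply_transcription_confined_to_anterior_half_of_tbx6_domain(
        self, wt_run, defaults
    ):
        # the nascent ripply domain must not extend past the midpoint
        # between the Tbx6 border and the dpErk border
        thr = ana.boundary_threshold(defaults)
        border = ana.tbx6_border_trace(wt_run)
        peak = wt_run.data["m_r"].max()
        checked = 0
        for k in range(20, len(wt_run.times), 10):
            if wt_run.data["m_r"][k].max() < 0.5 * peak:
                continue  # between pulses only a faint basal leak remains
            ext = ana.domain_extent(wt_run.data["m_r"][k], wt_run.positions)
            border_tb = border[k] - wt_run.shift_counts[k] * defaults.dx
            high = np.nonzero(wt_run.data["p_t"][k] >= thr)[0]
            tbx6_posterior = wt_run.positions[high[-1]]
            midpoint = (border_tb + tbx6_posterior) / 2.0
            assert ext[1] <= midpoint + defaults.dx
            checked += 1
        assert checked >= 4
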