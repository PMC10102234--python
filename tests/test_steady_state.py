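"""Tbx6 switch equilibria: closed forms, oracle equivalence, hysteresis,
spatial bifurcation structure, her-oscillation scan, phase-diagram slice."""

from dataclasses import replace

import numpy as np
import pytest

from somitesim import steady_state as ss
from somitesim.simulator import integrate_tbx6_cell
from somitesim.params import CLOCK_PERIOD
from somitesim.tissue import fgf_gradient


class TestFindSteadyStates:
    def test_closed_form_roots_without_input(self, defaults):
        # n6 = 2, F = 0: nonzero roots solve p^2 - p + K6^2 = 0
        s = ss.find_steady_states(0.0, 0.0, defaults)
        assert [lab for _, lab in s.states] == ["stable", "unstable", "stable"]
        disc = np.sqrt(1.0 - 4.0 * defaults.K6**2)
        expect = [0.0, (1.0 - disc) / 2.0, (1.0 + disc) / 2.0]
        assert np.allclose(s.roots, expect, atol=1e-9)

    def test_large_ripply_leaves_single_low_root(self, defaults):
        s = ss.find_steady_states(0.0, 1e4, defaults)
        assert len(s.roots) == 1
        assert s.states[0][1] == "stable"
        assert s.roots[0] < 1e-3

    def test_production_degradation_curves(self, defaults):
        grid = np.linspace(0.0, 5.0, 100)
        P, D = ss.production_degradation_curves(grid, 0.0, 0.0, defaults)
        assert np.allclose(D, grid)          # p_r = 0: identity line
        assert P[0] == 0.0                   # no signal, no Tbx6
        assert P[-1] <= 1.0 + defaults.gamma  # bounded production
        with pytest.raises(ValueError):
            ss.production_degradation_curves(np.array([]), 0.0, 0.0, defaults)

    def test_matches_dense_sign_scan_oracle(self, defaults):
        """Root sets agree with a brute-force 1e5-point sign scan."""
        rng = np.random.default_rng(20260930)
        for _ in range(100):
            K_FA = rng.uniform(0.05, 0.5)
            p = replace(
                defaults,
                K6=rng.uniform(0.05, 1.0),
                gamma=rng.uniform(0.1, 1.0),
                K_FA=K_FA,
                K_FR=K_FA * rng.uniform(1.5, 5.0),
                nA=rng.integers(1, 5),
                nR=rng.integers(1, 7),
            )
            F = rng.uniform(0.0, 1.0)
            p_r = rng.uniform(0.0, 1.0)
            s = ss.find_steady_states(F, p_r, p)

            # independent oracle: dense grid, raw sign changes
            grid = np.linspace(0.0, 10.0 * (1.0 + p.gamma), 100_000)
            from somitesim.kinetics import tbx6_production

            g = np.asarray(tbx6_production(grid, F, p)) - (1 + p.eta * p_r) * grid
            crossings = np.nonzero(g[:-1] * g[1:] < 0)[0]
            oracle_roots = [
                0.5 * (grid[i] + grid[i + 1]) for i in crossings
            ]
            if abs(g[0]) < 1e-13:
                oracle_roots = [0.0] + oracle_roots
            assert len(s.roots) == len(oracle_roots)
            assert np.allclose(s.roots, oracle_roots, atol=grid[1])
            # stabilities alternate, starting and ending stable
            labels = [lab for _, lab in s.states]
            assert labels[::2] == ["stable"] * len(labels[::2])
            assert labels[1::2] == ["unstable"] * len(labels[1::2])


class TestSaddleNode:
    def test_closed_form_examples(self, defaults):
        assert ss.sn_degradation_threshold(0.0, replace(defaults, K6=0.4)) == pytest.approx(
            1.25, abs=1e-4
        )
        assert ss.sn_degradation_threshold(0.0, replace(defaults, K6=0.25)) == pytest.approx(
            2.0, abs=1e-4
        )

    def test_monotone_decreasing_in_K6_for_other_exponents(self, defaults):
        for n6 in (2.0, 3.0):
            thresholds = [
                ss.sn_degradation_threshold(0.0, replace(defaults, K6=k6, n6=n6))
                for k6 in np.linspace(0.1, 0.45, 8)
            ]
            assert np.all(np.diff(thresholds) < 0)

    def test_monostable_input_flagged_or_rejected(self, defaults):
        p = replace(defaults, K6=0.8)  # PFL alone not bistable
        with pytest.raises(ValueError):
            ss.sn_degradation_threshold(0.0, p)
        assert ss.sn_degradation_threshold(0.0, p, allow_monostable=True) == 1.0


@pytest.fixture(scope="module")
def setting(defaults):
    F = float(fgf_gradient(150.0, defaults))  # anterior PSM position
    s = ss.find_steady_states(F, 0.0, defaults)
    return {
        "F": F,
        "low": min(s.stable_roots),
        "high": max(s.stable_roots),
        "dstar": ss.sn_degradation_threshold(F, defaults),
    }


class TestHysteresis:
    """The dynamic-to-static memory: a transient Ripply pulse flips the
    switch permanently iff it exceeds the saddle-node threshold."""

    def _pulse_run(self, defaults, setting, factor):
        p_r = (factor - 1.0) / defaults.eta
        pulse = lambda t: p_r if 20.0 <= t < 40.0 else 0.0
        t_max = 40.0 + 2.0 * CLOCK_PERIOD + 20.0  # two clock periods after pulse
        t, trace = integrate_tbx6_cell(
            defaults, setting["F"], pulse, setting["high"], t_max=t_max
        )
        return t, trace

    def test_supra_threshold_pulse_locks_low(self, defaults, setting):
        t, trace = self._pulse_run(defaults, setting, 1.3 * setting["dstar"])
        after = trace[t >= 40.0 + 2.0 * CLOCK_PERIOD]
        assert np.all(np.abs(after - setting["low"]) < 0.05)

    def test_sub_threshold_pulse_returns_high(self, defaults, setting):
        factor = 1.0 + 0.5 * (setting["dstar"] - 1.0)
        t, trace = self._pulse_run(defaults, setting, factor)
        assert trace[-1] == pytest.approx(setting["high"], abs=0.01)


class TestBifurcationAlongAxis:
    def test_wild_type_spatial_structure(self, defaults):
        sets = ss.bifurcation_along_axis(defaults, np.zeros(defaults.N))
        x = np.arange(defaults.N) * defaults.dx
        anterior = [s for s, xi in zip(sets, x) if xi <= 150.0]
        mid = [s for s, xi in zip(sets, x) if 240.0 <= xi <= 310.0]
        assert all(s.bistable for s in anterior)
        # mid-PSM: the IFFL input removes the low state -> monostable high
        assert all(len(s.stable_roots) == 1 and s.roots[0] > 0.1 for s in mid)
        # tailbud: the low branch exists and sits near zero (new cells stay low)
        tail = sets[-1]
        assert min(tail.stable_roots) < 0.05

    def test_supra_threshold_ripply_peak_removes_high_state(self, defaults):
        i = 15  # x = 150 um, anterior
        F = float(fgf_gradient(150.0, defaults))
        dstar = ss.sn_degradation_threshold(F, defaults)
        profile = np.zeros(defaults.N)
        profile[i] = 1.2 * (dstar - 1.0) / defaults.eta
        sets = ss.bifurcation_along_axis(defaults, profile)
        assert len(sets[i].stable_roots) == 1
        assert sets[i].roots[0] < 0.1
        assert sets[i - 1].bistable and sets[i + 1].bistable

    def test_without_iffl_structure_is_position_independent(self, defaults):
        p = replace(defaults, gamma=1e-12)
        sets = ss.bifurcation_along_axis(p, np.zeros(p.N))
        ref = sets[0].roots
        for s in sets[1:]:
            assert np.allclose(s.roots, ref, atol=1e-5)


class TestHerOscillationScan:
    def test_arrest_below_onset_and_growth_above(self, defaults):
        res = ss.her_oscillation_scan(
            np.array([0.0, 0.1, 0.3, 0.6, 0.9]), defaults, t_max=400.0, discard=200.0
        )
        assert res[0]["amplitude"] == 0.0  # no Tbx6, no anterior her transcription
        assert res[1]["amplitude"] == 0.0
        amps = [r["amplitude"] for r in res]
        assert amps[-1] > 1.0  # sustained oscillation at the high Tbx6 state
        assert np.all(np.diff(amps) >= 0.0)  # non-decreasing near onset
        osc = [r for r in res if r["amplitude"] > 0]
        assert all(30.0 < r["period"] < 60.0 for r in osc)


def test_phase_diagram_slice_tracks_saddle_node(defaults):
    """K6 = 0.4 row: the formed/failed transition brackets d* = 1.25."""
    pd = ss.phase_diagram(defaults, np.array([0.4]), np.array([0.3, 5.0]))
    assert pd.sn_factor[0] == pytest.approx(1.25, abs=0.01)
    assert not pd.outcome[0, 0] and pd.outcome[0, 1]
    assert pd.achieved_factor[0, 0] < pd.sn_factor[0] < pd.achieved_factor[0, 1]
    assert pd.errors == []
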