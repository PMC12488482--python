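"""Unit tests for the IFFL ODE model: Hill terms, derivatives, integration,
fixed points and pulse metrics."""

import math

import numpy as np
import pytest

from apcpulse import (
    KineticParameters,
    StimulusProtocol,
    SystemState,
    derivatives,
    hill_down,
    hill_up,
    pulse_metrics,
    reference_simulate,
    simulate,
    steady_state,
)
from apcpulse.model import Trajectory


class TestHillFunctions:
    @pytest.mark.parametrize(
        "x,k,n,expected",
        [
            (3.0, 0.2, 1.0, 0.9375),
            (0.0, 0.3, 1.0, 0.0),
            (0.2, 0.2, 2.0, 0.5),
        ],
    )
    def test_hill_up_values(self, x, k, n, expected):
        assert hill_up(x, k, n) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize(
        "x,k,n,expected",
        [
            (0.0, 0.8, 1.0, 1.0),
            (0.4, 0.4, 3.0, 0.5),
            (1.0, 0.4, 3.0, 0.064 / 1.064),
        ],
    )
    def test_hill_down_values(self, x, k, n, expected):
        assert hill_down(x, k, n) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("bad", [-0.1, float("nan"), float("inf")])
    def test_rejects_bad_input(self, bad):
        with pytest.raises(ValueError):
            hill_up(bad, 0.2, 1.0)
        with pytest.raises(ValueError):
            hill_down(bad, 0.2, 1.0)

    def test_rejects_bad_constants(self):
        with pytest.raises(ValueError):
            hill_up(1.0, 0.0, 1.0)
        with pytest.raises(ValueError):
            hill_up(1.0, 0.2, 0.5)


class TestParameterValidation:
    def test_default_constants_of_the_calibration(self):
        p = KineticParameters()
        assert (p.k1, p.n1, p.tau_mtor) == (0.2, 1.0, 0.5)
        assert (p.k2, p.n2, p.tau_pp) == (0.2, 1.0, 0.5)
        assert (p.k3, p.n3, p.tau_pcdh1) == (0.3, 1.0, 0.5)
        assert (p.k4, p.n4, p.tau_apc) == (0.2, 2.0, 0.5)
        assert (p.k5, p.n5) == (0.8, 1.0)
        assert (p.k6, p.n6, p.tau_geminin) == (0.4, 3.0, 0.3)

    @pytest.mark.parametrize(
        "kwargs", [{"k3": 0.0}, {"n4": 0.5}, {"tau_apc": -1.0}, {"k1": float("nan")}]
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            KineticParameters(**kwargs)

    def test_initial_state_is_quiescent_with_active_apc(self):
        s = SystemState()
        assert (s.mtor, s.pp, s.pcdh1, s.apc, s.geminin) == (0, 0, 0, 1, 0)

    def test_state_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            SystemState(apc=1.5)

    def test_protocol_rejects_negative_times(self):
        with pytest.raises(ValueError):
            StimulusProtocol(rapamycin_time=-1.0)
        with pytest.raises(ValueError):
            StimulusProtocol(mitogen_level=-0.5)


class TestDerivatives:
    def test_stimulated_initial_rates(self, params, control_protocol):
        d = derivatives(SystemState(), 0.0, params, control_protocol)
        assert d[0] == pytest.approx(1.875, abs=1e-12)  # mTOR drive on
        assert d[1] == 0.0  # PP held at zero until 4 h
        assert d[2] == 0.0  # no mTOR activity yet
        assert d[3] == 0.0  # APC at its no-pCDH1 fixed point
        assert d[4] == pytest.approx(0.2005012531, abs=1e-9)

    def test_quiescent_upstream_fixed_point(self, params):
        proto = StimulusProtocol(mitogen_level=0.0)
        d = derivatives(SystemState(), 0.0, params, proto)
        assert np.allclose(d[:4], 0.0)
        assert d[4] == pytest.approx(0.2005012531, abs=1e-9)

    @pytest.mark.parametrize("S,pp_active", [(0.0, False), (3.0, True), (0.5, True)])
    def test_steady_state_has_zero_derivatives(self, params, S, pp_active):
        ss = steady_state(params, S=S, pp_active=pp_active)
        proto = StimulusProtocol(mitogen_level=S, pp_onset_time=0.0)
        t_probe = 10.0  # past every switch
        d = derivatives(ss, t_probe, params, proto)
        if not pp_active:
            proto = StimulusProtocol(
                mitogen_level=S, phosphatase_inhibitor_time=0.0
            )
            d = derivatives(ss, t_probe, params, proto)
        assert np.max(np.abs(d)) < 1e-12


class TestSteadyState:
    def test_quiescent_cascade(self, params):
        ss = steady_state(params, S=0.0, pp_active=False)
        assert (ss.mtor, ss.pp, ss.pcdh1, ss.apc) == (0, 0, 0, 1)
        assert ss.geminin == pytest.approx(0.06015037594, abs=1e-9)

    def test_stimulated_without_phosphatase(self, params):
        ss = steady_state(params, S=3.0, pp_active=False)
        assert ss.pcdh1 == pytest.approx(0.7575757576, abs=1e-8)
        assert ss.apc == pytest.approx(0.5136186770, abs=1e-8)
        assert ss.geminin == pytest.approx(0.3208104696, abs=1e-8)

    def test_stimulated_with_phosphatase(self, params):
        ss = steady_state(params, S=3.0, pp_active=True)
        assert ss.pcdh1 == pytest.approx(0.0329772817, abs=1e-8)
        assert ss.apc == pytest.approx(0.9604103468, abs=1e-8)
        assert ss.geminin == pytest.approx(0.0673775694, abs=1e-8)

    @pytest.mark.parametrize("S", [0.0, 0.5, 3.0])
    @pytest.mark.parametrize("pp_active", [True, False])
    def test_matches_long_integration(self, params, S, pp_active):
        ss = steady_state(params, S=S, pp_active=pp_active)
        if pp_active:
            proto = StimulusProtocol(mitogen_level=S, pp_onset_time=0.0)
        else:
            proto = StimulusProtocol(mitogen_level=S, phosphatase_inhibitor_time=0.0)
        traj = simulate(params, proto, t_end=200.0, output_dt=50.0)
        final = np.array([traj[v][-1] for v in ("mtor", "pp", "pcdh1", "apc", "geminin")])
        assert np.max(np.abs(final - ss.as_array())) < 1e-6


class TestSimulate:
    def test_unstimulated_closed_form(self, params):
        """With S=0 the cascade decouples and geminin follows a linear ODE."""
        proto = StimulusProtocol(mitogen_level=0.0)
        traj = simulate(params, proto, t_end=12.0, output_dt=0.1)
        assert np.allclose(traj["mtor"], 0.0, atol=1e-10)
        assert np.allclose(traj["pp"], 0.0, atol=1e-10)
        assert np.allclose(traj["pcdh1"], 0.0, atol=1e-10)
        assert np.allclose(traj["apc"], 1.0, atol=1e-10)
        g_inf = 0.064 / 1.064
        expected = g_inf * (1.0 - np.exp(-traj.times / 0.3))
        assert np.max(np.abs(traj["geminin"] - expected)) < 1e-7

    def test_apc_dip_and_recovery(self, control_traj):
        apc = control_traj["apc"]
        t = control_traj.times
        i = int(np.argmin(apc))
        assert 4.0 <= t[i] <= 4.7
        assert apc[i] == pytest.approx(0.515, abs=0.01)
        assert apc[-1] >= 0.95

    def test_geminin_pulse(self, control_traj):
        gem = control_traj["geminin"]
        t = control_traj.times
        j = int(np.argmax(gem))
        assert 4.0 < t[j] < 6.0
        assert 0.30 <= gem[j] <= 0.32
        assert gem[-1] < 0.08

    def test_agrees_with_fixed_step_reference(self, control_traj, control_ref):
        for v in ("mtor", "pp", "pcdh1", "apc", "geminin"):
            assert np.max(np.abs(control_traj[v] - control_ref[v])) <= 1e-4

    def test_bounded_in_unit_cube(self, params):
        protocols = [
            StimulusProtocol(),
            StimulusProtocol(rapamycin_time=1.0),
            StimulusProtocol(phosphatase_inhibitor_time=0.0),
            StimulusProtocol(cdh1_phospho_blocked=True),
            StimulusProtocol(mitogen_level=0.4, pp_onset_time=2.0),
        ]
        for proto in protocols:
            traj = simulate(params, proto, t_end=12.0, output_dt=0.1)
            for v in ("mtor", "pp", "pcdh1", "apc", "geminin"):
                assert np.all(traj[v] >= -1e-7)
                assert np.all(traj[v] <= 1.0 + 1e-7)

    def test_started_at_steady_state_stays_there(self, params):
        ss = steady_state(params, S=3.0, pp_active=True)
        proto = StimulusProtocol(pp_onset_time=0.0)
        traj = simulate(params, proto, initial=ss, t_end=12.0, output_dt=0.5)
        for v in ("mtor", "pp", "pcdh1", "apc", "geminin"):
            assert np.max(np.abs(traj[v] - getattr(ss, v))) < 1e-7

    def test_initial_grid_point_is_initial_state(self, control_traj):
        assert control_traj["apc"][0] == 1.0
        assert control_traj["geminin"][0] == 0.0

    def test_invalid_grid_rejected(self, params, control_protocol):
        with pytest.raises(ValueError):
            simulate(params, control_protocol, t_end=0.0)
        with pytest.raises(ValueError):
            simulate(params, control_protocol, t_end=1.0, output_dt=2.0)


class TestScenarios:
    def test_rapamycin_at_zero_keeps_apc_active(self, params):
        traj = simulate(
            params, StimulusProtocol(rapamycin_time=0.0), t_end=12.0, output_dt=0.1
        )
        assert np.all(traj["apc"] >= 0.99)

    def test_dip_depth_monotone_in_rapamycin_time(self, params):
        dips = []
        for rt in [0.0, 0.5, 1.0, 2.0, 4.0]:
            traj = simulate(
                params, StimulusProtocol(rapamycin_time=rt), t_end=12.0, output_dt=0.05
            )
            dips.append(1.0 - float(np.min(traj["apc"])))
        assert all(b >= a - 1e-9 for a, b in zip(dips, dips[1:]))
        control_dip = 1.0 - float(
            np.min(simulate(params, StimulusProtocol(), t_end=12.0, output_dt=0.05)["apc"])
        )
        assert dips[3] >= 0.9 * control_dip  # addition at 2 h barely blunts the dip

    def test_phosphatase_inhibitor_sustains_geminin(self, params):
        traj = simulate(
            params,
            StimulusProtocol(phosphatase_inhibitor_time=0.0),
            t_end=12.0,
            output_dt=0.05,
        )
        g, t = traj["geminin"], traj.times
        late = g[t >= 0.5]
        assert np.all(np.diff(late) >= -1e-8)
        assert late[-1] > 0.3

    def test_control_and_inhibitor_identical_before_onset(self, params, control_traj):
        inh = simulate(
            params,
            StimulusProtocol(phosphatase_inhibitor_time=0.0),
            t_end=12.0,
            output_dt=0.05,
        )
        mask = control_traj.times <= 4.0
        for v in ("mtor", "pp", "pcdh1", "apc", "geminin"):
            assert np.max(np.abs(control_traj[v][mask] - inh[v][mask])) < 1e-9

    def test_t129a_blocks_inactivation(self, params):
        traj = simulate(
            params,
            StimulusProtocol(cdh1_phospho_blocked=True),
            t_end=12.0,
            output_dt=0.1,
        )
        assert np.all(traj["apc"] >= 0.999)

    def test_rapamycin_clamp_variant(self, params):
        traj = simulate(
            params,
            StimulusProtocol(rapamycin_time=1.0, rapamycin_clamp=True),
            t_end=12.0,
            output_dt=0.05,
        )
        soft = simulate(
            params, StimulusProtocol(rapamycin_time=1.0), t_end=12.0, output_dt=0.05
        )
        t = traj.times
        # clamped mTOR freezes instantly; the soft variant decays through it
        after = t >= 1.05
        assert np.all(traj["mtor"][after] <= soft["mtor"][after] + 1e-9)


class TestPulseMetrics:
    def _traj(self, times, values):
        n = len(times)
        base = {v: np.zeros(n) for v in ("mtor", "pp", "pcdh1", "apc")}
        base["geminin"] = np.asarray(values, dtype=float)
        return Trajectory(
            times=np.asarray(times, dtype=float),
            values=base,
            params=KineticParameters(),
            protocol=StimulusProtocol(),
        )

    def test_monotone_series_has_no_interior_extremum(self):
        traj = self._traj([0, 1, 2, 3], [0.0, 0.1, 0.2, 0.3])
        m = pulse_metrics(traj, "geminin", mode="maximum")
        assert not m.has_interior_extremum

    def test_triangle_maximum(self):
        traj = self._traj([0, 1, 2], [0.0, 1.0, 0.0])
        m = pulse_metrics(traj, "geminin", mode="maximum")
        assert m.has_interior_extremum
        assert m.extremum_value == 1.0
        assert m.extremum_time == 1.0
        assert m.baseline == 0.0
        assert m.recovery_value == 0.0

    def test_default_geminin_peak_location(self, control_traj):
        m = pulse_metrics(control_traj, "geminin", mode="maximum")
        assert m.has_interior_extremum
        assert 4.0 < m.extremum_time < 6.0

    def test_default_apc_dip(self, control_traj):
        m = pulse_metrics(control_traj, "apc", mode="minimum")
        assert m.has_interior_extremum
        assert m.extremum_value <= m.baseline
        assert m.extremum_value <= m.recovery_value

    def test_unknown_variable_raises(self, control_traj):
        with pytest.raises(KeyError):
            pulse_metrics(control_traj, "cyclin_e")
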