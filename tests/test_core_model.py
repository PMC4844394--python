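"""Unit and property tests of the adapted Li-Rinzel ODE system."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from elicitca import ModelParameters, StimulusProtocol, simulate
from elicitca.core_model import (
    SimulationError,
    flux_chan,
    flux_leak,
    flux_pump,
    h_steady_state,
    open_probability,
    resting_state,
    rhs,
)


class TestFluxes:
    @pytest.mark.parametrize(
        "ipx,ci,h,expected",
        [
            (1e9, 1e9, 1.0, 1.0),                     # saturation of all three factors
            (0.0, 2.0, 0.5, 0.0),                     # no stimulus, channel closed
            (0.1, 0.02, 1.0, 1.0 / 64.0),             # half-saturation of both ligands
        ],
    )
    def test_open_probability(self, params, ipx, ci, h, expected):
        assert open_probability(ipx, ci, h, params) == pytest.approx(expected, abs=1e-6)

    def test_open_probability_monotone(self, params):
        base = open_probability(0.5, 0.5, 0.5, params)
        assert open_probability(0.6, 0.5, 0.5, params) > base
        assert open_probability(0.5, 0.6, 0.5, params) > base
        assert open_probability(0.5, 0.5, 0.6, params) > base

    @pytest.mark.parametrize(
        "ci,expected",
        [(0.0, 0.0), (0.4, 0.25), (2.0, 0.5 * 4.0 / 4.16)],
    )
    def test_pump(self, params, ci, expected):
        assert flux_pump(ci, params) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize(
        "ci,expected",
        [(7.5 / 1.1, 0.0), (0.0, 0.375), (2.0, 0.05 * (7.5 - 2.2))],
    )
    def test_leak(self, params, ci, expected):
        assert flux_leak(ci, params) == pytest.approx(expected, abs=1e-12)

    def test_chan_zero_cases(self, params):
        assert flux_chan(0.0, 1.0, 0.5, params) == 0.0
        assert flux_chan(1.0, params.ci_max, 0.5, params) == pytest.approx(0.0, abs=1e-12)

    def test_chan_composition(self, params):
        # independent arithmetic: p * [(1/1.1)(2/2.02)]^3 h^3 * (7.5 - 2.2)
        o = ((1 / 1.1) * (2 / 2.02)) ** 3 * 0.1562**3
        assert flux_chan(1.0, 2.0, 0.1562, params) == pytest.approx(140.0 * o * 5.3, rel=1e-12)

    @pytest.mark.parametrize(
        "ci,expected", [(0.0, 1.0), (0.04, 0.5), (2.0, 0.04 / 2.04)]
    )
    def test_h_steady_state(self, params, ci, expected):
        assert h_steady_state(ci, params) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize(
        "fn,args",
        [
            (open_probability, (-1.0, 1.0, 0.5)),
            (open_probability, (1.0, -1.0, 0.5)),
            (open_probability, (1.0, 1.0, 1.5)),
            (flux_pump, (-0.1,)),
            (flux_leak, (-0.1,)),
        ],
    )
    def test_domain_errors(self, params, fn, args):
        with pytest.raises(ValueError):
            fn(*args, params)


class TestRhs:
    def test_gate_equilibrium(self, params):
        ci = 1.3
        _, dh = rhs(0.0, (ci, h_steady_state(ci, params)), lambda t: 0.2, params)
        assert dh == pytest.approx(0.0, abs=1e-15)

    def test_unstimulated_balance_at_root(self, params):
        # 1-D bracketing oracle for the resting Ca2+ level
        f = lambda c: flux_leak(c, params) - flux_pump(c, params) + params.j_in
        root = brentq(f, 0.0, params.ci_max)
        dci, _ = rhs(0.0, (root, 0.5), lambda t: 0.0, params)
        assert dci == pytest.approx(0.0, abs=1e-10)
        ci_star, h_star = resting_state(params)
        assert ci_star == pytest.approx(root, rel=1e-9)
        assert h_star == pytest.approx(h_steady_state(root, params), rel=1e-12)

    def test_initial_condition_derivative(self, params):
        # sum of the flux oracles at (ci=2, h=0.1562, ipx=0): 0.265 - 0.480769... + 0.1
        dci, _ = rhs(0.0, (2.0, 0.1562), lambda t: 0.0, params, include_jin=True)
        assert dci == pytest.approx(0.265 - 0.5 * 4.0 / 4.16 + 0.1, rel=1e-12)
        dci_iso, _ = rhs(0.0, (2.0, 0.1562), lambda t: 0.0, params, include_jin=False)
        assert dci_iso == pytest.approx(0.265 - 0.5 * 4.0 / 4.16, rel=1e-12)

    def test_nonfinite_state_rejected(self, params):
        with pytest.raises(SimulationError):
            rhs(0.0, (np.nan, 0.5), lambda t: 0.0, params)


class TestSimulate:
    def test_single_transient_peak_scale(self, params, unit_pulse):
        """A full-amplitude 7-min stimulus drives cytosolic Ca2+ to ~6 µM."""
        traj = simulate(params, unit_pulse, (0.0, 600.0), include_jin=False)
        assert traj.peak_ci == pytest.approx(6.0, rel=0.10)
        assert 60.0 < traj.time_of_peak < 480.0

    def test_unstimulated_no_transient(self, params):
        traj = simulate(params, StimulusProtocol(()), (0.0, 600.0))
        assert traj.peak_ci <= params.ci0 + 1e-9

    def test_state_bounds_and_store(self, params, unit_pulse):
        traj = simulate(params, unit_pulse, (0.0, 600.0), include_jin=False)
        assert np.all(traj.ci >= 0)
        assert np.all((traj.h >= 0) & (traj.h <= 1))
        assert np.all(traj.cer >= 0)
        np.testing.assert_allclose(
            traj.cer, (params.c0 - traj.ci) / params.c1, rtol=1e-12
        )

    def test_flux_balance_identity(self, params, unit_pulse):
        """Finite-difference dCi/dt matches the sum of the flux decomposition."""
        traj = simulate(
            params, unit_pulse, (0.0, 600.0), include_jin=True,
            with_fluxes=True, dt_out=0.1,
        )
        total = (
            traj.fluxes["j_chan"] + traj.fluxes["j_leak"]
            - traj.fluxes["j_pump"] + traj.fluxes["j_in"]
        )
        dci = np.gradient(traj.ci, traj.times)
        interior = np.ones_like(traj.times, dtype=bool)
        for edge in unit_pulse.breakpoints():  # central differences straddle edges
            interior &= np.abs(traj.times - edge) > 0.25
        assert np.max(np.abs(dci - total)[interior]) < 5e-3

    def test_two_pulse_refractory_suppression(self, params):
        """A strong first stimulus nearly suppresses the response to a second."""
        p = params.replace(p_ipx=200.0)
        protocol = StimulusProtocol(((1.0, 60.0, 420.0), (0.5, 540.0, 420.0)))
        traj = simulate(p, protocol, (0.0, 1100.0), include_jin=False)
        pre2 = np.median(traj.ci[(traj.times >= 510) & (traj.times < 540)])
        first = traj.ci[(traj.times >= 60) & (traj.times < 540)].max()
        second = traj.ci[traj.times >= 540].max() - pre2
        assert second / first <= 0.10
        assert second / first == pytest.approx(0.0741, abs=0.02)  # regression value

    def test_equilibrate_starts_at_fixed_point(self, params):
        traj = simulate(
            params, StimulusProtocol(()), (0.0, 300.0), equilibrate=True
        )
        ci_star, _ = resting_state(params)
        assert np.max(np.abs(traj.ci - ci_star)) < 1e-5

    def test_solver_convergence(self, params, unit_pulse):
        t1 = simulate(params, unit_pulse, (0, 600), include_jin=False)
        t2 = simulate(
            params, unit_pulse, (0, 600), include_jin=False,
            rtol=5e-7, atol=5e-10,
        )
        assert abs(t2.peak_ci - t1.peak_ci) / t1.peak_ci < 1e-3

    def test_monotone_dose_response(self, params):
        peaks = [
            simulate(
                params, StimulusProtocol.single(a, 60.0, 420.0), (0, 600),
                include_jin=False,
            ).peak_ci
            for a in (0.06, 0.11, 0.25, 0.5, 1.0)
        ]
        assert np.all(np.diff(peaks) >= -1e-9)

    def test_dinh_controls_refractoriness(self, params):
        """The second/first peak ratio grows with the inactivation constant."""
        ratios = []
        protocol = StimulusProtocol(((1.0, 60.0, 420.0), (0.5, 540.0, 420.0)))
        for dinh in (0.02, 0.04, 0.08):
            p = params.replace(p_ipx=200.0, d_inh=dinh)
            traj = simulate(p, protocol, (0, 1100), include_jin=False)
            pre2 = np.median(traj.ci[(traj.times >= 510) & (traj.times < 540)])
            b0 = np.median(traj.ci[traj.times < 60])
            first = traj.ci[(traj.times >= 60) & (traj.times < 540)].max() - b0
            ratios.append((traj.ci[traj.times >= 540].max() - pre2) / first)
        assert np.all(np.diff(ratios) >= 0)

    def test_invalid_span(self, params, unit_pulse):
        with pytest.raises(ValueError):
            simulate(params, unit_pulse, (10.0, 10.0))


@settings(max_examples=20, deadline=None, derandomize=True)
@given(
    amp=st.floats(0.05, 1.0),
    duration=st.floats(30.0, 420.0),
    dinh=st.floats(0.01, 0.2),
)
def test_gate_stays_in_unit_interval(amp, duration, dinh):
    """h remains a fraction in [0, 1] for any admissible single pulse."""
    p = ModelParameters(d_inh=dinh)
    traj = simulate(
        p, StimulusProtocol.single(amp, 30.0, duration),
        (0.0, 30.0 + duration + 120.0), include_jin=False, dt_out=2.0,
    )
    assert np.all((traj.h >= 0.0) & (traj.h <= 1.0))
    assert np.all(traj.ci >= 0.0)


def test_parameter_validation():
    with pytest.raises(ValueError):
        ModelParameters(p_ipx=-1.0)
    with pytest.raises(ValueError):
        ModelParameters(c1=0.0)
    with pytest.raises(ValueError):
        ModelParameters(h0=1.5)
    with pytest.raises(ValueError):
        ModelParameters(ci0=100.0)  # above c0/(1+c1)
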