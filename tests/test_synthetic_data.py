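"""Synthetic experiment generator: transient shapes, noise, determinism."""

import numpy as np
import pytest

from elicitca.calibration import CalibrationConstants, CaTrace, luminescence_to_ca
from elicitca.synthetic_data import (
    MAX_DOSE_UM,
    DesignRow,
    SyntheticConfig,
    ca_to_luminescence,
    desensitize,
    dose_amplitude,
    dose_series_design,
    double_elicitation_design,
    generate_experiment,
    kernel_peak_time,
    make_transient,
    transient_kernel,
)


class TestDoseAmplitude:
    def test_zero_and_anchor(self, config):
        assert dose_amplitude(0.0, config) == 0.0
        assert dose_amplitude(MAX_DOSE_UM, config) == pytest.approx(
            config.peak_at_max_dose, rel=1e-12
        )

    def test_half_of_asymptote_at_ec50(self, config):
        asymptote = dose_amplitude(1e12, config)
        assert dose_amplitude(config.dose_ec50, config) == pytest.approx(
            asymptote / 2.0, rel=1e-3
        )

    def test_saturating_monotone(self, config):
        doses = np.logspace(-4, 4, 60)
        amps = [dose_amplitude(d, config) for d in doses]
        assert np.all(np.diff(amps) > 0)
        assert amps[-1] < 2 * config.peak_at_max_dose


class TestKernel:
    def test_peak_location_matches_closed_form(self, config):
        """Sampled kernel argmax agrees with the analytic t* of the
        double exponential, t* = ln(d/r) * r*d/(d - r)."""
        tau = np.linspace(0.0, 600.0, 600_001)
        k = transient_kernel(tau, config.rise_tau, config.decay_tau)
        t_star = (
            np.log(config.decay_tau / config.rise_tau)
            * config.rise_tau * config.decay_tau
            / (config.decay_tau - config.rise_tau)
        )
        assert tau[np.argmax(k)] == pytest.approx(t_star, abs=1e-2)
        assert kernel_peak_time(config.rise_tau, config.decay_tau) == pytest.approx(t_star)
        assert np.max(k) == pytest.approx(1.0, rel=1e-9)

    def test_rise_faster_than_decay(self, config):
        t_star = kernel_peak_time(config.rise_tau, config.decay_tau)
        tau = np.arange(0.0, 500.0, 0.5)
        k = transient_kernel(tau, config.rise_tau, config.decay_tau)
        rise_time = tau[np.argmax(k >= 0.5)]
        fall = tau[(k < 0.5) & (tau > t_star)]
        assert (fall[0] - t_star) > (t_star - rise_time)


class TestMakeTransient:
    def test_zero_dose_is_flat_baseline(self, config):
        ca = make_transient(0.0, 60.0, config)
        np.testing.assert_allclose(ca.ca, config.baseline_ca)

    def test_max_dose_shape_features(self, config):
        ca = make_transient(MAX_DOSE_UM, 0.0, config)
        i = int(np.argmax(ca.ca))
        assert ca.times[i] <= 120.0                       # peak within two minutes
        assert np.max(ca.ca) == pytest.approx(config.baseline_ca + 6.0, rel=1e-3)
        # decayed to 10 % of peak by ~7 min and to 5 % within another minute
        resid = ca.ca - config.baseline_ca
        assert np.all(resid[ca.times >= 420.0] <= 0.10 * 6.0)
        assert np.all(resid[ca.times >= 490.0] <= 0.05 * 6.0)
        # flat before onset + lag
        np.testing.assert_allclose(ca.ca[ca.times < config.lag], config.baseline_ca)

    def test_gaussian_noise_mode(self, rng):
        cfg = SyntheticConfig(noise_model="gaussian_ca")
        ca = make_transient(MAX_DOSE_UM, 60.0, cfg, rng)
        resid = ca.ca[ca.times < 60.0] - cfg.baseline_ca
        assert 0.0 < np.std(resid) < 5 * cfg.gaussian_sigma


class TestDesensitize:
    def test_endpoints(self, config):
        assert desensitize(0.0, config) == 1.0
        assert desensitize(MAX_DOSE_UM, config) <= 0.10

    def test_monotone_decreasing(self, config):
        doses = np.logspace(-4, np.log10(MAX_DOSE_UM), 40)
        m = [desensitize(d, config) for d in doses]
        assert np.all(np.diff(m) < 0)

    def test_over_proportional_at_low_doses(self, config):
        """A tiny first dose already costs a disproportionate share of the
        second response: suppression exceeds the first dose's own relative
        amplitude."""
        d = 0.48  # 480 nM, 1/1000 of the maximal dose
        lost = 1.0 - desensitize(d, config)
        rel_first = dose_amplitude(d, config) / dose_amplitude(MAX_DOSE_UM, config)
        assert lost > rel_first


class TestCaToLuminescence:
    def test_flat_zero_ca(self, config):
        ca = CaTrace(np.arange(10.0), np.zeros(10))
        lum = ca_to_luminescence(ca, CalibrationConstants(), config)
        assert lum.l_tot == config.aequorin_pool
        assert np.all(lum.counts > 0)       # resting aequorin still glows
        np.testing.assert_allclose(luminescence_to_ca(lum).ca, 0.0, atol=1e-12)

    def test_fixed_seed_reproducible(self, config):
        ca = make_transient(MAX_DOSE_UM, 60.0, config)
        a = ca_to_luminescence(ca, CalibrationConstants(), config, np.random.default_rng(5))
        b = ca_to_luminescence(ca, CalibrationConstants(), config, np.random.default_rng(5))
        np.testing.assert_array_equal(a.counts, b.counts)

    def test_pool_exhaustion_flagged(self):
        cfg = SyntheticConfig(aequorin_pool=50.0)
        ca = CaTrace(np.arange(100.0), np.full(100, 1000.0))  # saturating Ca2+
        lum = ca_to_luminescence(ca, CalibrationConstants(), cfg)
        assert lum.saturated


class TestGenerateExperiment:
    def test_determinism(self, config):
        e1 = generate_experiment(dose_series_design(), config)
        e2 = generate_experiment(dose_series_design(), config)
        for r1, r2 in zip(e1.traces, e2.traces):
            for a, b in zip(r1, r2):
                np.testing.assert_array_equal(a.counts, b.counts)
        assert e1.seeds == e2.seeds

    def test_empty_design(self, config):
        exp = generate_experiment([], config)
        assert exp.traces == [] and exp.truth == []

    def test_dose_series_monotone_peak_means(self, config):
        exp = generate_experiment(dose_series_design(), config)
        means = []
        for reps in exp.traces:
            peaks = [np.max(luminescence_to_ca(t).ca) for t in reps]
            means.append(np.mean(peaks))
        assert np.all(np.diff(means) > 0)
        assert all(len(r) == config.replicates for r in exp.traces)

    def test_double_elicitation_truth_scaling(self, config):
        exp = generate_experiment(double_elicitation_design(), config, noise_free=True)
        firsts = [t.peaks[0] for t in exp.truth]
        seconds = [t.peaks[1] for t in exp.truth]
        assert np.all(np.diff(firsts) > 0)    # first response grows with dose1
        assert np.all(np.diff(seconds) < 0)   # second response shrinks
        assert all(len(t.onsets) == 2 for t in exp.truth)

    def test_truth_aligned_with_traces(self, config):
        exp = generate_experiment(dose_series_design(), config)
        assert len(exp.truth) == len(exp.traces) == len(exp.design)
        for rec, reps in zip(exp.truth, exp.traces):
            for lum in reps:
                np.testing.assert_array_equal(rec.ca.times, lum.times)

    def test_invalid_design(self):
        with pytest.raises(ValueError):
            DesignRow(dose1=-1.0)
        with pytest.raises(ValueError):
            DesignRow(dose1=1.0, dose2=240.0, interval=0.0)


def test_config_validation():
    with pytest.raises(ValueError):
        SyntheticConfig(rise_tau=100.0, decay_tau=50.0)  # decay must be slower
    with pytest.raises(ValueError):
        SyntheticConfig(replicates=0)
    with pytest.raises(ValueError):
        SyntheticConfig(noise_model="bogus")
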