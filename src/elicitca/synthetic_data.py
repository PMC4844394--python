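"""Seeded synthetic stand-ins for the tobacco cell-culture experiments.

Real elicitor experiments produce luminometer count series from
aequorin-expressing cell suspensions; no such raw traces are deposited,
so this module generates realistic substitutes with recorded ground
truth.  A phenomenological transient kernel (difference of exponentials
with a dead-time lag) reproduces the documented shape features of
chitopentaose (Ch5)-induced Ca2+ transients: ~50 s onset lag, a rise
faster than the decay, time-to-peak of one to two minutes, and a total
duration of about seven minutes.  Peak amplitude follows a saturating
Hill curve of dose anchored so the maximal dose (480 µM) yields a 6 µM
peak, and a desensitization multiplier reproduces the refractory
behavior under double elicitation (a first dose suppresses the response
to a second, over-proportionally at low first doses).

Generated Ca2+ truth is pushed through the exact inverse of the aequorin
calibration (plus optional Poisson counting noise and pool depletion) so
the calibration module round-trips on noise-free output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .calibration import CalibrationConstants, CaTrace, LuminescenceTrace, ca_to_ratio
from .core_model import ModelParameters, simulate
from .stimulus import StimulusProtocol, amplitude_for_dose

__all__ = [
    "SyntheticConfig",
    "DesignRow",
    "SyntheticExperiment",
    "kernel_peak_time",
    "transient_kernel",
    "dose_amplitude",
    "make_transient",
    "desensitize",
    "ca_to_luminescence",
    "generate_experiment",
    "dose_series_design",
    "double_elicitation_design",
]

#: Largest Ch5 dose used experimentally (µM); amplitude anchor of the generator.
MAX_DOSE_UM = 480.0


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings emulating the luminometer experiments.

    Defaults encode the documented study conditions: 50 s lag, rise
    faster than decay (time-to-peak ~96 s, return to 10 % of peak by
    ~6.6 min), 6 µM peak at the 480 µM maximal dose, three replicates
    per condition, 1 s sampling.  ``baseline_ca`` is a typical plant
    resting cytosolic Ca2+ of 0.1 µM.
    """

    seed: int = 0
    baseline_ca: float = 0.1        # µM
    lag: float = 50.0               # s, elicitation -> onset dead time
    rise_tau: float = 22.0          # s
    decay_tau: float = 120.0        # s
    peak_at_max_dose: float = 6.0   # µM above baseline at 480 µM
    dose_ec50: float = 5.0          # µM
    dose_hill: float = 0.4
    desens_strength: float = 15.0
    desens_power: float = 0.25
    aequorin_pool: float = 5e6      # total dischargeable light units
    noise_model: str = "poisson_counts"   # or "gaussian_ca" / "none"
    gaussian_sigma: float = 0.02    # µM, for gaussian_ca mode
    replicates: int = 3
    dt: float = 1.0                 # s sampling interval

    def __post_init__(self) -> None:
        if self.lag < 0:
            raise ValueError("lag must be >= 0")
        if not 0 < self.rise_tau < self.decay_tau:
            raise ValueError("need 0 < rise_tau < decay_tau (rise faster than decay)")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.desens_strength < 0:
            raise ValueError("desens_strength must be >= 0")
        if self.noise_model not in ("poisson_counts", "gaussian_ca", "none"):
            raise ValueError(f"unknown noise_model {self.noise_model!r}")

    def replace(self, **changes) -> "SyntheticConfig":
        return replace(self, **changes)


def kernel_peak_time(rise_tau: float, decay_tau: float) -> float:
    """Argmax of exp(-t/decay) - exp(-t/rise): t* = ln(decay/rise)*rise*decay/(decay-rise)."""
    return (
        math.log(decay_tau / rise_tau)
        * rise_tau * decay_tau / (decay_tau - rise_tau)
    )


def transient_kernel(tau, rise_tau: float, decay_tau: float):
    """Unit-peak double-exponential transient shape, zero for tau <= 0."""
    tau = np.asarray(tau, dtype=float)
    t_peak = kernel_peak_time(rise_tau, decay_tau)
    norm = math.exp(-t_peak / decay_tau) - math.exp(-t_peak / rise_tau)
    out = np.where(
        tau > 0,
        (np.exp(-np.clip(tau, 0, None) / decay_tau)
         - np.exp(-np.clip(tau, 0, None) / rise_tau)) / norm,
        0.0,
    )
    return float(out) if out.ndim == 0 else out


def kernel_return_time(rise_tau: float, decay_tau: float, frac: float = 0.10) -> float:
    """Time after onset at which the kernel has decayed back to ``frac`` of peak."""
    t_peak = kernel_peak_time(rise_tau, decay_tau)
    f = lambda tau: transient_kernel(tau, rise_tau, decay_tau) - frac
    hi = t_peak
    while f(hi) > 0:
        hi *= 2.0
    return brentq(f, t_peak, hi, xtol=1e-9)


def dose_amplitude(dose_um: float, config: SyntheticConfig = SyntheticConfig()) -> float:
    """Peak Ca2+ amplitude (µM above baseline) for a Ch5 dose.

    Saturating Hill curve of dose, normalized so the 480 µM maximal dose
    gives exactly ``peak_at_max_dose``.
    """
    if dose_um < 0:
        raise ValueError("dose must be >= 0")
    if dose_um == 0:
        return 0.0
    hill = lambda d: d**config.dose_hill / (d**config.dose_hill + config.dose_ec50**config.dose_hill)
    return config.peak_at_max_dose * hill(dose_um) / hill(MAX_DOSE_UM)


def desensitize(dose1_um: float, config: SyntheticConfig = SyntheticConfig()) -> float:
    """Second-response amplitude multiplier after a first dose.

    ``1/(1 + s*(dose1/480 µM)^q)`` with q below the dose-response Hill
    coefficient, so a weak first elicitation already has an
    over-proportional negative effect on the second response; at the
    maximal first dose the multiplier is <= 0.1 (near-complete
    suppression).
    """
    if dose1_um < 0:
        raise ValueError("dose must be >= 0")
    return 1.0 / (1.0 + config.desens_strength * (dose1_um / MAX_DOSE_UM) ** config.desens_power)


def _time_grid(t_end: float, dt: float) -> np.ndarray:
    return np.arange(0.0, t_end + 0.5 * dt, dt)


def _transient_series(times, stimuli, config: SyntheticConfig) -> np.ndarray:
    """Noise-free Ca2+ series for (onset, amplitude) stimulus pairs."""
    ca = np.full_like(times, config.baseline_ca, dtype=float)
    for onset, amp in stimuli:
        ca = ca + amp * transient_kernel(
            times - onset - config.lag, config.rise_tau, config.decay_tau
        )
    return ca


def make_transient(
    dose_um: float,
    onset: float,
    config: SyntheticConfig = SyntheticConfig(),
    rng: np.random.Generator | None = None,
    *,
    t_end: float = 540.0,
) -> CaTrace:
    """Synthetic single-elicitation Ca2+ trace.

    Baseline before ``onset + lag``, then a double-exponential transient
    of dose-dependent amplitude.  Gaussian noise is added only when
    ``rng`` is given and ``noise_model == "gaussian_ca"``; otherwise the
    trace is the noise-free ground truth (Poisson noise lives in the
    luminescence forward model, not here).
    """
    times = _time_grid(t_end, config.dt)
    ca = _transient_series(times, [(onset, dose_amplitude(dose_um, config))], config)
    if rng is not None and config.noise_model == "gaussian_ca":
        ca = np.clip(ca + rng.normal(0.0, config.gaussian_sigma, ca.shape), 0.0, None)
    return CaTrace(times=times, ca=ca)


def ca_to_luminescence(
    ca: CaTrace,
    consts: CalibrationConstants = CalibrationConstants(),
    config: SyntheticConfig = SyntheticConfig(),
    rng: np.random.Generator | None = None,
) -> LuminescenceTrace:
    """Forward aequorin model: Ca2+ trace -> luminometer counts.

    Exact inverse of the calibration: at each sample the fraction
    ``ratio = r(Ca)^n`` of light is emitted relative to the remaining
    pool *after* the sample, i.e. ``L_i = ratio * L_rem/(1 + ratio)``,
    which makes ``L_i / (L_tot - cumsum)`` recover ``ratio`` exactly.
    With ``noise_model == "poisson_counts"`` and an ``rng``, counts are
    Poisson draws around the expectation; the pool is depleted by the
    realized counts.  ``l_tot`` is the initial pool (discharge included).
    """
    r = ca_to_ratio(np.asarray(ca.ca, dtype=float) * 1e-6, consts)
    ratio = np.atleast_1d(r) ** consts.n
    counts = np.empty_like(ratio)
    remaining = float(config.aequorin_pool)
    saturated = False
    poisson = rng is not None and config.noise_model == "poisson_counts"
    for i, q in enumerate(ratio):
        expected = q * remaining / (1.0 + q)
        c = float(rng.poisson(expected)) if poisson else expected
        c = min(c, remaining)
        counts[i] = c
        remaining -= c
        if remaining <= 0.0:
            saturated = True
            remaining = 0.0
    if remaining < 0.5:  # less than one light unit left: effectively discharged
        saturated = True
    return LuminescenceTrace(
        times=np.asarray(ca.times, dtype=float).copy(),
        counts=counts,
        l_tot=float(config.aequorin_pool),
        dt=config.dt,
        saturated=saturated,
    )


@dataclass(frozen=True)
class DesignRow:
    """One experimental condition: first dose, optional second dose, interval."""

    dose1: float                 # µM Ch5
    dose2: float | None = None   # µM Ch5, fixed across a refractory series
    interval: float = 420.0      # s between the two elicitations

    def __post_init__(self) -> None:
        if self.dose1 < 0 or (self.dose2 is not None and self.dose2 < 0):
            raise ValueError("doses must be >= 0")
        if self.dose2 is not None and self.interval <= 0:
            raise ValueError("interval must be > 0 for double elicitation")


@dataclass
class TruthRecord:
    """Per-trace ground truth: noise-free Ca2+ and per-stimulus features."""

    ca: CaTrace
    onsets: tuple[float, ...]
    peaks: tuple[float, ...]        # µM above baseline
    lag: float
    time_to_peak: float             # s after elicitation
    duration: float                 # s after elicitation (10 % return)
    baseline: float


@dataclass
class SyntheticExperiment:
    """A full synthetic experiment: design rows x replicates with truth."""

    design: tuple[DesignRow, ...]
    config: SyntheticConfig
    consts: CalibrationConstants
    traces: list[list[LuminescenceTrace]]       # [row][replicate]
    truth: list[TruthRecord]                    # one per row (noise-free)
    first_onset: float
    seeds: list[list[int]] = field(default_factory=list)

    def second_onset(self, row: int) -> float | None:
        r = self.design[row]
        return None if r.dose2 is None else self.first_onset + r.interval


def dose_series_design(doses_um: Sequence[float] = (4.8e-4, 4.8e-2, 0.48, 4.8, 48.0, 480.0)) -> list[DesignRow]:
    """Single-elicitation dose series spanning 480 pM to 480 µM."""
    return [DesignRow(dose1=d) for d in doses_um]


def double_elicitation_design(
    doses1_um: Sequence[float] = (4.8e-5, 4.8, 480.0),
    dose2_um: float = 240.0,
    interval: float = 420.0,
) -> list[DesignRow]:
    """Double-elicitation series: variable first dose, fixed 240 µM second."""
    return [DesignRow(dose1=d, dose2=dose2_um, interval=interval) for d in doses1_um]


def generate_experiment(
    design: Sequence[DesignRow],
    config: SyntheticConfig = SyntheticConfig(),
    consts: CalibrationConstants = CalibrationConstants(),
    *,
    first_onset: float = 60.0,
    noise_free: bool = False,
    truth_source: str = "kernel",
    model_params: ModelParameters | None = None,
) -> SyntheticExperiment:
    """Assemble a seeded synthetic experiment from a design table.

    Per row: a noise-free ground-truth Ca2+ trace (kernel transients, the
    second scaled by :func:`desensitize`; or, with
    ``truth_source="model"``, an adapted Li-Rinzel simulation driven via
    the dose->amplitude anchor table), converted per replicate to
    luminometer counts with independent child seeds.
    ``noise_free=True`` produces expectation-valued counts.
    """
    design = tuple(design)
    rows: list[list[LuminescenceTrace]] = []
    truths: list[TruthRecord] = []
    seeds: list[list[int]] = []
    ss = np.random.SeedSequence(config.seed)
    row_seqs = ss.spawn(len(design)) if design else []

    ttp = kernel_peak_time(config.rise_tau, config.decay_tau)
    dur = kernel_return_time(config.rise_tau, config.decay_tau, 0.10)

    for row, row_seq in zip(design, row_seqs):
        onsets = [first_onset]
        amps = [dose_amplitude(row.dose1, config)]
        if row.dose2 is not None:
            onsets.append(first_onset + row.interval)
            amps.append(dose_amplitude(row.dose2, config) * desensitize(row.dose1, config))
            t_end = onsets[-1] + 420.0 + config.lag  # 15 min run for double rows
        else:
            t_end = first_onset + 480.0
        times = _time_grid(t_end, config.dt)

        if truth_source == "model":
            params = model_params or ModelParameters()
            protocol = StimulusProtocol(
                tuple(
                    (min(amplitude_for_dose(d), 1.0), o, 420.0)
                    for d, o in zip(
                        [row.dose1] + ([row.dose2] if row.dose2 is not None else []),
                        onsets,
                    )
                )
            )
            traj = simulate(params, protocol, (0.0, t_end), include_jin=False,
                            dt_out=config.dt)
            ca_truth = np.interp(times, traj.times, traj.ci)
        elif truth_source == "kernel":
            ca_truth = _transient_series(times, list(zip(onsets, amps)), config)
        else:
            raise ValueError(f"unknown truth_source {truth_source!r}")

        truth_trace = CaTrace(times=times, ca=ca_truth)
        truths.append(
            TruthRecord(
                ca=truth_trace,
                onsets=tuple(onsets),
                peaks=tuple(amps) if truth_source == "kernel" else
                      (float(np.max(ca_truth) - ca_truth[0]),),
                lag=config.lag,
                time_to_peak=config.lag + ttp,
                duration=config.lag + dur,
                baseline=config.baseline_ca,
            )
        )

        rep_traces: list[LuminescenceTrace] = []
        rep_seeds: list[int] = []
        for child in row_seq.spawn(config.replicates):
            seed_val = int(child.generate_state(1)[0] % (2**31))
            rep_seeds.append(seed_val)
            rng = None if noise_free else np.random.default_rng(child)
            ca = truth_trace
            if rng is not None and config.noise_model == "gaussian_ca":
                ca = CaTrace(
                    times=times,
                    ca=np.clip(
                        ca_truth + rng.normal(0.0, config.gaussian_sigma, times.shape),
                        0.0, None,
                    ),
                )
            rep_traces.append(ca_to_luminescence(ca, consts, config, rng))
        rows.append(rep_traces)
        seeds.append(rep_seeds)

    return SyntheticExperiment(
        design=design, config=config, consts=consts,
        traces=rows, truth=truths, first_onset=first_onset, seeds=seeds,
    )
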