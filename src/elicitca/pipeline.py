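"""Analysis stages over Ca2+ traces: features, dose-response, refractory.

Operational definitions (thresholds are configurable and declared here,
since the descriptive quantities — lag, time-to-peak, duration — have no
standard definition for these transients):

* baseline: median of the pre-elicitation window;
* onset: first post-elicitation sample exceeding
  ``baseline + max(onset_frac * peak_above_baseline, noise_k * MAD)``;
* duration: elicitation to the first post-peak return below
  ``baseline + return_frac * peak_above_baseline``;
* second responses in double-elicitation runs are measured relative to
  the level immediately before the second stimulus, because the first
  transient has almost, but not exactly, returned to baseline by then.

Aggregation over replicates is mean ± standard deviation throughout; the
underlying experiments report descriptive statistics only.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import CalibrationConstants, CaTrace, luminescence_to_ca
from .core_model import ModelParameters, Trajectory, simulate
from .stimulus import StimulusProtocol
from .synthetic_data import (
    SyntheticConfig,
    SyntheticExperiment,
    dose_series_design,
    double_elicitation_design,
    generate_experiment,
)

__all__ = [
    "TraceFeatures",
    "FeatureThresholds",
    "extract_features",
    "dose_response",
    "refractory_analysis",
    "compare_trace",
    "run_protocol",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class FeatureThresholds:
    """Detection thresholds for :func:`extract_features`."""

    onset_frac: float = 0.05     # fraction of peak-above-baseline
    return_frac: float = 0.10
    noise_k: float = 3.0         # multiples of baseline MAD
    min_peak: float = 0.0        # µM above baseline below which: no response


@dataclass(frozen=True)
class TraceFeatures:
    """Descriptive features of one Ca2+ transient (times in s, Ca in µM).

    ``lag``, ``time_to_peak`` and ``duration`` are measured from the
    elicitation time.  ``responded`` is False for flat traces, in which
    case peak is 0 and the timing features are NaN.
    """

    baseline: float
    lag: float
    time_to_peak: float
    peak: float
    duration: float
    responded: bool = True


def extract_features(
    trace: CaTrace,
    elicitation_time: float,
    thresholds: FeatureThresholds = FeatureThresholds(),
    *,
    baseline_window: tuple[float, float] | None = None,
    t_end: float | None = None,
) -> TraceFeatures:
    """Extract lag / time-to-peak / peak / duration from a Ca2+ trace.

    ``baseline_window`` defaults to everything before the elicitation;
    ``t_end`` restricts the analysis window (used to stop a first-response
    analysis before a second stimulus).
    """
    t = np.asarray(trace.times, dtype=float)
    ca = np.asarray(trace.ca, dtype=float)
    if t_end is not None:
        keep = t <= t_end
        t, ca = t[keep], ca[keep]
    if elicitation_time < t[0] or elicitation_time > t[-1]:
        raise ValueError("trace does not cover the elicitation time")

    if baseline_window is None:
        base_mask = t < elicitation_time
    else:
        base_mask = (t >= baseline_window[0]) & (t < baseline_window[1])
    if not np.any(base_mask):
        raise ValueError("empty baseline window before elicitation")
    base_vals = ca[base_mask]
    baseline = float(np.median(base_vals))
    mad = float(np.median(np.abs(base_vals - baseline)))

    post = t >= elicitation_time
    tp, cap = t[post], ca[post]
    i_peak = int(np.argmax(cap))
    peak_above = float(cap[i_peak] - baseline)

    threshold = baseline + max(
        thresholds.onset_frac * max(peak_above, 0.0), thresholds.noise_k * mad
    )
    above = cap > threshold
    if peak_above <= thresholds.min_peak or not np.any(above):
        return TraceFeatures(
            baseline=baseline, lag=float("nan"), time_to_peak=float("nan"),
            peak=0.0, duration=float("nan"), responded=False,
        )

    i_onset = int(np.argmax(above))
    lag = float(tp[i_onset] - elicitation_time)
    time_to_peak = float(tp[i_peak] - elicitation_time)

    return_level = baseline + thresholds.return_frac * peak_above
    after_peak = cap[i_peak:] < return_level
    if np.any(after_peak):
        duration = float(tp[i_peak + int(np.argmax(after_peak))] - elicitation_time)
    else:
        duration = float(tp[-1] - elicitation_time)
    return TraceFeatures(
        baseline=baseline, lag=lag, time_to_peak=time_to_peak,
        peak=peak_above, duration=duration, responded=True,
    )


def _calibrated_traces(
    experiment: SyntheticExperiment, row: int
) -> list[tuple[int, CaTrace]]:
    """Calibrate every replicate of a row, logging and skipping failures."""
    out: list[tuple[int, CaTrace]] = []
    for rep, lum in enumerate(experiment.traces[row]):
        try:
            out.append((rep, luminescence_to_ca(lum, experiment.consts)))
        except ValueError as err:  # saturation / discharge inconsistency
            log.warning("row %d replicate %d excluded: %s", row, rep, err)
    return out


def dose_response(experiment: SyntheticExperiment) -> pd.DataFrame:
    """Peak response (mean ± sd over replicates) per dose.

    Calibrates every replicate luminescence trace to Ca2+, extracts the
    peak above baseline, and aggregates.  Columns: dose_um, mean_peak_um,
    sd_peak_um, n.
    """
    rows = []
    for i, drow in enumerate(experiment.design):
        peaks = []
        for _rep, ca in _calibrated_traces(experiment, i):
            f = extract_features(ca, experiment.first_onset)
            peaks.append(f.peak)
        if not peaks:
            raise ValueError(f"no calibratable replicates for dose {drow.dose1}")
        rows.append(
            {
                "dose_um": drow.dose1,
                "mean_peak_um": float(np.mean(peaks)),
                "sd_peak_um": float(np.std(peaks, ddof=0)),
                "n": len(peaks),
            }
        )
    return pd.DataFrame(rows).sort_values("dose_um", ignore_index=True)


def refractory_analysis(
    experiment: SyntheticExperiment, *, pre_window: float = 30.0
) -> pd.DataFrame:
    """First- and second-response peaks per first dose (second dose fixed).

    The second response is measured relative to the level in the
    ``pre_window`` seconds before the second stimulus.  Columns:
    dose1_um, dose2_um, first_mean_um, first_sd_um, second_mean_um,
    second_sd_um, n.
    """
    dose2s = {r.dose2 for r in experiment.design}
    if None in dose2s:
        raise ValueError("refractory analysis requires a second stimulus in every row")
    if len(dose2s) != 1:
        raise ValueError(f"second dose must be constant across rows, got {sorted(dose2s)}")

    rows = []
    for i, drow in enumerate(experiment.design):
        t2 = experiment.second_onset(i)
        firsts, seconds = [], []
        for _rep, ca in _calibrated_traces(experiment, i):
            f1 = extract_features(ca, experiment.first_onset, t_end=t2)
            f2 = extract_features(
                ca, t2, baseline_window=(t2 - pre_window, t2)
            )
            firsts.append(f1.peak)
            seconds.append(f2.peak)
        rows.append(
            {
                "dose1_um": drow.dose1,
                "dose2_um": drow.dose2,
                "first_mean_um": float(np.mean(firsts)),
                "first_sd_um": float(np.std(firsts, ddof=0)),
                "second_mean_um": float(np.mean(seconds)),
                "second_sd_um": float(np.std(seconds, ddof=0)),
                "n": len(firsts),
            }
        )
    return pd.DataFrame(rows).sort_values("dose1_um", ignore_index=True)


def compare_trace(simulated: Trajectory, measured: CaTrace) -> dict[str, float]:
    """Compare a simulated trajectory against a measured/synthetic Ca2+ trace.

    Peaks and their times are taken on each series' own support; the RMSE
    is computed on the overlapping time window after linear resampling of
    both onto its grid.
    """
    ts, cs = np.asarray(simulated.times, float), np.asarray(simulated.ci, float)
    tm, cm = np.asarray(measured.times, float), np.asarray(measured.ca, float)
    lo, hi = max(ts[0], tm[0]), min(ts[-1], tm[-1])
    if hi <= lo:
        raise ValueError("simulated and measured traces have disjoint time ranges")
    grid = np.linspace(lo, hi, 512)
    rmse = float(
        np.sqrt(np.mean((np.interp(grid, ts, cs) - np.interp(grid, tm, cm)) ** 2))
    )
    peak_s, peak_m = float(np.max(cs)), float(np.max(cm))
    tp_s = float(ts[int(np.argmax(cs))])
    tp_m = float(tm[int(np.argmax(cm))])
    return {
        "peak_error_um": peak_s - peak_m,
        "peak_error_rel": (peak_s - peak_m) / peak_m if peak_m else float("inf"),
        "time_to_peak_error_s": tp_s - tp_m,
        "rmse_um": rmse,
    }


def run_protocol(config: dict, out_dir: str | Path, seed: int | None = None) -> dict:
    """Config-driven dispatcher over the analysis stages.

    ``config["task"]`` selects the stage (``simulate``, ``synth``,
    ``dose_response``, ``refractory``); remaining keys override defaults.
    Writes CSV/JSON artifacts under ``out_dir`` and returns a manifest of
    what was written.  Entry point behind the numbered analysis scripts.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    task = config.get("task")
    manifest: dict = {"task": task, "outputs": []}

    def _write_df(df: pd.DataFrame, name: str) -> None:
        p = out_dir / name
        df.to_csv(p, index=False)
        manifest["outputs"].append(str(p))

    if task == "simulate":
        params = ModelParameters(**config.get("params", {}))
        protocol = StimulusProtocol.from_dicts(
            config.get(
                "pulses",
                [{"amplitude": 1.0, "onset_s": 60.0, "duration_s": 420.0}],
            )
        )
        t_span = tuple(config.get("t_span", (0.0, 600.0)))
        traj = simulate(
            params, protocol, t_span,
            include_jin=config.get("include_jin", True), with_fluxes=True,
        )
        from .io import write_trajectory

        p = out_dir / "trajectory.csv"
        write_trajectory(traj, p, protocol=protocol)
        manifest["outputs"] += [str(p), str(p.with_suffix(".json"))]
        manifest["peak_ci_um"] = traj.peak_ci
    elif task in ("synth", "dose_response", "refractory"):
        cfg_kw = dict(config.get("synthetic", {}))
        if seed is not None:
            cfg_kw["seed"] = seed
        cfg = SyntheticConfig(**cfg_kw)
        if task == "refractory":
            design = double_elicitation_design(**config.get("design", {}))
        else:
            design = dose_series_design(**config.get("design", {}))
        exp = generate_experiment(
            design, cfg, noise_free=config.get("noise_free", False),
            truth_source=config.get("truth_source", "kernel"),
        )
        if task == "dose_response":
            _write_df(dose_response(exp), "dose_response.csv")
        elif task == "refractory":
            _write_df(refractory_analysis(exp), "refractory.csv")
        else:
            from .io import write_luminometer_csv

            for i, reps in enumerate(exp.traces):
                for j, lum in enumerate(reps):
                    p = out_dir / f"trace_row{i}_rep{j}.csv"
                    write_luminometer_csv(lum, p)
                    manifest["outputs"].append(str(p))
        manifest["seeds"] = exp.seeds
    else:
        raise ValueError(f"unknown task {task!r}")

    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
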