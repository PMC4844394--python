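"""Adapted Li-Rinzel model of elicitor-induced cytosolic Ca2+ release.

The model is a two-variable reduction of the De Young-Keizer IP3-receptor
scheme, adapted to a plant cell in which the vacuole is the internal Ca2+
store and an unidentified inositol-phosphate species ("IPx") gates the
release channels.  State variables are the cytosolic Ca2+ concentration
``Ci`` (µM) and the slow channel-inactivation gate ``h`` (dimensionless,
fraction of channels not inactivated by Ca2+).

The cytosolic Ca2+ balance is

    dCi/dt = J_chan + J_leak - J_pump (+ J_in)

with

    J_chan = p_ipx * O(IPx, Ci, h) * (C0 - (1 + c1) * Ci)
    O      = (IPx/(IPx + d_ipx))^3 * (Ci/(Ci + d_act))^3 * h^3
    J_leak = p_l * (C0 - (1 + c1) * Ci)
    J_pump = v_store * Ci^2 / (k_store^2 + Ci^2)

and the gate relaxes towards its Ca2+-dependent equilibrium

    dh/dt = a * (Ci + d_inh) * (d_inh/(Ci + d_inh) - h).

``C0 = Ci + c1 * CER`` is the conserved total Ca2+ concentration, ``c1``
the store/cytosol volume ratio, so the store content is
``CER = (C0 - Ci)/c1``.  Cytosolic Ca2+ buffering is deliberately not
modeled.  ``J_in`` is a small constant plasma-membrane influx; setting it
to zero describes an isolated cell.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, fields, replace
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

__all__ = [
    "ModelParameters",
    "ModelState",
    "Trajectory",
    "SimulationError",
    "open_probability",
    "flux_pump",
    "flux_leak",
    "flux_chan",
    "h_steady_state",
    "rhs",
    "resting_state",
    "simulate",
]


class SimulationError(RuntimeError):
    """Raised when the ODE solver fails or produces non-physical output."""


@dataclass(frozen=True)
class ModelParameters:
    """Parameter set of the adapted Li-Rinzel system.

    Defaults are the values used for the plant-cell (tobacco) simulations;
    time in seconds, concentrations in µM (arbitrary units in origin).

    Attributes
    ----------
    p_ipx : float
        Maximal permeability of the store membrane through the
        IPx-gated release channels (s^-1).
    p_l : float
        Leak permeability of the store membrane (s^-1).
    v_store : float
        Maximal Ca2+ uptake rate of the store pump (µM s^-1).
    k_store : float
        Pump activation constant (µM).
    d_ipx : float
        IPx dissociation constant of the release channel (µM).
    d_act : float
        Ca2+-activation dissociation constant (µM).
    d_inh : float
        Ca2+-inactivation dissociation constant (µM); controls the
        refractory behavior under repeated stimulation.
    a : float
        Time-scale parameter of the inactivation gate (s^-1 µM^-1 in
        effect, printed as s^-1).
    c0 : float
        Conserved total Ca2+ concentration (µM).
    c1 : float
        Store/cytosol volume ratio (0.1 ~ plant vacuole/cytosol).
    j_in : float
        Constant plasma-membrane Ca2+ influx (µM s^-1).
    ci0, h0 : float
        Initial cytosolic Ca2+ (µM) and gate value.
    """

    p_ipx: float = 140.0
    p_l: float = 0.05
    v_store: float = 0.5
    k_store: float = 0.4
    d_ipx: float = 0.1
    d_act: float = 0.02
    d_inh: float = 0.04
    a: float = 0.001
    c0: float = 7.5
    c1: float = 0.1
    j_in: float = 0.1
    ci0: float = 2.0
    h0: float = 0.1562

    def __post_init__(self) -> None:
        positive = (
            "p_ipx", "p_l", "v_store", "k_store",
            "d_ipx", "d_act", "d_inh", "a", "c0",
        )
        for name in positive:
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)!r}")
        if self.j_in < 0:
            raise ValueError(f"j_in must be >= 0, got {self.j_in!r}")
        if not 0 < self.c1 <= 1:
            raise ValueError(f"c1 must be in (0, 1], got {self.c1!r}")
        if not 0 <= self.h0 <= 1:
            raise ValueError(f"h0 must be in [0, 1], got {self.h0!r}")
        if not 0 <= self.ci0 <= self.ci_max:
            raise ValueError(
                f"ci0 must be in [0, c0/(1+c1)={self.ci_max:g}], got {self.ci0!r}"
            )

    @property
    def ci_max(self) -> float:
        """Cytosolic Ca2+ at which the store gradient vanishes, C0/(1+c1)."""
        return self.c0 / (1.0 + self.c1)

    def replace(self, **changes: float) -> "ModelParameters":
        return replace(self, **changes)

    def to_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "ModelParameters":
        return cls(**d)


@dataclass(frozen=True)
class ModelState:
    """Instantaneous model state: time (s), cytosolic Ca2+ (µM), gate h."""

    t: float
    ci: float
    h: float

    def __post_init__(self) -> None:
        if self.ci < 0:
            raise ValueError(f"ci must be >= 0, got {self.ci!r}")
        if not 0.0 <= self.h <= 1.0:
            raise ValueError(f"h must be in [0, 1], got {self.h!r}")


def _check_nonneg(name: str, value: float) -> None:
    if np.any(np.asarray(value) < 0):
        raise ValueError(f"{name} must be non-negative")


def open_probability(ipx, ci, h, params: ModelParameters):
    """Equilibrium open probability of the IPx-gated release channel.

    ``O = (IPx/(IPx+d_ipx))^3 * (Ci/(Ci+d_act))^3 * h^3`` — cooperative
    binding of IPx and of activating Ca2+ (CICR), each with a Hill-like
    cubic, gated by the slow inactivation variable h.
    """
    _check_nonneg("ipx", ipx)
    _check_nonneg("ci", ci)
    if np.any(np.asarray(h) < 0) or np.any(np.asarray(h) > 1):
        raise ValueError("h must be in [0, 1]")
    ipx = np.asarray(ipx, dtype=float)
    ci = np.asarray(ci, dtype=float)
    m = np.divide(ipx, ipx + params.d_ipx, out=np.zeros_like(ipx), where=ipx + params.d_ipx > 0)
    n = np.divide(ci, ci + params.d_act, out=np.zeros_like(ci), where=ci + params.d_act > 0)
    out = (m * n) ** 3 * np.asarray(h, dtype=float) ** 3
    return float(out) if out.ndim == 0 else out


def flux_pump(ci, params: ModelParameters):
    """SERCA-like store pump flux, Hill kinetics of order 2 (µM s^-1)."""
    _check_nonneg("ci", ci)
    ci = np.asarray(ci, dtype=float)
    out = params.v_store * ci**2 / (params.k_store**2 + ci**2)
    return float(out) if out.ndim == 0 else out


def flux_leak(ci, params: ModelParameters):
    """Passive leak down the store gradient: p_l*(C0 - (1+c1)*Ci) (µM s^-1)."""
    _check_nonneg("ci", ci)
    ci = np.asarray(ci, dtype=float)
    out = params.p_l * (params.c0 - (1.0 + params.c1) * ci)
    return float(out) if out.ndim == 0 else out


def flux_chan(ipx, ci, h, params: ModelParameters):
    """Release flux through the IPx-gated channels (µM s^-1)."""
    o = open_probability(ipx, ci, h, params)
    ci = np.asarray(ci, dtype=float)
    out = params.p_ipx * o * (params.c0 - (1.0 + params.c1) * ci)
    return float(out) if np.ndim(out) == 0 else out


def h_steady_state(ci, params: ModelParameters):
    """Equilibrium of the inactivation gate, h_inf = d_inh/(Ci + d_inh)."""
    _check_nonneg("ci", ci)
    ci = np.asarray(ci, dtype=float)
    out = params.d_inh / (ci + params.d_inh)
    return float(out) if out.ndim == 0 else out


def rhs(
    t: float,
    state: Sequence[float],
    stimulus: Callable[[float], float],
    params: ModelParameters,
    include_jin: bool = True,
) -> tuple[float, float]:
    """Time derivatives (dCi/dt, dh/dt) at time ``t``.

    ``stimulus`` maps time (s) to the normalized IPx amplitude, which is
    used directly as the IPx concentration in µM.  With ``include_jin``
    false the constant plasma-membrane influx is omitted (isolated cell).
    """
    ci, h = float(state[0]), float(state[1])
    if not (np.isfinite(ci) and np.isfinite(h)):
        raise SimulationError(f"non-finite state at t={t}: ci={ci}, h={h}")
    ipx = float(stimulus(t))
    # clip transient solver excursions below 0 / outside [0,1]
    ci_c = max(ci, 0.0)
    h_c = min(max(h, 0.0), 1.0)
    dci = (
        flux_chan(ipx, ci_c, h_c, params)
        + flux_leak(ci_c, params)
        - flux_pump(ci_c, params)
    )
    if include_jin:
        dci += params.j_in
    dh = params.a * (ci_c + params.d_inh) * (h_steady_state(ci_c, params) - h)
    return dci, dh


@dataclass
class Trajectory:
    """Simulated time course on a uniform output grid.

    ``fluxes`` (optional) carries the per-time decomposition with keys
    ``j_chan``, ``j_leak``, ``j_pump``, ``j_in`` (µM s^-1).
    """

    times: np.ndarray
    ci: np.ndarray
    h: np.ndarray
    stimulus: np.ndarray
    fluxes: dict[str, np.ndarray] | None = None
    params: ModelParameters | None = None
    cer: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        n = len(self.times)
        for name in ("ci", "h", "stimulus"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length must match times")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.cer is None and self.params is not None:
            self.cer = (self.params.c0 - self.ci) / self.params.c1

    @property
    def peak_ci(self) -> float:
        return float(np.max(self.ci))

    @property
    def time_of_peak(self) -> float:
        return float(self.times[int(np.argmax(self.ci))])


def resting_state(
    params: ModelParameters, include_jin: bool = True
) -> tuple[float, float]:
    """Unstimulated fixed point (ci*, h*) of the system.

    With no stimulus J_chan = 0, so ci* is the root of
    J_leak(ci) - J_pump(ci) (+ J_in) = 0 on [0, c0/(1+c1)] and
    h* = h_inf(ci*).
    """

    def f(ci: float) -> float:
        v = flux_leak(ci, params) - flux_pump(ci, params)
        return v + params.j_in if include_jin else v

    ci_star = brentq(f, 0.0, params.ci_max, xtol=1e-12, rtol=1e-14)
    return float(ci_star), h_steady_state(ci_star, params)


def simulate(
    params: ModelParameters,
    stimulus,
    t_span: tuple[float, float],
    *,
    include_jin: bool = True,
    equilibrate: bool = False,
    rtol: float = 1e-6,
    atol: float = 1e-9,
    dt_out: float = 0.5,
    max_step: float = np.inf,
    with_fluxes: bool = False,
) -> Trajectory:
    """Integrate the model over ``t_span`` under a stimulus protocol.

    Integration uses an adaptive explicit Runge-Kutta pair (Dormand-
    Prince, scipy ``RK45``) restarted at every stimulus edge so the
    solver never steps across a pulse discontinuity.  Output is sampled
    on a uniform grid of spacing ``dt_out``.

    Parameters
    ----------
    stimulus : callable or StimulusProtocol
        Maps time (s) to the normalized IPx amplitude; if it exposes a
        ``breakpoints()`` method (as StimulusProtocol does) those times
        delimit the integration segments.
    equilibrate : bool
        If true, relax the unstimulated system to its resting state
        first and start the run from there instead of (ci0, h0).
    """
    t0, t1 = float(t_span[0]), float(t_span[1])
    if not t1 > t0:
        raise ValueError("t_span must be increasing")

    y0 = np.array([params.ci0, params.h0], dtype=float)
    if equilibrate:
        y0 = np.asarray(resting_state(params, include_jin=include_jin), dtype=float)

    edges = [t0, t1]
    if hasattr(stimulus, "breakpoints"):
        edges += [float(b) for b in stimulus.breakpoints() if t0 < b < t1]
    edges = sorted(set(edges))

    times = np.arange(t0, t1 + 0.5 * dt_out, dt_out)
    times = times[times <= t1 + 1e-9]
    ci_out = np.empty_like(times)
    h_out = np.empty_like(times)

    y = y0
    for a, b in zip(edges[:-1], edges[1:]):
        sol = solve_ivp(
            rhs,
            (a, b),
            y,
            args=(stimulus, params, include_jin),
            method="RK45",
            rtol=rtol,
            atol=atol,
            max_step=max_step,
            dense_output=True,
        )
        if not sol.success:
            raise SimulationError(
                f"solver failed on [{a:g}, {b:g}]: {sol.message}"
            )
        mask = (times >= a - 1e-9) & (times <= b + 1e-9)
        seg = sol.sol(np.clip(times[mask], a, b))
        ci_out[mask] = seg[0]
        h_out[mask] = seg[1]
        y = sol.y[:, -1]

    ci_out = np.clip(ci_out, 0.0, None)
    h_out = np.clip(h_out, 0.0, 1.0)
    if np.max(ci_out) > params.ci_max * (1.0 + 1e-3):
        warnings.warn(
            f"ci exceeded the store-gradient ceiling c0/(1+c1)={params.ci_max:g} µM",
            RuntimeWarning,
            stacklevel=2,
        )

    stim_out = np.array([float(stimulus(t)) for t in times])
    fluxes = None
    if with_fluxes:
        fluxes = {
            "j_chan": flux_chan(stim_out, ci_out, h_out, params),
            "j_leak": flux_leak(ci_out, params),
            "j_pump": flux_pump(ci_out, params),
            "j_in": np.full_like(times, params.j_in if include_jin else 0.0),
        }
    return Trajectory(
        times=times, ci=ci_out, h=h_out, stimulus=stim_out,
        fluxes=fluxes, params=params,
    )
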