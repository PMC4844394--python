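"""Normalized IPx stimulus protocols and the Ch5 transfer function.

The receptor-to-store signaling chain (elicitor recognition, phospholipase
C activity, inositol-phosphate production) is treated as a black box: the
model is driven by a normalized stimulus amplitude in [0, 1], and a fitted
transfer function ``y(x) = A*(x - x0)^p`` converts that amplitude into the
chitopentaose (Ch5) concentration applied in an experiment.

Two amplitude<->dose pathways are provided, because the fitted formula and
the figure-caption anchor points are not mutually consistent (the formula
gives y(1) ~ 6.7 mM, while the captions equate amplitude 1 with 480 µM):

* :class:`TransferFunction` — the fitted power law, with its inverse;
* :data:`REFERENCE_PAIRS` — the caption anchor points (480 pM .. 480 µM),
  interpolated on log-dose, used by default when emulating experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "Pulse",
    "StimulusProtocol",
    "TransferFunction",
    "REFERENCE_PAIRS",
    "evaluate_stimulus",
    "transfer_forward",
    "transfer_inverse",
    "fit_transfer",
    "amplitude_for_dose",
    "dose_for_amplitude",
]


@dataclass(frozen=True)
class Pulse:
    """One rectangular stimulus pulse: amplitude in [0,1], onset and duration in s."""

    amplitude: float
    onset: float
    duration: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.amplitude <= 1.0:
            raise ValueError(f"amplitude must be in [0, 1], got {self.amplitude!r}")
        if self.duration <= 0:
            raise ValueError(f"duration must be > 0, got {self.duration!r}")

    @property
    def end(self) -> float:
        return self.onset + self.duration


@dataclass(frozen=True)
class StimulusProtocol:
    """A train of non-overlapping pulses with an optional linear edge ramp.

    With ``ramp > 0`` each pulse rises linearly over ``ramp`` seconds from
    its onset and falls linearly over ``ramp`` seconds ending at
    ``onset + duration``; ``ramp = 0`` (default) gives ideal rectangles.
    """

    pulses: tuple[Pulse, ...]
    ramp: float = 0.0

    def __post_init__(self) -> None:
        pulses = tuple(
            p if isinstance(p, Pulse) else Pulse(*p) for p in self.pulses
        )
        object.__setattr__(self, "pulses", pulses)
        if self.ramp < 0:
            raise ValueError("ramp must be >= 0")
        prev_end = -np.inf
        for p in pulses:
            if p.onset < prev_end:
                raise ValueError("pulses must be non-overlapping and ordered by onset")
            if self.ramp > 0 and 2 * self.ramp > p.duration:
                raise ValueError("ramp exceeds half the pulse duration")
            prev_end = p.end

    @classmethod
    def single(
        cls, amplitude: float = 1.0, onset: float = 60.0,
        duration: float = 420.0, ramp: float = 0.0,
    ) -> "StimulusProtocol":
        return cls((Pulse(amplitude, onset, duration),), ramp=ramp)

    def breakpoints(self) -> list[float]:
        """Times at which the stimulus is non-smooth (solver restart points)."""
        out: list[float] = []
        for p in self.pulses:
            if self.ramp > 0:
                out += [p.onset, p.onset + self.ramp, p.end - self.ramp, p.end]
            else:
                out += [p.onset, p.end]
        return sorted(set(out))

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        for p in self.pulses:
            if self.ramp > 0:
                up = np.clip((t - p.onset) / self.ramp, 0.0, 1.0)
                down = np.clip((p.end - t) / self.ramp, 0.0, 1.0)
                shape = np.minimum(up, down) * ((t >= p.onset) & (t < p.end))
            else:
                shape = ((t >= p.onset) & (t < p.end)).astype(float)
            out = out + p.amplitude * shape
        return float(out) if out.ndim == 0 else out

    def to_dicts(self) -> list[dict[str, float]]:
        return [
            {"amplitude": p.amplitude, "onset_s": p.onset, "duration_s": p.duration}
            for p in self.pulses
        ]

    @classmethod
    def from_dicts(cls, dicts, ramp: float = 0.0) -> "StimulusProtocol":
        return cls(
            tuple(Pulse(d["amplitude"], d["onset_s"], d["duration_s"]) for d in dicts),
            ramp=ramp,
        )


def evaluate_stimulus(protocol: StimulusProtocol, t):
    """Normalized stimulus amplitude at time ``t`` (s)."""
    return protocol(t)


@dataclass(frozen=True)
class TransferFunction:
    """Fitted power law mapping normalized amplitude x to Ch5 dose (µM).

    ``y = A*(x - x0)^p`` for x > x0, else 0.  Defaults are the Ch5 fit
    (A = 8328.75, x0 = 0.06, p = 3.57).
    """

    scale: float = 8328.75
    offset: float = 0.06
    power: float = 3.57

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be > 0")
        if not 0.0 <= self.offset < 1.0:
            raise ValueError("offset must be in [0, 1)")
        if self.power <= 0:
            raise ValueError("power must be > 0")

    def forward(self, x):
        return transfer_forward(x, self)

    def inverse(self, y):
        return transfer_inverse(y, self)


def transfer_forward(x, tf: TransferFunction = TransferFunction()):
    """Ch5 dose for normalized amplitude x; 0 at or below the threshold x0."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0) or np.any(x > 1):
        raise ValueError("normalized amplitude must be in [0, 1]")
    out = np.where(x > tf.offset, tf.scale * np.clip(x - tf.offset, 0, None) ** tf.power, 0.0)
    return float(out) if out.ndim == 0 else out


def transfer_inverse(y, tf: TransferFunction = TransferFunction()):
    """Normalized amplitude for Ch5 dose y; inverse of :func:`transfer_forward`.

    ``x = x0 + (y/A)^(1/p)``; y = 0 maps to the threshold x0.  Doses above
    the calibrated range (x > 1) raise ValueError.
    """
    y = np.asarray(y, dtype=float)
    if np.any(y < 0):
        raise ValueError("dose must be >= 0")
    x = tf.offset + (y / tf.scale) ** (1.0 / tf.power)
    if np.any(x > 1.0 + 1e-12):
        raise ValueError("dose exceeds the calibrated range (x > 1)")
    out = np.clip(x, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def fit_transfer(pairs) -> TransferFunction:
    """Least-squares fit of (A, x0, p) to (amplitude, dose) pairs.

    Minimizes squared error in log-dose: sum_i (ln y_i - ln A - p*ln(x_i - x0))^2.
    A coarse grid over the threshold x0 (closed-form A, p at each candidate)
    seeds a bounded Levenberg-Marquardt-style refinement.
    """
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValueError("need at least 3 (amplitude, dose) pairs")
    x, y = arr[:, 0], arr[:, 1]
    keep = y > 0
    x, y = x[keep], y[keep]
    if len(x) < 3 or len(np.unique(x)) < 3:
        raise ValueError("need >= 3 distinct amplitudes with positive dose")
    logy = np.log(y)
    xmin = float(np.min(x))

    def closed_form(x0: float) -> tuple[float, float, float]:
        lx = np.log(x - x0)
        A = np.vstack([np.ones_like(lx), lx]).T
        coef, res, rank, _ = np.linalg.lstsq(A, logy, rcond=None)
        sse = float(res[0]) if res.size else float(np.sum((A @ coef - logy) ** 2))
        return coef[0], coef[1], sse

    candidates = np.linspace(0.0, 0.999 * xmin, 200)
    best = min(candidates, key=lambda x0: closed_form(x0)[2])
    la0, p0, _ = closed_form(best)
    if p0 <= 0:
        raise ValueError("degenerate pairs: fitted power is not positive")

    def resid(theta):
        la, x0, p = theta
        return la + p * np.log(np.clip(x - x0, 1e-12, None)) - logy

    sol = least_squares(
        resid,
        x0=[la0, best, p0],
        bounds=([-np.inf, 0.0, 1e-6], [np.inf, 0.999 * xmin, np.inf]),
    )
    if not sol.success:
        raise ValueError(f"transfer-function fit failed: {sol.message}")
    la, x0, p = sol.x
    return TransferFunction(scale=float(np.exp(la)), offset=float(x0), power=float(p))


#: Caption anchor points (normalized amplitude, Ch5 dose in µM) tying the
#: two-pulse protocols to experimental doses: 1 <-> 480 µM, 0.5 <-> 240 µM,
#: 0.11 <-> 480 nM, 0.06 <-> 480 pM.
REFERENCE_PAIRS: tuple[tuple[float, float], ...] = (
    (0.06, 4.8e-4),
    (0.11, 0.48),
    (0.5, 240.0),
    (1.0, 480.0),
)


def amplitude_for_dose(dose_um: float) -> float:
    """Normalized amplitude for a Ch5 dose via the caption anchor points.

    Piecewise-linear interpolation of amplitude against log10(dose) between
    the anchors; exact at the anchors, clamped to [0, 1] outside them.
    Doses at or below zero map to amplitude 0.
    """
    if dose_um < 0:
        raise ValueError("dose must be >= 0")
    if dose_um == 0:
        return 0.0
    xs = np.array([p[0] for p in REFERENCE_PAIRS])
    ds = np.log10([p[1] for p in REFERENCE_PAIRS])
    return float(np.clip(np.interp(np.log10(dose_um), ds, xs), 0.0, 1.0))


def dose_for_amplitude(amplitude: float) -> float:
    """Ch5 dose (µM) for a normalized amplitude via the caption anchors."""
    if not 0.0 <= amplitude <= 1.0:
        raise ValueError("amplitude must be in [0, 1]")
    xs = np.array([p[0] for p in REFERENCE_PAIRS])
    ds = np.log10([p[1] for p in REFERENCE_PAIRS])
    if amplitude <= xs[0]:
        return 0.0 if amplitude < xs[0] else float(10 ** ds[0])
    return float(10 ** np.interp(amplitude, xs, ds))
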