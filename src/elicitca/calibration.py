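"""Aequorin luminescence <-> cytosolic Ca2+ calibration.

Aequorin-expressing cells emit light as a function of cytosolic Ca2+.  At
the end of an experiment the remaining photoprotein is fully discharged
with excess CaCl2, giving the total dischargeable light ``L_tot``.  The
remaining pool at sample ``i`` is

    L_max,i = L_tot - (L_1 + L_2 + ... + L_i)

and the ratiometric quantity ``r_i = (L_i / L_max,i)^(1/n)`` maps to the
absolute Ca2+ concentration (model B of the aequorin calibration
literature):

    Ca (M) = (r + r*K_TR - 1) / (K_R * (1 - r))

with constants K_R = 7.23e6 M^-1, K_TR = 120 and n = 2.99.  ``r`` values
at or above 1 mean the reporter is exhausted (saturation); ``r`` below
1/(1+K_TR) would give negative concentrations and is clamped to zero
(below detection).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CalibrationConstants",
    "LuminescenceTrace",
    "CaTrace",
    "SaturationError",
    "DischargeError",
    "lmax_series",
    "ratio_to_ca",
    "ca_to_ratio",
    "luminescence_to_ca",
]

_R_POLE = 1.0 - 1e-12


class SaturationError(ValueError):
    """The aequorin pool is exhausted (L_i/L_max ratio at or above 1)."""


class DischargeError(ValueError):
    """Cumulative counts exceed the recorded total discharge light."""


@dataclass(frozen=True)
class CalibrationConstants:
    """Empirical constants of the aequorin Ca2+-light relationship."""

    k_r: float = 7.23e6   # M^-1
    k_tr: float = 120.0
    n: float = 2.99

    def __post_init__(self) -> None:
        for name in ("k_r", "k_tr", "n"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def r_floor(self) -> float:
        """r at which the calibrated Ca2+ is exactly zero, 1/(1+K_TR)."""
        return 1.0 / (1.0 + self.k_tr)


@dataclass
class LuminescenceTrace:
    """Luminometer read-out: per-interval counts plus the discharge total."""

    times: np.ndarray
    counts: np.ndarray
    l_tot: float
    dt: float = 1.0
    saturated: bool = False

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.times.shape != self.counts.shape:
            raise ValueError("times and counts must have the same shape")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.l_tot < np.sum(self.counts) - 1e-6 * max(self.l_tot, 1.0):
            raise DischargeError("l_tot must be >= sum(counts)")


@dataclass
class CaTrace:
    """Cytosolic Ca2+ concentration series in µM."""

    times: np.ndarray
    ca: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.ca = np.asarray(self.ca, dtype=float)
        if self.times.shape != self.ca.shape:
            raise ValueError("times and ca must have the same shape")
        if not np.all(np.isfinite(self.ca)) or np.any(self.ca < 0):
            raise ValueError("ca must be finite and non-negative")


def lmax_series(trace: LuminescenceTrace) -> np.ndarray:
    """Remaining dischargeable light after each sample: L_tot - cumsum(counts)."""
    lmax = trace.l_tot - np.cumsum(trace.counts)
    if np.any(lmax < -1e-6 * max(trace.l_tot, 1.0)):
        i = int(np.argmax(lmax < 0))
        raise DischargeError(
            f"cumulative counts exceed l_tot at sample {i} (L_max={lmax[i]:g})"
        )
    return np.clip(lmax, 0.0, None)


def ratio_to_ca(r, consts: CalibrationConstants = CalibrationConstants()):
    """Ca2+ concentration in M for the ratiometric quantity r = (L/L_max)^(1/n).

    Negative numerators (r below 1/(1+K_TR), i.e. below-detection light)
    are clamped to 0.  r at or above 1 raises :class:`SaturationError`.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("r must be non-negative")
    if np.any(r >= _R_POLE):
        raise SaturationError("r at or above 1: aequorin exhausted")
    ca = (r + r * consts.k_tr - 1.0) / (consts.k_r * (1.0 - r))
    out = np.clip(ca, 0.0, None)
    return float(out) if out.ndim == 0 else out


def ca_to_ratio(ca_m, consts: CalibrationConstants = CalibrationConstants()):
    """Inverse of :func:`ratio_to_ca`: r = (1 + K_R*Ca) / (1 + K_TR + K_R*Ca)."""
    ca_m = np.asarray(ca_m, dtype=float)
    if np.any(ca_m < 0):
        raise ValueError("ca must be non-negative")
    out = (1.0 + consts.k_r * ca_m) / (1.0 + consts.k_tr + consts.k_r * ca_m)
    return float(out) if out.ndim == 0 else out


def luminescence_to_ca(
    trace: LuminescenceTrace,
    consts: CalibrationConstants = CalibrationConstants(),
) -> CaTrace:
    """Convert a luminometer trace to cytosolic Ca2+ in µM.

    Pipeline per sample: counts -> L_max,i -> r_i = (L_i/L_max,i)^(1/n)
    -> Ca (M) -> µM.  Raises :class:`SaturationError` with the offending
    sample index if the pool is exhausted mid-trace.
    """
    lmax = lmax_series(trace)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(lmax > 0, trace.counts / np.where(lmax > 0, lmax, 1.0), np.inf)
    ratio = np.where((trace.counts == 0) & (lmax == 0), np.inf, ratio)
    bad = ratio**(1.0 / consts.n) >= _R_POLE
    if np.any(bad):
        raise SaturationError(
            f"aequorin pool exhausted at sample {int(np.argmax(bad))}"
        )
    r = ratio ** (1.0 / consts.n)
    ca_um = ratio_to_ca(r, consts) * 1e6
    return CaTrace(times=trace.times.copy(), ca=np.atleast_1d(ca_um))
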