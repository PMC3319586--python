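"""Sampled periodic waveforms (flow, pressure, wall distension)."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

__all__ = ["Waveform"]


@dataclass(frozen=True)
class Waveform:
    """One cardiac cycle (or more) of a sampled signal.

    ``time_s`` must be strictly increasing.  The signal is treated as
    periodic with period ``time_s[-1] - time_s[0]`` when sampled outside
    its support.  Units of ``values`` are whatever the caller declares
    (ml/s for flow, mmHg for pressure, mm for diameter).
    """

    time_s: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.time_s, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or t.shape != v.shape or t.size < 2:
            raise ValidationError("waveform needs matching 1-d time/value arrays (>= 2 samples)")
        if not np.all(np.diff(t) > 0):
            raise ValidationError("waveform time axis must be strictly increasing")
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "values", v)

    @property
    def period_s(self) -> float:
        return float(self.time_s[-1] - self.time_s[0])

    def mean(self) -> float:
        """Time average over the sampled support (trapezoidal)."""
        return float(np.trapezoid(self.values, self.time_s) / self.period_s)

    def sample(self, t) -> np.ndarray:
        """Periodic linear interpolation at arbitrary times."""
        t0 = self.time_s[0]
        tau = np.mod(np.asarray(t, dtype=float) - t0, self.period_s)
        return np.interp(tau, self.time_s - t0, self.values)

    def scaled(self, factor: float) -> "Waveform":
        return Waveform(self.time_s, self.values * factor)
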