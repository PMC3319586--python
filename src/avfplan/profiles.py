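"""Piecewise-linear diameter profiles from discrete duplex stations.

Duplex ultrasound yields vessel diameters at a handful of axial stations;
the lumped discretization needs a diameter at every segment midpoint.
Missing positions are obtained by linear inter-/extrapolation between the
measured stations, with a constant fallback when only a single station is
available and a positive floor to guard against aggressive extrapolation.
"""

from __future__ import annotations

from typing import Sequence, Tuple

import numpy as np

from .errors import MissingMeasurementError, ValidationError

#: extrapolated diameters never fall below this (mm)
DIAMETER_FLOOR_MM = 0.5


def interpolate_diameters(
    stations: Sequence[Tuple[float, float]],
    vessel_length: float,
    *,
    floor_mm: float = DIAMETER_FLOOR_MM,
    vessel_name: str = "vessel",
):
    """Return ``f(position_cm) -> diameter_mm`` from measured stations.

    Piecewise linear between stations, linear extrapolation beyond the
    outermost pair (continuing the end slope), constant when a single
    station exists.  Results are floored at ``floor_mm``.
    """
    if len(stations) == 0:
        raise MissingMeasurementError(vessel_name)
    pts = sorted((float(p), float(d)) for p, d in stations)
    pos = np.array([p for p, _ in pts])
    dia = np.array([d for _, d in pts])
    if np.any(dia <= 0):
        raise ValidationError(f"{vessel_name}: non-positive station diameter")
    if pos[0] < -1e-9 or pos[-1] > vessel_length + 1e-9:
        raise ValidationError(f"{vessel_name}: station outside [0, length]")

    if len(pts) == 1:
        const = float(dia[0])

        def profile_const(x):
            return np.maximum(np.full_like(np.asarray(x, dtype=float), const), floor_mm)

        return profile_const

    def profile(x):
        x = np.asarray(x, dtype=float)
        y = np.interp(x, pos, dia)
        # extend the outermost slopes beyond the measured range
        lo = x < pos[0]
        hi = x > pos[-1]
        if np.any(lo):
            s = (dia[1] - dia[0]) / (pos[1] - pos[0])
            y = np.where(lo, dia[0] + s * (x - pos[0]), y)
        if np.any(hi):
            s = (dia[-1] - dia[-2]) / (pos[-1] - pos[-2])
            y = np.where(hi, dia[-1] + s * (x - pos[-1]), y)
        return np.maximum(y, floor_mm)

    return profile
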