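"""Latin-Hypercube Monte-Carlo propagation of input-parameter uncertainty.

Every uncertain input is given a uniform distribution over
``nominal +/- half-width`` (absolute or relative).  A Latin-Hypercube design
guarantees that, per parameter, the ``n`` samples occupy all ``n``
equal-probability strata exactly once.  Each sample is mapped onto a
:class:`~avfplan.personalize.Perturbation`, run through the full prediction
pipeline, and the resulting flow distribution is summarized by its median
and 25th-75th percentile interval (computed over converged runs only, with
linear interpolation between order statistics).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
from scipy.stats import qmc

from .errors import AvfPlanError, ValidationError
from .personalize import (
    ANASTOMOSIS_ANGLE_BOUNDS_DEG,
    DEFAULT_ANASTOMOSIS_ANGLE_DEG,
    DEFAULT_OPTIONS,
    Perturbation,
    PersonalizationOptions,
)
from .pipeline import predict_postop_flow
from .records import PatientRecord
from .solver import DEFAULT_CONTROLS, SolverControls

__all__ = [
    "UncertainParameter",
    "UncertaintySpec",
    "default_uncertainty_spec",
    "FlowDistribution",
    "lhs_sample",
    "run_monte_carlo",
]

#: perturbation fields a parameter path may address
_PATHS = (
    "artery_diameter_scale",
    "vein_diameter_scale",
    "length_scale",
    "youngs_modulus_scale",
    "windkessel_resistance_scale",
    "leak_resistance_scale",
    "anastomosis_angle_deg",
    "venous_pressure_mmhg",
)


@dataclass(frozen=True)
class UncertainParameter:
    """One uniform uncertainty band: nominal +/- half-width."""

    path: str
    nominal: float
    half_width: float
    relative: bool = False  # half-width as a fraction of the nominal

    def __post_init__(self):
        if self.path not in _PATHS:
            raise ValidationError(f"unknown parameter path: {self.path!r}")
        if self.half_width < 0:
            raise ValidationError("half-width must be non-negative")

    @property
    def bounds(self):
        hw = self.half_width * abs(self.nominal) if self.relative else self.half_width
        return self.nominal - hw, self.nominal + hw


@dataclass(frozen=True)
class UncertaintySpec:
    parameters: Sequence[UncertainParameter]

    def __post_init__(self):
        paths = [p.path for p in self.parameters]
        if len(paths) != len(set(paths)):
            raise ValidationError("duplicate parameter paths in uncertainty spec")


def default_uncertainty_spec() -> UncertaintySpec:
    """Default uncertainty bands for the Monte-Carlo layer.

    Diameters: +/-10 % arterial, +/-20 % venous; lengths +/-10 %; Young's
    moduli +/-20 %; windkessel resistances +/-20 %; leakage resistance
    +/-50 %; anastomosis angle uniform over the surgical 30-60 degree range;
    venous pressure +/-5 mmHg.
    """
    lo, hi = ANASTOMOSIS_ANGLE_BOUNDS_DEG
    return UncertaintySpec((
        UncertainParameter("artery_diameter_scale", 1.0, 0.10, relative=True),
        UncertainParameter("vein_diameter_scale", 1.0, 0.20, relative=True),
        UncertainParameter("length_scale", 1.0, 0.10, relative=True),
        UncertainParameter("youngs_modulus_scale", 1.0, 0.20, relative=True),
        UncertainParameter("windkessel_resistance_scale", 1.0, 0.20, relative=True),
        UncertainParameter("leak_resistance_scale", 1.0, 0.50, relative=True),
        UncertainParameter("anastomosis_angle_deg",
                           DEFAULT_ANASTOMOSIS_ANGLE_DEG, (hi - lo) / 2.0),
        UncertainParameter("venous_pressure_mmhg", 10.0, 5.0),
    ))


def lhs_sample(spec: UncertaintySpec, n_runs: int, seed: int) -> List[Dict[str, float]]:
    """Draw ``n_runs`` Latin-Hypercube parameter sets.

    Per parameter the unit interval is cut into ``n_runs`` equal strata and
    each stratum receives exactly one sample; degenerate bands (half-width
    zero) collapse onto the nominal.
    """
    if n_runs < 2:
        raise ValidationError("Latin-Hypercube sampling needs n_runs >= 2")
    params = list(spec.parameters)
    sampler = qmc.LatinHypercube(d=len(params), seed=int(seed))
    u = sampler.random(n=n_runs)
    out = []
    for row in u:
        entry = {}
        for uj, p in zip(row, params):
            lo, hi = p.bounds
            entry[p.path] = lo + uj * (hi - lo)
        out.append(entry)
    return out


def _to_perturbation(sample: Dict[str, float]) -> Perturbation:
    return Perturbation(**sample)


@dataclass
class FlowDistribution:
    """Monte-Carlo distribution of the predicted postoperative flow."""

    configuration: str
    flows_ml_min: np.ndarray   # per requested run; NaN where not converged
    n_requested: int
    n_converged: int
    median: Optional[float]
    p25: Optional[float]
    p75: Optional[float]
    seed: int

    @property
    def simulable(self) -> bool:
        return self.n_converged > 0

    @classmethod
    def from_flows(cls, configuration: str, flows, seed: int) -> "FlowDistribution":
        flows = np.asarray(flows, dtype=float)
        ok = flows[np.isfinite(flows)]
        if ok.size:
            med, p25, p75 = (float(np.percentile(ok, q)) for q in (50, 25, 75))
        else:
            med = p25 = p75 = None
        return cls(configuration=configuration, flows_ml_min=flows,
                   n_requested=int(flows.size), n_converged=int(ok.size),
                   median=med, p25=p25, p75=p75, seed=int(seed))


def run_monte_carlo(record: PatientRecord, configuration: str,
                    spec: Optional[UncertaintySpec] = None,
                    n_runs: int = 256, seed: int = 0, *,
                    options: PersonalizationOptions = DEFAULT_OPTIONS,
                    controls: SolverControls = DEFAULT_CONTROLS
                    ) -> FlowDistribution:
    """Propagate input uncertainty through the flow prediction.

    One simulation per Latin-Hypercube parameter set; runs whose
    personalization or simulation fails (or does not converge) are counted
    but excluded from the percentiles.  Identical parameter sets (all
    half-widths zero) are computed once and reused, so the degenerate spec
    costs a single simulation.
    """
    spec = spec or default_uncertainty_spec()
    samples = lhs_sample(spec, n_runs, seed)
    flows = np.full(n_runs, np.nan)
    cache: Dict[tuple, float] = {}
    for i, sample in enumerate(samples):
        key = tuple(sorted(sample.items()))
        if key in cache:
            flows[i] = cache[key]
            continue
        try:
            pred = predict_postop_flow(record, configuration,
                                       perturbation=_to_perturbation(sample),
                                       options=options, controls=controls)
            value = (pred.mean_brachial_flow_ml_min
                     if pred.converged and pred.baroreflex_restored else math.nan)
        except AvfPlanError:
            value = math.nan
        cache[key] = value
        flows[i] = value
    return FlowDistribution.from_flows(configuration, flows, seed)
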