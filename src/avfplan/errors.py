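"""Exception types raised across the package."""


class AvfPlanError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(AvfPlanError, ValueError):
    """An input violates a documented invariant."""


class IncompleteDomainError(AvfPlanError):
    """A vessel required by the requested configuration is missing.

    Mirrors the clinical situation where a vein cannot be visualized
    preoperatively (for example pre-existing thrombosis of the cephalic
    vein), making some fistula configurations unsimulable.
    """

    def __init__(self, vessel_name: str):
        self.vessel_name = vessel_name
        super().__init__(f"incomplete domain: {vessel_name}")


class MissingMeasurementError(AvfPlanError):
    """A vessel has no diameter station at all."""

    def __init__(self, vessel_name: str):
        self.vessel_name = vessel_name
        super().__init__(f"missing vessel measurement: {vessel_name}")


class UnknownVesselError(AvfPlanError, KeyError):
    """A vessel identifier is not one of the modeled vessels."""


class InconsistentMeasurementsError(AvfPlanError):
    """Measured flows/pressures cannot be reconciled with the network.

    Raised e.g. when the serial resistance of the modeled upstream segments
    already exceeds the total resistance implied by MAP and a measured mean
    flow, which would require a negative peripheral resistance.
    """


class RigidVesselError(AvfPlanError):
    """Zero wall distension over the cardiac cycle (would imply infinite E)."""


class SimulationError(AvfPlanError):
    """Numerical failure while integrating the network equations."""
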