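"""Exception hierarchy shared across the package."""


class VentBenchError(Exception):
    """Base class for all package-specific errors."""


class InvalidSettingsError(VentBenchError, ValueError):
    """Ventilator settings violate a physical or protocol constraint."""


class InfeasibleVentilationError(VentBenchError, ValueError):
    """Tidal volume does not exceed total dead space: no alveolar ventilation,
    hence no CO2 clearance is possible at these settings."""


class OutOfDomainError(VentBenchError, ValueError):
    """Input outside the model's domain (e.g. an EtCO2 ratio below 1,
    which would imply a device that removes dead space)."""


class UnitConfusionError(VentBenchError, ValueError):
    """A quantity was plausibly passed in the wrong unit (e.g. tidal volume
    in millilitres where litres are required)."""


class TitrationError(VentBenchError, RuntimeError):
    """EtCO2 could not be returned to the target band within the step budget.

    Carries the partial trajectory in :attr:`trajectory` as a list of
    ``(setting_value, etco2)`` pairs.
    """

    def __init__(self, message, trajectory=None):
        super().__init__(message)
        self.trajectory = list(trajectory or [])
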