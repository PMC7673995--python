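"""Exception hierarchy for the drug-combination prediction pipeline."""


class DrugComboError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(DrugComboError):
    """An input table is missing a mandatory column or has an invalid layout."""


class InputError(DrugComboError):
    """An input value or table violates a precondition (empty, non-positive, out of range)."""


class ConfigurationError(DrugComboError):
    """A configuration object is internally inconsistent (e.g. conflicting identifier mappings)."""


class FitError(DrugComboError):
    """A dose-response curve could not be fit (too few distinct concentrations, etc.)."""


class ComponentLookupError(DrugComboError, KeyError):
    """A treatment component (drug, concentration) is absent from the panel."""

    def __str__(self) -> str:  # KeyError quotes its repr; keep the message readable
        return Exception.__str__(self)


class InsufficientDataError(DrugComboError):
    """Fewer complete-case cell lines than the configured minimum.

    Carries the observed count in ``n_available`` and the requested
    minimum in ``min_lines``.
    """

    def __init__(self, message: str, n_available: int, min_lines: int):
        super().__init__(message)
        self.n_available = n_available
        self.min_lines = min_lines


class OrientationError(DrugComboError):
    """A panel orientation incompatible with the requested model (Bliss needs viability)."""


class RangeError(DrugComboError):
    """A requested concentration exceeds the extrapolation limit for a drug."""


class UndefinedHazardRatioError(DrugComboError):
    """Control mean hazard is zero, so the hazard ratio is undefined."""


class ConsistencyError(DrugComboError):
    """Two predictions that must share a cell-line set do not."""


class BootstrapFailureError(DrugComboError):
    """The bootstrapped statistic failed in more than half the simulations."""

    def __init__(self, message: str, n_failed: int, n_sims: int):
        super().__init__(message)
        self.n_failed = n_failed
        self.n_sims = n_sims
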