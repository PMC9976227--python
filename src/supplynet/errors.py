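"""Exception hierarchy.

All package-raised errors derive from :class:`SupplyNetError` so callers can
catch a single base class; subclasses map one-to-one onto the failure modes of
the public operations.
"""


class SupplyNetError(Exception):
    """Base class for all supplynet errors."""


class ConfigurationError(SupplyNetError):
    """Bad configuration: missing columns, unknown formats, invalid regimes."""


class ParameterError(SupplyNetError):
    """A scalar argument is outside its admissible range."""


class EmptyNetworkError(SupplyNetError):
    """Requested year (or node restriction) yields no flows at all."""


class UndefinedDensityError(SupplyNetError):
    """Density is undefined for networks with fewer than two nodes."""


class DegenerateShareError(SupplyNetError):
    """Trade shares are undefined when the grand total is zero."""


class InsufficientSupportError(SupplyNetError):
    """Distribution fitting needs at least two distinct degree values."""


class UndefinedModularityError(SupplyNetError):
    """Modularity is undefined for graphs with zero total edge weight."""


class InfeasibleClassificationError(SupplyNetError):
    """Fewer distinct values than requested classes."""


class DegenerateRangeError(SupplyNetError):
    """Equal-interval breaks need max > min."""


class IndicatorError(SupplyNetError):
    """Missing or invalid GDP / CRI indicator data.

    ``countries`` lists the offending country codes when applicable.
    """

    def __init__(self, message: str, countries: list[str] | None = None):
        super().__init__(message)
        self.countries = list(countries or [])


class UndefinedConcentrationError(SupplyNetError):
    """Import concentration is undefined for an importer with zero imports."""


class UnattainableDensityError(SupplyNetError):
    """Threshold calibration cannot reach the requested density.

    ``attainable`` carries the (min, max) achievable density range.
    """

    def __init__(self, message: str, attainable: tuple[float, float]):
        super().__init__(message)
        self.attainable = attainable
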