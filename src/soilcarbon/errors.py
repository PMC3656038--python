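"""Exception hierarchy for soilcarbon."""


class SoilCarbonError(Exception):
    """Base class for all soilcarbon errors."""


class ParameterError(SoilCarbonError, ValueError):
    """Invalid model parameter (negative rate, fraction outside [0, 1], ...)."""


class StateError(SoilCarbonError, ValueError):
    """Invalid pool state (negative or non-finite carbon density)."""


class InputError(SoilCarbonError, ValueError):
    """Invalid forcing or observation input."""


class ConfigError(SoilCarbonError, ValueError):
    """Invalid run configuration file."""


class UnknownRegionError(SoilCarbonError, KeyError):
    """Region name absent from a lookup table."""


class NoSteadyStateError(SoilCarbonError, ArithmeticError):
    """The daily map admits no finite steady state for the given forcing."""


class NumericError(SoilCarbonError, ArithmeticError):
    """A numerical search failed to converge."""


class UndefinedStatisticError(SoilCarbonError, ValueError):
    """An evaluation statistic is undefined for the given data."""
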