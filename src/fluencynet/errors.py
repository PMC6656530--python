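"""Exception hierarchy shared across the package."""


class FluencyNetError(Exception):
    """Base class for all package-specific errors."""


class FormatError(FluencyNetError, ValueError):
    """A data file violates the expected on-disk format."""


class EstimationError(FluencyNetError, RuntimeError):
    """Network or parameter estimation could not produce a finite result."""


class UndefinedMeasureError(FluencyNetError, ValueError):
    """A network measure is undefined for the given graph (e.g. C_rand = 0)."""


class DegenerateDataError(FluencyNetError, ValueError):
    """Input data are degenerate for the requested statistic."""
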