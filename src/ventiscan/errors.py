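"""Exception hierarchy for ventiscan."""


class VentiscanError(Exception):
    """Base class for all ventiscan errors."""


class ConfigurationError(VentiscanError):
    """A variable map, config file, or scenario is invalid."""


class DataError(VentiscanError):
    """An input file violates the half-hourly flux dialect."""


class TimestampParseError(DataError):
    """A TIMESTAMP_START cell could not be parsed as YYYYMMDDHHMM."""


class UndefinedCorrelationError(VentiscanError):
    """Correlation is undefined (constant input or zero residual variance).

    Distinct from a correlation of zero: the statistic has no value at all,
    and the detector maps it to "not a ventilation episode".
    """


class IllConditionedError(VentiscanError):
    """Covariate rank columns are collinear; carries the offending names."""

    def __init__(self, columns):
        self.columns = tuple(columns)
        super().__init__(
            "collinear covariate rank columns: " + ", ".join(self.columns)
        )
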