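"""Exception hierarchy shared by all modules."""


class MirEnsembleError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(MirEnsembleError):
    """Table structure does not match the declared predictor schema."""


class ParseError(MirEnsembleError):
    """A cell or label could not be interpreted under its column's dialect."""


class EmptyTableError(MirEnsembleError):
    """A score table with zero data rows."""


class FitError(MirEnsembleError):
    """A transform could not be fitted (e.g. no finite values in a column)."""


class DomainError(MirEnsembleError):
    """A value outside the mathematical domain of a transform (e.g. log of a negative)."""


class RankError(MirEnsembleError):
    """Too few samples for the requested decomposition (N <= M)."""


class DegenerateCovarianceError(MirEnsembleError):
    """PCA requested on data with zero total variance."""


class DivergenceError(MirEnsembleError):
    """Network training produced a non-finite loss."""


class UndefinedMetricError(MirEnsembleError):
    """Confusion counts for which the requested metric is undefined."""
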