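"""Exception hierarchy for mrmediate."""


class MRMediateError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MRMediateError):
    """Invalid configuration: missing column mappings, bad thresholds, etc."""


class DataError(MRMediateError):
    """Malformed or unusable input data (empty file, duplicate ids, ...)."""


class InsufficientInstruments(MRMediateError):
    """Too few instruments for the requested method (e.g. Egger needs >= 3)."""


class CollinearityError(MRMediateError):
    """Rank-deficient exposure matrix in multivariable estimation."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(
            "exposure beta matrix is rank deficient; offending columns: "
            + ", ".join(self.columns)
        )


class ConvergenceError(MRMediateError):
    """An iterative optimiser failed to converge at the stated tolerance."""


class SelectionFailure(MRMediateError):
    """MR-Lasso found no penalty level admitting a usable valid set."""
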