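"""Exception hierarchy.

All package-raised errors derive from :class:`GblueError` so callers can
catch the whole family; most also derive from the matching builtin
(``ValueError`` for bad inputs) so generic handling keeps working.
"""


class GblueError(Exception):
    """Base class for all errors raised by gblue."""


class ConfigurationError(GblueError, ValueError):
    """Invalid simulation or scan configuration."""


class DimensionError(GblueError, ValueError):
    """Non-conformable array dimensions."""


class RankDeficiencyError(GblueError, ValueError):
    """A design matrix does not have full column rank.

    Carries ``dependent_columns``: indices (into the offending matrix's
    columns) that are numerically linearly dependent on the others.
    """

    def __init__(self, message: str, dependent_columns=None):
        super().__init__(message)
        self.dependent_columns = list(dependent_columns or [])


class SingularDowndateError(GblueError):
    """The Woodbury down-date capacitance matrix is numerically singular."""

    def __init__(self, message: str, condition_number: float | None = None):
        super().__init__(message)
        self.condition_number = condition_number


class NumericalDegeneracyError(GblueError):
    """A quantity that should be positive definite is not, within tolerance."""


class ParseError(GblueError, ValueError):
    """Malformed genotype/phenotype/config file."""


class SampleJoinError(GblueError, ValueError):
    """Sample identifiers do not match between genotype and phenotype inputs.

    Carries ``offenders``: the IDs present in one input but not the other.
    """

    def __init__(self, message: str, offenders=None):
        super().__init__(message)
        self.offenders = list(offenders or [])
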