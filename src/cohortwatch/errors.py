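"""Exception hierarchy shared across the pipeline.

Exit-code mapping used by the CLI: ConfigError -> 2, data validation -> 3,
statistical failures -> 4.
"""


class CohortWatchError(Exception):
    """Base class for all pipeline errors."""


class ConfigError(CohortWatchError):
    """Invalid or inconsistent study configuration."""


class SchemaError(CohortWatchError):
    """Input table does not match the declared schema."""


class ValidationError(CohortWatchError):
    """A row violates a field-level invariant (bad date, unknown enum value)."""


class StructuralError(CohortWatchError):
    """Internal consistency violation (cycle in the cohort tree, negative time)."""


class SeparationError(CohortWatchError):
    """Perfect separation in logistic regression."""


class RankDeficiencyError(CohortWatchError):
    """Design matrix is rank deficient."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(f"collinear columns: {', '.join(self.columns)}")


class ConvergenceError(CohortWatchError):
    """An iterative fit diverged or failed to converge."""
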