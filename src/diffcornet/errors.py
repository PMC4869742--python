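"""Exception hierarchy.

Exit-code mapping used by the command line interface:
config/schema problems -> 2, input/output problems -> 3,
numerical/statistical problems -> 4.
"""


class DiffcornetError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigError(DiffcornetError):
    """Invalid configuration, schema, or partition definition."""

    exit_code = 2


class DataValidationError(DiffcornetError):
    """Malformed or inconsistent input data."""

    exit_code = 3


class ZeroVarianceError(DiffcornetError):
    """A metabolite has no variance where variance is required."""

    exit_code = 4

    def __init__(self, metabolite: str, context: str = "standardize"):
        self.metabolite = metabolite
        super().__init__(
            f"metabolite {metabolite!r} has zero variance ({context})"
        )


class SaturatedCorrelationError(DiffcornetError):
    """|r| >= 1 where a finite Fisher z is required."""

    exit_code = 4


class InsufficientSamplesError(DiffcornetError):
    """Too few samples for the requested computation."""

    exit_code = 4
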