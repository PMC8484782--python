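"""Exception hierarchy for the telqpcr pipeline.

Every stage raises a subclass of :class:`TelqpcrError` so that the CLI can map
failures onto exit codes (2 = configuration, 3 = data) without string matching.
"""


class TelqpcrError(Exception):
    """Base class for all telqpcr errors."""


class ConfigError(TelqpcrError):
    """Invalid configuration (thresholds, layouts, infeasible correlation targets)."""


class FormatError(TelqpcrError):
    """A file does not conform to the documented CSV layout (e.g. missing column)."""


class DataError(TelqpcrError):
    """Well-formed file with inconsistent content (duplicates, cycles out of order,
    cyclic parentage, unknown tissue labels)."""


class InsufficientDataError(DataError):
    """Too few observations for the requested computation."""


class InvalidCurveError(DataError):
    """A standard curve with non-negative slope: efficiency undefined."""


class WindowFailureError(DataError):
    """No fluorescence band satisfies the window-of-linearity constraints for
    enough reactions in an amplicon group."""

    def __init__(self, message, offending_reactions=()):
        super().__init__(message)
        self.offending_reactions = list(offending_reactions)


class AggregationError(DataError):
    """An efficiency aggregation scope is empty after exclusions."""


class QCError(DataError):
    """A sample failed replicate quality control."""


class PairingError(DataError):
    """T and S plates cannot be paired as required."""


class LayoutError(ConfigError):
    """A synthetic plate layout exceeds the physical well count."""
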