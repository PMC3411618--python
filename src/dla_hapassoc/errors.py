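"""Exception hierarchy for the pipeline.

Each error class maps to a distinct nonzero exit code in the CLI so that
callers can distinguish malformed input from analysis-stage failures.
"""


class DlaHapassocError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ParseError(DlaHapassocError):
    """Malformed input file (wrong column count, bad token); names the line."""

    exit_code = 2


class ValidationError(DlaHapassocError):
    """Structurally valid input that violates a domain invariant."""

    exit_code = 3


class PhasingError(DlaHapassocError):
    """Unresolved dogs where a fully phased cohort is required."""

    exit_code = 4


class DegenerateTableError(DlaHapassocError):
    """A frequency table unusable for testing (fewer than two categories)."""

    exit_code = 5


class SimulationError(DlaHapassocError):
    """Rejection sampling could not fill the requested cohort."""

    exit_code = 6
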