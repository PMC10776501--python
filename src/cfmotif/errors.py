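"""Exception hierarchy.

Errors are grouped by the kind of failure so the CLI can map them to
distinct exit codes: configuration problems (bad parameter values), input
problems (malformed or inconsistent files), and compute-stage failures.
"""


class CfMotifError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CfMotifError, ValueError):
    """A parameter or config value violates its contract."""


class InputError(CfMotifError, ValueError):
    """An input file is malformed or inconsistent with other inputs."""


class SimulationError(CfMotifError, RuntimeError):
    """The simulator cannot honour the requested configuration."""


class ExtractionError(CfMotifError, RuntimeError):
    """A fragment's end motif cannot be read from the reference."""


class EmptyProfileError(CfMotifError, ValueError):
    """A motif count vector with zero counted ends cannot be normalised."""


class TrainingError(CfMotifError, RuntimeError):
    """Classifier training preconditions are not met."""


class EvaluationError(CfMotifError, RuntimeError):
    """An evaluation statistic is undefined for the given inputs."""
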