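"""Exception hierarchy shared across the pipeline.

The CLI maps these onto distinct exit codes: configuration problems,
data problems, and computation problems are distinguishable by a caller.
"""


class StereotrendError(Exception):
    """Base class for all package errors."""


class ConfigurationError(StereotrendError):
    """Invalid configuration: unknown dialect, bad window spec, infeasible trajectory."""


class DataError(StereotrendError):
    """Invalid or insufficient input data: empty corpus, duplicate ANOVA rows, missing ratings."""


class ComputationError(StereotrendError):
    """A statistic is undefined on the given input: zero variance, degenerate design."""
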