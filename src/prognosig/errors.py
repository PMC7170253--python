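"""Exception hierarchy.

Three broad classes map onto CLI exit codes: configuration problems,
data/format problems, and numerical/degeneracy problems.
"""


class PrognosigError(Exception):
    """Base class for all package errors."""


class ConfigError(PrognosigError):
    """Invalid configuration or parameters."""


class FormatError(PrognosigError):
    """Malformed or inconsistent input data."""


class EmptyCohortError(PrognosigError):
    """No usable samples remain after filtering/intersection."""


class DegenerateError(PrognosigError):
    """A computation is undefined on the given data (zero variance, zero margin...)."""


class CoverageError(PrognosigError):
    """Too few signature genes present in the expression matrix."""
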