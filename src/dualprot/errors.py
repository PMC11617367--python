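"""Exception hierarchy shared across the pipeline.

The CLI maps these onto exit codes: format/input problems exit 2,
configuration problems exit 3 and violated internal invariants exit 4.
"""


class DualprotError(Exception):
    """Base class for all package errors."""


class FormatError(DualprotError):
    """An input file or record violates its documented dialect."""


class ConfigError(DualprotError):
    """A configuration value violates a stated invariant."""


class InternalError(DualprotError):
    """An internal pipeline invariant was violated (a bug, not bad input)."""
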