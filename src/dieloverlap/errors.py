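"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: :class:`InputError` -> 2,
:class:`EstimationError` -> 3.
"""


class DieloverlapError(Exception):
    """Base class for package errors."""


class InputError(DieloverlapError, ValueError):
    """Malformed or missing input data (bad CSV row, missing role/site, ...)."""


class EstimationError(DieloverlapError, RuntimeError):
    """A statistical estimate could not be produced (degenerate sample, ...)."""
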