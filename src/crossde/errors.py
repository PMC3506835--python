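"""Exception hierarchy shared across the pipeline.

The CLI maps :class:`FormatError` to exit code 2 and
:class:`DegenerateError` to exit code 3.
"""


class CrossDEError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(CrossDEError):
    """An on-disk artifact or in-memory table violates its contract."""


class DegenerateError(CrossDEError):
    """A statistical stage cannot proceed (e.g. all effects exactly zero)."""
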