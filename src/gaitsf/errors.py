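"""Exception hierarchy shared by all gaitsf modules.

The CLI maps these onto exit codes (see :mod:`gaitsf.cli`): schema problems
exit 2, degenerate-range problems exit 3.
"""


class GaitSFError(Exception):
    """Base class for all gaitsf errors."""


class InputError(GaitSFError, ValueError):
    """Invalid input data (non-monotone times, empty collections, ...)."""


class InsufficientDataError(InputError):
    """Too few samples or subjects for the requested operation."""


class DegenerateRangeError(GaitSFError):
    """Both curves' ranges of motion are (near-)zero; SF is undefined.

    Raised instead of returning +/-inf: the symmetry function is unstable
    for very small ranges of motion, so a hard error is safer than a huge
    finite number.
    """


class SchemaError(InputError):
    """A CSV/table does not conform to the expected long-format schema."""


class ConfigurationError(GaitSFError):
    """Unknown mode, preset or option value."""
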