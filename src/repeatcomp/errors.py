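"""Exception hierarchy shared across the package.

``InputError`` maps to CLI exit code 2 (bad or missing inputs) and
``DegenerateStatisticError`` to exit code 3 (a statistic is mathematically
undefined on the given data, e.g. zero variance or too few complete bins).
"""


class RepeatCompError(Exception):
    """Base class for repeatcomp errors."""


class InputError(RepeatCompError):
    """Malformed, missing, or inconsistent input."""

    exit_code = 2


class DegenerateStatisticError(RepeatCompError):
    """A requested statistic is undefined on the given data."""

    exit_code = 3
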