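"""Exception types shared across the package.

The CLI maps these onto exit codes: configuration problems exit with 2,
inputs on which no measurement is possible exit with 3, and I/O failures
(builtin ``OSError``) exit with 4.
"""


class ConfigurationError(ValueError):
    """A parameter value violates a documented precondition."""


class UnmeasurableInputError(RuntimeError):
    """The input contains no region on which a pulse can be measured."""


class ShapeMismatchError(ValueError):
    """Arrays that must share a shape do not."""
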