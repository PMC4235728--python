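"""Exception hierarchy shared across the package.

Every error raised on bad user input derives from :class:`ArisaKitError`
so callers (and the CLI) can catch one base class.
"""


class ArisaKitError(Exception):
    """Base class for all arisakit errors."""


class SchemaError(ArisaKitError):
    """A required column or field is missing from an input file."""


class ParseError(ArisaKitError):
    """A data row could not be parsed; the message names the line number."""


class ValidationError(ArisaKitError):
    """Parsed data violates an invariant (negative values, duplicate ids...)."""


class EmptyInputError(ArisaKitError):
    """An input file or collection contains no usable data."""


class JoinError(ArisaKitError):
    """Two inputs that must share sample labels do not."""


class ConfigError(ArisaKitError):
    """An invalid parameter combination in a run or simulation config."""
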