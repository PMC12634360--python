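"""Exception hierarchy shared across the package."""


class DDSSError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(DDSSError):
    """A feature schema violates its structural invariants."""


class RecordParseError(DDSSError):
    """A CSV row could not be mapped onto the feature schema."""


class ValidationError(DDSSError):
    """An operation's precondition on its input data is violated."""


class PipelineError(DDSSError):
    """A pipeline stage failed; the message is tagged with the stage name."""
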