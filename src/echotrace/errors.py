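"""Exception hierarchy.

Validation errors signal rejected inputs (bad parameters, malformed files);
analysis errors signal failures while processing accepted inputs (e.g. all
tracked features lost). The CLI maps these to exit codes 2 and 3.
"""


class EchotraceError(Exception):
    """Base class for package errors."""


class ValidationError(EchotraceError, ValueError):
    """Input or parameter rejected before any analysis ran."""


class SchemaError(ValidationError):
    """A file or config violated its declared schema."""


class AnalysisError(EchotraceError, RuntimeError):
    """Analysis could not be completed on otherwise valid input."""
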