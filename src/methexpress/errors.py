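"""Exception hierarchy for methexpress.

Every error raised on bad user input identifies the offending record
(probe id, sample id, cell, or file) so that validation failures on
large array tables are actionable.
"""


class MethExpressError(Exception):
    """Base class for all package errors."""


class FormatError(MethExpressError):
    """A file does not conform to the expected TSV dialect (duplicate ids,
    missing columns, unparseable values)."""


class ValidationError(MethExpressError):
    """A well-formed table violates a domain invariant (beta out of [0,1],
    unknown group label, mismatched list lengths)."""


class ConfigurationError(MethExpressError):
    """A simulation or pipeline configuration is inconsistent."""


class PipelineError(MethExpressError):
    """A pipeline stage failed; the message names the stage."""
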