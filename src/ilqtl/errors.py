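"""Exception types shared across the pipeline."""


class ILQTLError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(ILQTLError, ValueError):
    """A configuration value violates its invariants (exit code 2 in the CLI)."""


class ParseError(ILQTLError, ValueError):
    """An input file is malformed; the message names the offending row/cell."""


class AnalysisError(ILQTLError, RuntimeError):
    """A statistical operation received data it cannot analyse."""
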