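"""Exception hierarchy shared across the package."""


class PiweError(Exception):
    """Base class for all package errors."""


class ParseError(PiweError):
    """Malformed input file (FASTA, label TSV, config)."""


class ValidationError(PiweError):
    """Input violates a domain invariant (alphabet, length range, labels)."""


class ParameterError(PiweError):
    """Encoder or algorithm parameter outside its admissible range."""


class ConfigurationError(PiweError):
    """Inconsistent run configuration (missing property, empty library, ...)."""


class DegenerateInputError(PiweError):
    """Input too small for the requested operation (e.g. k > sequence length)."""
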