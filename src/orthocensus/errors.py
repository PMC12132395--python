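"""Exception hierarchy shared across the package."""


class OrthocensusError(ValueError):
    """Base class for all package-specific errors."""


class FormatError(OrthocensusError):
    """A file or in-memory record violates its format contract."""


class ConfigError(OrthocensusError):
    """A species-group configuration violates the nesting contract."""


class ConsistencyError(OrthocensusError):
    """Cross-file references do not resolve (e.g. unmapped protein IDs)."""


class ParameterError(OrthocensusError):
    """Invalid or mutually impossible parameter values."""


class SequenceError(OrthocensusError):
    """A nucleotide/protein sequence contains characters outside its alphabet."""
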