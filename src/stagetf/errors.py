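"""Exception hierarchy."""


class StageTFError(Exception):
    """Base class for all package errors."""


class ParseError(StageTFError):
    """Malformed input file (bad cell, bad GMT line, ...)."""


class ValidationError(StageTFError):
    """Inputs are well-formed but violate a contract (duplicate ids,
    empty intersection, degenerate gene set, ...)."""


class ConfigurationError(StageTFError):
    """Infeasible or invalid configuration values."""
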