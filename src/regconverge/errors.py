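"""Exception types shared across the package."""


class RegconvergeError(Exception):
    """Base class for package errors."""


class InputError(RegconvergeError, ValueError):
    """Invalid user-supplied parameter or table."""


class ParseError(RegconvergeError, ValueError):
    """Malformed input file (GFF3, PWM, TSV)."""


class GenerationError(RegconvergeError, RuntimeError):
    """Synthetic-data request that cannot be satisfied (packing, overflow)."""


class LookupError_(RegconvergeError, KeyError):
    """Missing contig / gene / species referenced by name."""
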