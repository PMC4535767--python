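"""Exception hierarchy shared across the package."""


class CrypticPocketError(Exception):
    """Base class for all package-specific errors."""


class FormatError(CrypticPocketError):
    """Malformed input file (bad PDB record, empty file, ...)."""


class ConsistencyError(CrypticPocketError):
    """Inputs that are individually valid but mutually inconsistent."""


class SelectionError(CrypticPocketError):
    """Malformed or empty-where-forbidden atom selection."""


class ParameterError(CrypticPocketError):
    """Out-of-range analysis parameter."""


class InputError(CrypticPocketError):
    """Input data that cannot support the requested computation."""


class SpecError(CrypticPocketError):
    """Invalid synthetic-data specification."""


class GenerationError(CrypticPocketError):
    """Synthetic-data generation failed to satisfy its own constraints."""
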