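"""Typed exceptions used across the pipeline.

The hierarchy distinguishes configuration mistakes (bad manifests, invalid
simulation parameters), format problems in input files, and data-level
problems (degenerate inputs that make a quantity undefined), so that the
command-line layer can map them to distinct exit codes.
"""


class GoconvergeError(Exception):
    """Base class for all package errors."""


class ConfigError(GoconvergeError):
    """Invalid configuration: manifest, simulation parameters, analysis setup."""


class FormatError(GoconvergeError):
    """Malformed input file (bad GO token, unparseable record, schema mismatch)."""


class DataError(GoconvergeError):
    """Valid input that makes the requested quantity undefined
    (zero denominator, all-equal reference values, double adjustment...)."""
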