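"""Exception hierarchy shared across the package.

The command-line layer maps these onto process exit codes
(configuration error -> 2, numerical failure -> 3, oracle failure -> 4).
"""


class StagecommError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(StagecommError, ValueError):
    """Invalid configuration value, schema violation or unknown label."""


class NumericalError(StagecommError, RuntimeError):
    """A numerical procedure failed (no convergence, no bracketing, ...)."""


class OracleError(StagecommError, AssertionError):
    """A dynamics-oracle consistency check failed."""
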