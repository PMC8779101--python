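"""Exception hierarchy.

ConfigurationError maps to CLI exit code 2, SolverError to exit code 1.
"""


class PofluxError(Exception):
    """Base class for all package errors."""


class ModelIOError(PofluxError):
    """A model file could not be read or written."""


class ConfigurationError(PofluxError):
    """Invalid configuration: bad format name, missing role, bad parameter."""


class SolverError(PofluxError):
    """The LP solver failed in a way that is not plain infeasibility."""
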