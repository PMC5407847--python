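"""Exception hierarchy.

``ValidationError`` covers malformed user input (bad graphs, labels,
matrices) and maps to exit code 2 on the command line; anything else that
escapes is an internal error (exit code 1).
"""


class LogicNEMError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(LogicNEMError, ValueError):
    """Invalid user-supplied input (graph, gate, label, matrix, config)."""


class CyclicGraphError(ValidationError):
    """A directed cycle where the acyclic signaling model is required."""


class DataFormatError(ValidationError):
    """A file could not be parsed into a valid effect dataset or network."""
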