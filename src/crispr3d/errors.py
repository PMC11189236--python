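"""Exception hierarchy shared across the pipeline.

Exit-code mapping for the CLI: InputError/FormatError -> 2,
ParameterError -> 3, DependencyError -> 4, everything else -> 1.
"""


class Crispr3DError(Exception):
    """Base class for all package errors."""


class ParameterError(Crispr3DError, ValueError):
    """A configuration knob or function argument is out of its valid range."""


class InputError(Crispr3DError, ValueError):
    """Input data violates a precondition (empty table, negative coordinate...)."""


class FormatError(InputError):
    """A file does not conform to its declared on-disk format."""


class DegenerateInputError(InputError):
    """Structurally valid input on which the operation is undefined
    (all-zero matrix, empty distance vector, zero-variance vector)."""


class BackendError(Crispr3DError, RuntimeError):
    """A pluggable computational backend failed; message carries diagnostics."""


class DependencyError(Crispr3DError, RuntimeError):
    """A pipeline stage is missing an upstream artifact."""
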