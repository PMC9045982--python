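"""Exception hierarchy shared across the pipeline."""


class GLCMError(Exception):
    """Base class for all package errors."""


class InvalidInputError(GLCMError, ValueError):
    """Raised when an argument violates an operation's preconditions."""


class InvalidStateError(GLCMError, RuntimeError):
    """Raised when an object is in the wrong state for an operation
    (e.g. symmetrizing an already-symmetric tensor)."""


class DegenerateInputError(GLCMError, ValueError):
    """Raised for structurally valid inputs on which the operation is
    undefined (e.g. normalizing an all-zero tensor)."""
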