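"""Exception hierarchy shared across the pipeline stages."""


class VoxelearnError(Exception):
    """Base class for all package errors."""


class FormatError(VoxelearnError):
    """A file could not be parsed in the requested/advertised format."""


class ValidationError(VoxelearnError):
    """An input object violates a documented invariant."""


class SchemaError(VoxelearnError):
    """Feature schema mismatch between a model and the data offered to it."""


class UntrainableError(VoxelearnError):
    """Training was requested on data that cannot define a two-class problem."""


class StateError(VoxelearnError):
    """An operation was attempted in a job state that does not allow it."""


class NotFoundError(VoxelearnError):
    """A job or file token does not exist."""
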