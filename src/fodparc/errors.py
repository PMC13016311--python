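"""Exception hierarchy used across the package.

All errors derive from :class:`FodparcError` so callers (and the CLI) can
distinguish computation failures from programming errors. The subclasses
also inherit from the matching builtin so idiomatic ``except ValueError``
still works.
"""


class FodparcError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(FodparcError, ValueError):
    """An argument violates a documented precondition."""


class ShapeMismatchError(FodparcError, ValueError):
    """Two volumes or arrays that must share a grid/shape do not."""


class FormatError(FodparcError, ValueError):
    """A file's on-disk content is not what the reader expects."""


class DegenerateInputError(FodparcError, ValueError):
    """Input is syntactically valid but makes the requested quantity undefined."""


class BoundsError(FodparcError, IndexError):
    """A voxel index lies outside the volume grid."""
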