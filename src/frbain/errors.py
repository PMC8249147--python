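"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: validation problems exit 1, I/O
problems exit 2.
"""


class FrbainError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(FrbainError):
    """Invalid input data, parameters, or configuration."""


class DimensionError(ValidationError):
    """Mismatched channel counts or vector lengths."""


class ParseError(ValidationError):
    """A record file contained a cell that could not be parsed as a number."""


class DataIOError(FrbainError):
    """A file or directory could not be read or written."""


class DegenerateMembershipError(FrbainError):
    """Every fuzzy membership evaluated to zero: the signal matches no kernel
    center at all and cannot be normalised onto the membership simplex."""


class DegenerateSeparationError(ValidationError):
    """Cluster separation is undefined (single cluster) or zero (duplicate
    medoids), so the validity index cannot be evaluated."""


class StructureError(ValidationError):
    """A network structure request is unsupported (e.g. rule layer too large)."""


class GeneratorError(FrbainError):
    """The synthetic generator could not satisfy its separation contract."""
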