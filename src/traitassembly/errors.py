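"""Typed exceptions raised across the package.

Every malformed input raises one of these; nothing is silently coerced.
"""


class TraitAssemblyError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(TraitAssemblyError):
    """A file or table does not have the declared columns / trait schema."""


class ValidationError(TraitAssemblyError):
    """A table has the right shape but violates a domain invariant."""


class DegenerateInputError(TraitAssemblyError):
    """The input is valid but the requested statistic is undefined on it
    (single-species plot, constant axis, coplanar point cloud, ...)."""


class ConvergenceError(TraitAssemblyError):
    """An iterative fit failed to converge; diagnostics attached."""
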