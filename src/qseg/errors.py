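"""Exception hierarchy shared across the package.

Exit-code mapping for the CLI lives in :mod:`qseg.cli`; library code raises
these types directly.
"""


class QsegError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(QsegError, ValueError):
    """An argument violates a documented precondition."""


class FormatError(QsegError):
    """A file on disk does not conform to its declared format."""


class GradientTableError(FormatError):
    """bvec/bval files are malformed or inconsistent."""


class SpecificationError(QsegError):
    """A phantom or acquisition specification is internally inconsistent."""


class ConfigurationError(QsegError):
    """Run/model configuration is inconsistent with the data or the stage."""


class DegenerateVoxelError(QsegError):
    """An in-mask voxel has no usable b0 signal for normalization."""


class ShapeError(QsegError, ValueError):
    """Array shapes of paired inputs do not match."""


class AlignmentError(QsegError):
    """Paired volumes do not share grid shape/spacing/orientation."""


class DependencyError(QsegError):
    """A pipeline stage is missing an upstream artifact."""


class MappingError(QsegError):
    """A label is not covered by a merge/group mapping."""


class UndefinedMetricError(QsegError):
    """A metric is undefined for the given inputs (e.g. empty region)."""


class UndefinedTestError(QsegError):
    """A statistical test is undefined for the given inputs."""


class ContractViolationError(QsegError):
    """An internal numerical contract was violated by the caller."""
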