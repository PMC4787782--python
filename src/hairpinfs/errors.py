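"""Exception hierarchy.

All package-specific failures derive from :class:`HairpinError` so callers can
catch one base class; each subclass maps to a distinct failure mode (domain
violations, configuration problems, grid mismatches, statistics preconditions,
state-assignment failures, file-format problems, missing pipeline stages).
"""


class HairpinError(Exception):
    """Base class for all hairpinfs errors."""


class DomainError(HairpinError, ValueError):
    """An argument lies outside the physical domain of a model."""


class ConfigurationError(HairpinError, ValueError):
    """A parameter set or config is inconsistent or unsolvable."""


class GridError(HairpinError, ValueError):
    """Incompatible or too-coarse numerical grids."""


class StatisticsError(HairpinError, ValueError):
    """Not enough data for a statistical operation."""


class AssignmentError(HairpinError, ValueError):
    """Two-state assignment of a trace failed (levels not separable)."""


class FormatError(HairpinError, ValueError):
    """A file does not conform to the expected text dialect."""


class DependencyError(HairpinError, RuntimeError):
    """A pipeline stage is missing an upstream artifact."""


class EmptyDataError(StatisticsError):
    """An operation received no usable events."""


class SequenceError(HairpinError, ValueError):
    """A nucleotide sequence contains an unknown base or base step."""
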