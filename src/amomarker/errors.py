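"""Exception hierarchy for the authentication pipeline.

Every module raises subclasses of :class:`AmomarkerError` so that the CLI
can map library failures to a single "data error" exit code.
"""


class AmomarkerError(Exception):
    """Base class for all errors raised by this package."""


class FastaParseError(AmomarkerError):
    """Malformed FASTA input (missing header, empty record, bad character)."""


class ConfigError(AmomarkerError):
    """Invalid generator or pipeline configuration."""


class DesignError(AmomarkerError):
    """No feasible primer or panel under the given constraints."""


class PanelAssemblyError(DesignError):
    """Multiplex panel violates size-resolution, dimer, or Tm-spread rules."""


class SaturationError(AmomarkerError):
    """A pairwise distance is undefined (logarithm argument non-positive)."""


class AmbiguousBandError(AmomarkerError):
    """A gel band matches more than one expected product within tolerance."""


class DataError(AmomarkerError):
    """Inconsistent or incomplete data passed between pipeline stages."""
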