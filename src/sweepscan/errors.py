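"""Exception hierarchy shared across the pipeline stages."""


class SweepscanError(Exception):
    """Base class for all package errors."""


class CoordinateError(SweepscanError):
    """A genomic coordinate falls outside the genome layout."""


class ConfigurationError(SweepscanError):
    """An invalid parameter or an unknown identifier in a configuration."""


class StructuralError(SweepscanError):
    """Inputs violate a structural precondition (mismatched layouts,
    overlapping sweeps within one population, ...)."""


class InfeasibleError(SweepscanError):
    """The requested statistic cannot be computed on this genome
    (e.g. every chromosome is shorter than the run length)."""


class FixtureParseError(SweepscanError):
    """A packaged data file is malformed."""
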