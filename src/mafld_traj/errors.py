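"""Shared exception types."""


class MafldTrajError(Exception):
    """Base class for package errors."""


class MappingError(MafldTrajError):
    """Malformed or inconsistent code-mapping input."""


class PhenotypeError(MafldTrajError):
    """Invalid biomarker or genotype input."""


class MatchingError(MafldTrajError):
    """Matching cannot proceed (empty arms, bad spec)."""


class SeparationError(MatchingError):
    """Perfect separation in the propensity model.

    Fall back to exact matching on the offending covariates (no caliper).
    """


class ConfigError(MafldTrajError):
    """Rejected simulation or pipeline configuration."""
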