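"""Exception hierarchy for egocircles."""


class EgocirclesError(Exception):
    """Base class for all package-specific errors."""


class ScaleError(EgocirclesError, ValueError):
    """Invalid cost scale (e.g. s_max <= s_min or negative bounds)."""


class DegenerateScaleError(ScaleError):
    """Cost scale collapsed to a point: every tie has the same weight."""


class NoSolutionError(EgocirclesError, ValueError):
    """A root-finding problem has no solution in the admissible range."""


class DomainError(EgocirclesError, ValueError):
    """Argument outside the mathematical domain of a model function."""


class DegenerateSummaryError(DomainError):
    """Normalized mean distance t outside the open interval (0, 1)."""


class ImproperPosteriorError(EgocirclesError, ValueError):
    """Posterior for eta is not normalizable (t_bar at 0 or 1)."""


class UndefinedDistanceError(EgocirclesError, ValueError):
    """Relative eta-distance undefined because the anchor eta is zero."""


class ParseError(EgocirclesError, ValueError):
    """Malformed input data file."""


class ValidationError(EgocirclesError, ValueError):
    """Input values violate a documented invariant."""
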