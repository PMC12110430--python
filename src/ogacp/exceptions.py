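"""Exception hierarchy for ogacp.

All errors raised by the library derive from :class:`OgacpError` so callers
can catch everything with one clause; subclasses carry the failure mode.
"""


class OgacpError(Exception):
    """Base class for all ogacp errors."""


class ConfigError(OgacpError, ValueError):
    """Invalid tuning-parameter configuration (empty grid, bad range, ...)."""


class InvalidBlockLengthError(OgacpError, ValueError):
    """Block length m outside the admissible range [1, n/2)."""


class InsufficientDataError(OgacpError, ValueError):
    """Series too short for the requested operation (lag order, 4q+4, ...)."""


class ParseError(OgacpError, ValueError):
    """Malformed input file; message carries the offending row where known."""


class NoCandidateError(OgacpError, ValueError):
    """No usable (non-constant) columns available for greedy selection."""


class WindowFailureError(OgacpError, RuntimeError):
    """Every candidate split point in a refinement window was singular."""


class RankDeficiencyError(OgacpError, RuntimeError):
    """Piecewise design is rank deficient; message names the segment."""


class DegenerateSegmentError(OgacpError, ValueError):
    """An estimated segment holds fewer than 2 residuals to resample."""


class NothingToBootstrapError(OgacpError, ValueError):
    """Bootstrap requested on a fit with no detected change points."""
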