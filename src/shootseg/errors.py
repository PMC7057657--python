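"""Exception hierarchy shared across the package."""


class ShootSegError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(ShootSegError, ValueError):
    """Raised when an input violates a documented contract."""


class DegenerateNeighborhoodError(ShootSegError, ValueError):
    """Raised when a point neighbourhood is too small to form a covariance."""
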