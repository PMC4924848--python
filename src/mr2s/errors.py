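"""Exception hierarchy.

Everything raised deliberately by the package derives from :class:`MRError`
so callers (and the CLI) can distinguish analysis errors from bugs.
"""


class MRError(Exception):
    """Base class for all mr2s errors."""


class ConfigError(MRError):
    """A configuration value or column mapping is missing or invalid."""


class ValidationError(MRError):
    """Input data violates a structural invariant (duplicates, bad ranges)."""


class DomainError(MRError):
    """A numeric precondition of an estimator or transform is violated."""


class HarmonizationError(MRError):
    """Exposure and outcome records cannot be aligned onto one allele."""
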