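"""Exception hierarchy for lipidsig.

All package-specific failures derive from :class:`LipidSigError` so callers
can catch one base class at pipeline boundaries.
"""


class LipidSigError(Exception):
    """Base class for all lipidsig errors."""


class ConfigurationError(LipidSigError):
    """Invalid generator / pipeline / split configuration."""


class SchemaError(LipidSigError):
    """Feature table, lipid schema or internal-standard layout is inconsistent."""


class DataError(LipidSigError):
    """Values are out of range (negative ISTD areas, p-values outside [0,1], ...)."""


class StateError(LipidSigError):
    """Operation applied to a table in the wrong state (e.g. log of a log table)."""


class InsufficientDataError(LipidSigError):
    """Too few samples/replicates/lipids for the requested computation."""
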