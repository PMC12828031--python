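"""Exception and warning types used across the package."""


class CascadeFlimError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(CascadeFlimError, ValueError):
    """A physical parameter is outside its valid domain (e.g. negative lifetime)."""


class InsufficientDataError(CascadeFlimError, ValueError):
    """Too few counts / entries to attempt a fit."""


class UndefinedLifetimeError(CascadeFlimError, ValueError):
    """A mean lifetime is requested from a fit with zero total amplitude."""


class ConfigurationError(CascadeFlimError, ValueError):
    """Missing or inconsistent configuration (e.g. unknown fluorophore pair)."""


class MissingConditionError(ConfigurationError):
    """A pipeline input condition (construct / control) is absent."""


class InconsistentMeasurementError(CascadeFlimError, ValueError):
    """Measured rates violate a physical constraint (e.g. K_total < 1/tau_D)."""


class InfeasibleGeometryError(CascadeFlimError, ValueError):
    """Pairwise separations violate the triangle inequality."""


class NoFretWarning(UserWarning):
    """A transfer rate came out negative (no measurable FRET) and was clamped to 0."""
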