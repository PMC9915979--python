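"""Exception hierarchy for the benzrisk pipeline."""


class BenzriskError(Exception):
    """Base class for all benzrisk errors."""


class DomainError(BenzriskError, ValueError):
    """A numeric argument lies outside its physical domain (e.g. negative time)."""


class ConfigError(BenzriskError, ValueError):
    """A parameter set or generator configuration is invalid or infeasible."""


class SaturationError(BenzriskError):
    """The observed biomarker exceeds the forward model's metabolic ceiling.

    Urinary tt-MA output saturates at f_ttma * Vmax * interval * (MW ratio) /
    void_volume; an observation at or above that bound cannot be explained by
    any finite air concentration.
    """


class EmptyCohortError(BenzriskError):
    """No children remain after the exclusion rules; nothing to estimate."""


class CohortSchemaError(BenzriskError, ValueError):
    """A cohort CSV does not conform to the documented schema."""
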