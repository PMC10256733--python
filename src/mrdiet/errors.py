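"""Exception hierarchy shared across the pipeline."""


class MrdietError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(MrdietError, ValueError):
    """A config, column map, or simulation truth is malformed or impossible."""


class ValidationError(MrdietError, ValueError):
    """A data value violates an invariant (bad allele, SE <= 0, ...)."""


class NoSharedVariantsError(MrdietError):
    """Exposure and outcome studies have an empty variant intersection."""


class InsufficientInstrumentsError(MrdietError):
    """An estimator was called with fewer instruments than it requires."""


class InvalidInstrumentError(MrdietError, ValueError):
    """A single instrument is unusable (e.g. zero exposure effect)."""
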