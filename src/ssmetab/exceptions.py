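"""Exception hierarchy for the pipeline."""


class SSMetabError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(SSMetabError):
    """A configuration value is inconsistent or refers to unknown entities."""


class DomainError(SSMetabError):
    """An input violates a mathematical precondition of an operation."""


class CalibrationError(SSMetabError):
    """Chemical-shift calibration could not find a reference peak."""
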