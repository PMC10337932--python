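"""Exception types shared across the package."""


class VoyageEBError(Exception):
    """Base class for package errors."""


class ConfigurationError(VoyageEBError):
    """A configuration value is invalid or inconsistent with the domain."""


class OutOfDomainError(VoyageEBError):
    """A requested sample point lies outside the gridded field domain."""


class FieldFormatError(VoyageEBError):
    """A gridded environment file is missing a required variable or dimension."""


class ModelRangeError(VoyageEBError):
    """A model was evaluated outside its calibrated/valid range."""
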