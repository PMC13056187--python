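"""Exception taxonomy shared across the package."""


class FlowcatchError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(FlowcatchError):
    """A configuration file, column mapping, or option is invalid."""


class ValidationError(FlowcatchError):
    """Input data violate a dataset invariant (duplicate ids, negative counts...)."""


class InsufficientDataError(FlowcatchError):
    """Too few observations for the requested fit or statistic."""


class DegenerateInputError(FlowcatchError):
    """The statistic is undefined on this input (zero variance, all zeros...)."""
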