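"""Exception hierarchy for the pipeline."""


class GpsMsmError(Exception):
    """Base class for all package errors."""


class ConfigurationError(GpsMsmError):
    """A configuration field is invalid; the message names the field."""


class DataError(GpsMsmError):
    """Input data violate a precondition (schema, positivity, variance)."""


class FitError(GpsMsmError):
    """A model fit failed (non-convergence, rank deficiency, basis too large)."""
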