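"""Exception hierarchy for the drift toolkit."""


class DriftError(Exception):
    """Base class for all package-specific errors."""


class DomainError(DriftError):
    """A query point lies outside a field's spatial bounding box."""


class MaskedValueError(DriftError):
    """All nodes enclosing a query point are masked (land / fill)."""


class FieldLoadError(DriftError):
    """A gridded input file is missing variables, units, or monotone axes."""


class ConfigurationError(DriftError):
    """A simulation configuration is inconsistent or unsatisfiable."""
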