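"""Exception hierarchy shared across the pipeline stages."""


class Tp53PhenocopyError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(Tp53PhenocopyError):
    """An invalid configuration value or an incompatible combination of settings."""


class ValidationError(Tp53PhenocopyError):
    """Input data violates a structural contract (duplicates, unknown vocabulary, ...)."""


class SingularDesignError(Tp53PhenocopyError):
    """A regression design matrix is collinear to machine precision."""


class SeparationError(Tp53PhenocopyError):
    """Complete or quasi-complete separation in a logistic model."""
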