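"""Exception hierarchy shared across the package."""


class EbprError(Exception):
    """Base class for all package errors."""


class FormatError(EbprError):
    """A file does not conform to the expected dialect (missing columns, bad header)."""


class ValidationError(EbprError, ValueError):
    """Well-formed input carrying invalid values (bad labels, negative counts...)."""


class ConfigurationError(EbprError):
    """Inconsistent or incomplete analysis configuration."""


class InfeasibleSpecError(EbprError):
    """A simulation spec that cannot be realised (e.g. negative concentrations)."""


class UndefinedRatioError(EbprError):
    """A stoichiometric ratio whose denominator is zero."""
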