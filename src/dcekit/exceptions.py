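"""Exception hierarchy for dcekit."""


class DcekitError(Exception):
    """Base class for all dcekit errors."""


class FormatError(DcekitError):
    """A file does not conform to the expected tabular/volume format."""


class ValidationError(DcekitError):
    """Input data violate a documented invariant."""


class ConversionError(DcekitError):
    """Signal-to-concentration conversion is impossible (e.g. S0 <= 0)."""


class FitError(DcekitError):
    """A kinetic fit cannot be set up (too few samples, bad inputs)."""


class DomainError(DcekitError):
    """A parameter lies outside its physical domain."""
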