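"""Exception hierarchy shared across the package."""


class ThresholdAgeError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(ThresholdAgeError):
    """An input table or document does not match the expected schema."""


class ParseError(ThresholdAgeError):
    """A field could not be parsed into the expected type."""


class FitError(ThresholdAgeError):
    """A model or distribution fit failed to converge."""


class FitInfeasibleError(FitError):
    """The requested moments/quantiles cannot be matched by the family."""


class DegenerateSpreadError(FitError):
    """A five-number summary has zero interquartile spread."""


class DegeneratePosteriorError(ThresholdAgeError):
    """The stage likelihood is numerically zero over the whole prior support."""


class CombinationError(ThresholdAgeError):
    """An indicator combination that the model does not allow."""
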