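"""Exception hierarchy shared across the package."""


class FretPaintError(Exception):
    """Base class for all package errors."""


class ConfigurationError(FretPaintError):
    """A configuration object violates one of its invariants."""


class FormatError(FretPaintError):
    """An on-disk dataset is malformed; message names file and field."""


class EstimationError(FretPaintError):
    """A statistical estimate could not be formed from the data given."""


class FittingError(FretPaintError):
    """A nonlinear fit failed to converge from every starting point."""
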