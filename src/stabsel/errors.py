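"""Typed exceptions used across the package.

Degenerate inputs (empty selected sets, all features selected, constant
features) are rejected with dedicated error types rather than silently
imputed, so that callers can report a stability measure as *undefined*
for a given selection ensemble instead of propagating a bogus number.
"""


class StabselError(Exception):
    """Base class for all errors raised by this package."""


class ShapeError(StabselError):
    """Inputs have inconsistent or unusable dimensions."""


class ConfigError(StabselError):
    """A configuration or generator specification is invalid."""


class EmptySetError(StabselError):
    """A selected feature set is empty where a measure requires nonempty sets."""


class DegenerateSelectionError(StabselError):
    """A stability measure's denominator vanishes for this ensemble.

    Typical cause: all features selected in every set, which leaves the
    chance-corrected measures undefined.
    """


class UndefinedCorrelationError(StabselError):
    """A required Pearson correlation is undefined (constant feature)."""


class UndefinedStabilityError(StabselError):
    """A requested stability value is undefined for some configurations."""


class SingleClassError(StabselError):
    """The label vector contains only one class."""


class FormatError(StabselError):
    """A data file does not conform to the expected format."""


class BackendError(StabselError):
    """A classifier backend failed while fitting or predicting."""
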