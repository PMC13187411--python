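"""Exception hierarchy shared across leafoptics modules."""


class LeafOpticsError(Exception):
    """Base class for all leafoptics errors."""


class GridMismatchError(LeafOpticsError, ValueError):
    """Two spectral objects do not share the same wavelength grid."""


class DivisionHazardError(LeafOpticsError, ZeroDivisionError):
    """A denominator of zero was encountered at a named wavelength."""


class InsufficientSamplesError(LeafOpticsError, ValueError):
    """An operation requires more samples than were provided."""


class SampleAlignmentError(LeafOpticsError, ValueError):
    """Paired datasets whose sample_id ordering disagrees."""


class SchemaError(LeafOpticsError, ValueError):
    """A table on disk violates the expected column layout."""


class SpecError(LeafOpticsError, ValueError):
    """A synthetic-data specification is internally inconsistent."""


class DomainError(LeafOpticsError, ValueError):
    """A scalar argument lies outside the physical domain."""


class NonPhysicalLayerError(LeafOpticsError, ValueError):
    """A plate layer with reflectance + transmittance > 1."""


class InversionFailure(LeafOpticsError, RuntimeError):
    """The optimizer produced a non-finite merit; carries the trait vector."""

    def __init__(self, message, traits=None):
        super().__init__(message)
        self.traits = traits


class DegenerateDesignError(LeafOpticsError, ValueError):
    """A trial design that cannot support variance-component estimation."""


class DegenerateResponseError(LeafOpticsError, ValueError):
    """A constant response vector was passed to a regression fit."""


class DivergenceError(LeafOpticsError, RuntimeError):
    """NaN training loss; reports the epoch and learning rate at failure."""

    def __init__(self, message, epoch=None, learning_rate=None):
        super().__init__(message)
        self.epoch = epoch
        self.learning_rate = learning_rate
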