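"""Exception hierarchy for the karyofish pipeline."""


class KaryofishError(Exception):
    """Base class for all pipeline errors."""


class UnknownSpeciesError(KaryofishError, KeyError):
    """A species id does not name a packaged fixture or a fixture file."""


class FixtureValidationError(KaryofishError, ValueError):
    """A karyotype fixture violates one of its invariants."""


class ConstructionError(KaryofishError, ValueError):
    """A measurement table cannot be built under the fixture's constraints."""


class PlacementError(KaryofishError, RuntimeError):
    """Chromosomes could not be placed on the canvas without overlap."""


class MeasurementError(KaryofishError, ValueError):
    """Invalid input to a measurement or analytics operation."""


class ChannelMissingError(KaryofishError, KeyError):
    """A required fluorescence channel is absent from the image."""
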