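"""Exception hierarchy for map construction."""


class MapweaverError(Exception):
    """Base class for all package errors."""


class FormatError(MapweaverError):
    """A file does not conform to its declared dialect (wrong column count etc.)."""


class ValidationError(MapweaverError):
    """A record or record list violates a domain invariant."""


class IntegrationError(MapweaverError):
    """The integration engine hit an irrecoverable state (non-convergence, bad anchors)."""


class PlacementError(MapweaverError):
    """A centromere or locus could not be placed from the available evidence."""
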