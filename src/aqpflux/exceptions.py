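"""Exception hierarchy shared across the package."""


class AqpfluxError(ValueError):
    """Base class for all package-specific errors."""


class FormatError(AqpfluxError):
    """A file does not conform to its declared on-disk format."""


class StructureError(AqpfluxError):
    """Topology/trajectory contents are internally inconsistent."""


class SelectionError(AqpfluxError):
    """An atom selection criterion is malformed."""


class InsufficientDataError(AqpfluxError):
    """Not enough frames/points for the requested analysis."""


class SpecError(AqpfluxError):
    """A channel/filter/config specification violates its invariants."""
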