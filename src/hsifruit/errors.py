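"""Exception hierarchy.

``DomainError`` flags scientifically invalid inputs (bad parameter values,
degenerate data); ``ContractError`` flags programming-contract violations
(shape/band mismatches); ``FormatError`` flags malformed files on disk.
"""


class HsiFruitError(Exception):
    """Base class for all package errors."""


class DomainError(HsiFruitError, ValueError):
    """Input is outside the scientific domain of the operation."""


class ContractError(HsiFruitError, ValueError):
    """Caller violated an interface contract (shapes, band subsets, tags)."""


class FormatError(HsiFruitError, ValueError):
    """A file on disk does not conform to its expected format."""


class SegmentationError(HsiFruitError, RuntimeError):
    """Fruit/background segmentation produced an empty or invalid mask."""
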