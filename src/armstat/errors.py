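"""Exception hierarchy for armstat."""


class ArmstatError(Exception):
    """Base class for all armstat-specific errors."""


class DegenerateConfiguration(ArmstatError):
    """End-point coincides with the shoulder axis; gamma_s is undefined."""


class UnequalLengths(ArmstatError):
    """An operation requiring equal segment lengths received unequal ones."""


class DomainError(ArmstatError):
    """Input lies outside the domain of a coordinate-route computation."""


class GridTooLarge(ArmstatError):
    """A joint-angle grid reaches or exceeds pi radians."""


class OnBoundary(ArmstatError):
    """Force direction falls exactly on a force singular point."""
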