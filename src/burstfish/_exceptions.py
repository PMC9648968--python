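"""Exception and warning types shared across the package."""


class BurstfishError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(BurstfishError, ValueError):
    """A kinetic parameter or model specification is invalid (negative, non-finite, ...)."""


class TruncationError(BurstfishError, RuntimeError):
    """State-space truncation grew past the hard cap without capturing enough mass."""

    def __init__(self, cap: int, tail_mass: float):
        self.cap = cap
        self.tail_mass = tail_mass
        super().__init__(
            f"state-space truncation exceeded hard cap {cap} "
            f"(uncaptured tail mass {tail_mass:.3g})"
        )


class SchemaError(BurstfishError, ValueError):
    """A cell table does not conform to the documented CSV schema."""


class UndefinedQuantityError(BurstfishError, ZeroDivisionError):
    """A derived quantity (fraction ON, burst size, ...) is undefined for these rates."""


class DataModelMismatchWarning(UserWarning):
    """An observation received a model probability below the floor used in the likelihood."""


class DegenerateDataWarning(UserWarning):
    """The dataset is degenerate (e.g. all zeros); estimates sit at a search-space boundary."""
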