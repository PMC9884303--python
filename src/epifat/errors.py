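"""Exception types shared across the pipeline."""


class EpifatError(ValueError):
    """Base class for all domain errors raised by this package."""


class InvalidGeometryError(EpifatError):
    """Requested phantom geometry does not fit the grid or is inconsistent."""


class PlacementError(EpifatError):
    """An injected corruption would fall (partly) outside the image grid."""


class AlignmentError(EpifatError):
    """Volume and mask grids do not share the same shape."""


class MaskValueError(EpifatError):
    """A mask image contains values other than 0 and 1."""


class ParameterError(EpifatError):
    """A numeric parameter violates its documented invariant."""


class UndefinedStatisticError(EpifatError):
    """A statistic (median, tau, ...) is undefined for the given input."""


class CollinearityError(EpifatError):
    """A regression design matrix is rank deficient.

    Carries the names of the offending columns in ``columns``.
    """

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(
            "design matrix is rank deficient; offending columns: "
            + ", ".join(self.columns)
        )
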