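"""Exception hierarchy for henorm.

Every error raised on purpose by the library derives from :class:`HenormError`
so callers (and the CLI) can distinguish domain failures from bugs.
"""


class HenormError(Exception):
    """Base class for all henorm domain errors."""


class InvalidParameterError(HenormError, ValueError):
    """A parameter is outside its documented domain."""


class InvalidInputError(HenormError, ValueError):
    """Inputs are malformed or mutually inconsistent (shape/emptiness)."""


class DegenerateStainError(HenormError):
    """Stain-vector estimation or deconvolution is impossible: too few
    chromatic foreground pixels, a rank-deficient optical-density cloud, or
    an ill-conditioned stain matrix."""


class DegenerateReferenceError(HenormError):
    """A reference image carries no usable statistics (e.g. constant)."""


class UndefinedMetricError(HenormError):
    """A quality metric's denominator vanishes (all-black image, fully
    achromatic image)."""


class UndefinedScoreError(HenormError):
    """A segmentation score is undefined (empty ground-truth label)."""


class UndefinedAggregateError(HenormError):
    """Aggregation was requested but every per-image value is missing."""


class PlacementError(HenormError):
    """The synthetic scene generator could not place the requested number of
    nuclei; carries the achieved count."""

    def __init__(self, requested: int, achieved: int):
        self.requested = requested
        self.achieved = achieved
        super().__init__(
            f"could only place {achieved} of {requested} requested nuclei"
        )
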