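"""Exception hierarchy for the exoct pipeline.

Every stage failure is a named exception so batch drivers can record and
skip individual slices without losing the reason.
"""


class ExoctError(Exception):
    """Base class for all pipeline errors."""


class PhantomSpecError(ExoctError):
    """A phantom specification violates one of its invariants."""

    def __init__(self, constraint: str, message: str = ""):
        self.constraint = constraint
        super().__init__(f"invalid phantom spec [{constraint}]: {message}")


class NoBoneFoundError(ExoctError):
    """Rim extraction produced an empty mask."""


class NoEyeFoundError(ExoctError):
    """The eye mask is empty or lacks the expected number of globes."""


class EmptyRegionError(ExoctError):
    """A rim-apex search region (image third or half) contains no set pixels."""

    def __init__(self, region: str):
        self.region = region
        super().__init__(f"{region} has no rim pixels")


class DegenerateInputError(ExoctError):
    """A statistic is undefined for the given data (e.g. zero variance)."""
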