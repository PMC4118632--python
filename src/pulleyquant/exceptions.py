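"""Package exception hierarchy."""


class PulleyQuantError(Exception):
    """Base class for all pulleyquant errors."""


class GenerationError(PulleyQuantError):
    """Raised when a phantom or cohort cannot be generated within its
    retry budget (e.g. nucleus density too high for non-overlapping
    placement, or truncated-normal rejection sampling exhausted)."""


class NoSuitableImagesError(PulleyQuantError):
    """Raised when a specimen has zero suitable images to select from."""

    def __init__(self, specimen_id: str):
        self.specimen_id = specimen_id
        super().__init__(f"specimen {specimen_id!r}: no suitable images")


class UndefinedStatisticError(PulleyQuantError):
    """Raised when a statistic is undefined for the given input
    (zero variance, expected agreement of one, empty denominator)."""
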