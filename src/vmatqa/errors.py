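"""Exception types shared across the package."""


class VmatQaError(Exception):
    """Base class for all package-specific errors."""


class PlanFormatError(VmatQaError):
    """A plan file (DICOM RT Plan or JSON dialect) could not be interpreted."""


class UndefinedMetricError(VmatQaError):
    """A metric is mathematically undefined for the given input.

    Raised e.g. for the irregularity of a zero-area aperture or the
    MU-weighted aggregates of a beam whose aperture is closed everywhere.
    """
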