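"""Exception types shared across the segmentation cascade."""


class CystSegError(Exception):
    """Base class for all cystseg errors."""


class DegenerateImageError(CystSegError):
    """Image has no usable dynamic range (e.g. constant intensity)."""


class DegenerateDataError(CystSegError):
    """Clustering input has fewer distinct values than requested clusters."""


class UnsupportedFormatError(CystSegError):
    """Input file decodes, but not to a single 2-D grayscale frame."""
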