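"""Exception hierarchy for veinmotion."""


class VeinMotionError(Exception):
    """Base class for all veinmotion errors."""


class InputError(VeinMotionError):
    """Unreadable, empty, or otherwise unusable input."""


class DimensionMismatchError(InputError):
    """Frames in one sequence do not share a single shape."""


class DomainError(VeinMotionError, ValueError):
    """Argument outside its mathematical domain (zero/negative size etc.)."""


class ConfigurationError(VeinMotionError):
    """Grid/subset/search geometry incompatible with the frame dimensions."""


class OutOfBoundsError(VeinMotionError):
    """A subset (plus any required margin) crosses the image border."""


class DegenerateSubsetError(VeinMotionError):
    """Subset has (near-)zero intensity variance; correlation is undefined."""


class EmptyRegionError(VeinMotionError):
    """A reference region contains no valid grid points."""


class GridMismatchError(VeinMotionError):
    """Maps defined on different grids cannot be combined."""


class MarginError(VeinMotionError):
    """Synthetic displacement would push scene content beyond the frame."""
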