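"""Exception hierarchy shared across the package."""


class RtnfError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(RtnfError):
    """A run/paradigm/phantom configuration violates its preconditions."""


class InvalidSpecError(RtnfError):
    """A phantom specification is internally inconsistent."""


class InvalidContrastError(RtnfError):
    """A classification contrast cannot be built (e.g. an empty class)."""


class GridMismatchError(RtnfError):
    """Two volumes/masks that must share a grid do not."""


class MaskError(RtnfError):
    """Brain-mask construction produced an empty or invalid mask."""


class DesignError(RtnfError):
    """A GLM design matrix is rank deficient or otherwise unusable."""
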