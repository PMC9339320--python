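"""Exception types shared across the package."""


class PvlasError(Exception):
    """Base class for all package-specific errors."""


class DimensionError(PvlasError, ValueError):
    """Array shapes or lengths are mutually inconsistent."""


class ConstraintError(PvlasError, ValueError):
    """A breeding-program constraint (selection count, partition, ...) is violated."""


class SizeError(PvlasError, ValueError):
    """An exact/enumerative routine was asked for an instance beyond its size guard."""


class FormatError(PvlasError, ValueError):
    """A data file does not conform to its dialect; message names the offending record."""
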