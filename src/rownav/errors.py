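"""Typed failure modes of the pipeline.

Field frames legitimately contain no vegetation or no identifiable crop
row; those conditions are part of the public contract, not crashes.
"""


class RowNavError(Exception):
    """Base class for all rownav errors."""


class InvalidInputError(RowNavError):
    """The input image or point set is malformed (empty, wrong shape)."""


class ConfigError(RowNavError):
    """A configuration value is outside its admissible range."""


class NoVegetationError(RowNavError):
    """No foreground vegetation found where the pipeline requires some."""


class NoRowError(RowNavError):
    """No plantation-row cluster / fitting region could be identified."""


class DegenerateError(RowNavError):
    """Geometric degeneracy: coincident points, zero-length direction."""
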