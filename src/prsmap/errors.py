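"""Exception hierarchy shared across the package."""


class PrsmapError(Exception):
    """Base class for all package-specific errors."""


class FormatError(PrsmapError):
    """Malformed input file (FASTA/GFF3) or invalid sequence alphabet."""


class CoordinateError(PrsmapError):
    """A coordinate falls outside its chromosome or interval bounds."""


class NotFoundError(PrsmapError):
    """A required sequence match (e.g. the oriC probe) was not found."""


class LowConfidenceError(PrsmapError):
    """A signal-based call (e.g. terC) does not rise above the noise floor."""


class AmbiguityError(PrsmapError):
    """A call cannot be resolved uniquely (e.g. attR overlapping two genes)."""
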