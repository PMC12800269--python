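"""Exception hierarchy shared across the package."""


class PhenolinkError(Exception):
    """Base class for all package-specific errors."""


class CoverageError(PhenolinkError):
    """Daily climate does not cover a requested date."""


class CollinearityError(PhenolinkError):
    """Design matrix is rank deficient."""


class TooShortSeriesError(PhenolinkError):
    """Not enough usable years for the requested fit."""


class DegenerateSeriesError(PhenolinkError):
    """A variable has zero variance and cannot be standardized."""


class LabellingError(PhenolinkError):
    """A species label is absent from the phylogeny."""


class NotUltrametricError(PhenolinkError):
    """Tree depths differ beyond tolerance; rescale before building a correlation."""
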