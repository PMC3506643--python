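"""Exception hierarchy for ancestrymapper.

Every error raised on a contract violation derives from
:class:`AncestryMapperError`, so callers can catch the package's own
failures separately from programming errors.
"""


class AncestryMapperError(Exception):
    """Base class for all ancestrymapper errors."""


class MalformedFileError(AncestryMapperError):
    """A genotype or metadata file does not follow its declared format."""


class DuplicateSampleError(AncestryMapperError):
    """The same sample id appears more than once."""


class InvalidAlleleError(AncestryMapperError):
    """An allele code outside {0, 1, 2} was encountered."""


class InvalidCellError(AncestryMapperError):
    """A genotype TSV cell is not one of 2, 3, 4 or NA."""


class NoOverlapError(AncestryMapperError):
    """Two datasets share no SNP ids."""


class EmptyPopulationError(AncestryMapperError):
    """A population has no genotyped members."""


class IncomparablePairError(AncestryMapperError):
    """A sample pair has zero jointly non-missing SNPs."""


class DegenerateScaleError(AncestryMapperError):
    """All off-diagonal distances are equal; no affine rescale exists."""


class InsufficientOverlapError(AncestryMapperError):
    """Too few jointly non-missing SNPs between an individual and a reference."""

    def __init__(self, message: str, n_used: int | None = None):
        super().__init__(message)
        self.n_used = n_used


class DegenerateProfileError(AncestryMapperError):
    """A raw AMid vector is constant and cannot be normalized."""


class InsufficientSnpsError(AncestryMapperError):
    """Requested subsample size exceeds the available SNPs."""


class InvalidKError(AncestryMapperError):
    """Cluster count K outside 1..n."""


class TooFewSamplesError(AncestryMapperError):
    """A sample filter selected fewer samples than clusters requested."""


class PanelMismatchError(AncestryMapperError):
    """Two AMid profiles were computed against different panels."""


class InvalidRouteError(AncestryMapperError):
    """A geographic route needs at least two waypoints."""


class SimulationConfigError(AncestryMapperError):
    """A simulation configuration violates its invariants."""
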