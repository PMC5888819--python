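"""Exception hierarchy for study validation and model fitting."""


class MirpairError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(MirpairError):
    """A configuration field is missing, out of range, or inconsistent."""


class PairingError(MirpairError):
    """A subject lacks its tumor or normal sample for an assay."""


class FormatError(MirpairError):
    """An input file violates the expected tabular or FASTA format."""


class DegenerateSampleError(MirpairError):
    """A sample has no usable signal (e.g. zero 75th percentile or zero total)."""


class CapacityError(MirpairError):
    """Requested seed sites cannot be packed into the UTR length."""


class IntegrityError(MirpairError):
    """A packaged fixture does not match its recorded checksum."""


class FitError(MirpairError):
    """A per-gene model fit failed to converge; carries the gene id."""

    def __init__(self, message: str, gene: str | None = None):
        super().__init__(message)
        self.gene = gene


class CollinearityError(MirpairError):
    """The regression design matrix is rank deficient."""


class SizeError(MirpairError):
    """Too few subjects (or pairs) for the requested fit."""


class SubgroupSizeError(SizeError):
    """A subgroup restriction leaves too few pairs to analyze."""


class GroupingError(MirpairError):
    """Results passed to a grouped operation span more than one group."""


class AlphabetError(MirpairError):
    """A sequence contains characters outside the expected alphabet."""


class SpecError(MirpairError):
    """An operation-level specification (e.g. bootstrap plan) is invalid."""
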