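"""Exception hierarchy shared across the package."""


class RibodeltaError(Exception):
    """Base class for all package-specific errors."""


class MalformedAnnotationError(RibodeltaError, ValueError):
    """Exon records are inconsistent (mixed chrom/strand, overlapping exons...)."""


class CoordinateError(RibodeltaError, ValueError):
    """A genomic interval falls outside its chromosome."""


class LookupError_(RibodeltaError, KeyError):
    """A chromosome or identifier is missing from a resource."""


class DegenerateInputError(RibodeltaError, ValueError):
    """An input is empty or otherwise too small to operate on."""


class UndefinedProfileError(RibodeltaError, ValueError):
    """A coverage profile cannot be normalized (zero total depth)."""


class SegmentationMissingError(RibodeltaError, ValueError):
    """A region-level operation was requested for a transcript with no ORF."""


class InsufficientDataError(RibodeltaError, ValueError):
    """A statistical routine has fewer observations than it requires."""


class UndefinedCorrelationError(RibodeltaError, ValueError):
    """Correlation is undefined because one variable has zero variance."""


class ValidationError(RibodeltaError, ValueError):
    """An argument violates its documented contract."""


class InsufficientPoolError(RibodeltaError, ValueError):
    """Expression-matched sampling cannot fill one or more bins."""

    def __init__(self, deficient_bins):
        self.deficient_bins = list(deficient_bins)
        msg = "; ".join(
            f"bin {b}: need {need}, pool has {have}"
            for b, need, have in self.deficient_bins
        )
        super().__init__(f"insufficient pool genes for expression matching: {msg}")
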