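"""Exception hierarchy shared across the pipeline."""


class CroakerGSError(Exception):
    """Base class for all pipeline errors."""


class GenotypeParseError(CroakerGSError):
    """A genotype file could not be parsed; message names the offending line."""


class GenotypeValidationError(CroakerGSError):
    """A container invariant was violated (duplicate ids, bad codes, shape mismatch)."""


class ConfigurationError(CroakerGSError):
    """An option or threshold outside its legal range."""


class MonomorphicMarkerError(CroakerGSError):
    """A marker with allele frequency 0 or 1 reached a step that requires polymorphism."""


class KernelError(CroakerGSError):
    """A relationship kernel is not symmetric positive semi-definite within tolerance."""


class LinearAlgebraError(CroakerGSError):
    """A mixed-model coefficient matrix could not be factorized."""


class MarkerAlignmentError(CroakerGSError):
    """Candidate markers do not match the training markers."""


class ConvergenceError(CroakerGSError):
    """An iterative fit produced non-finite values; message carries the iteration trace."""


class DomainError(CroakerGSError):
    """A quantity left the domain where a formula is defined (e.g. accuracy >= 1)."""
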