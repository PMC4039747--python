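"""Exception types shared across the package."""


class BalscanError(Exception):
    """Base class for all package errors."""


class FormatError(BalscanError, ValueError):
    """A file does not conform to its declared format (FASTA/GFF3/VCF/bedGraph/TSV)."""


class ValidationError(BalscanError, ValueError):
    """An in-memory object violates one of its invariants, or an argument is out of range."""


class BoundsError(ValidationError):
    """A genomic interval or position falls outside its chromosome."""


class InsufficientDataError(BalscanError):
    """Not enough observations to compute a statistic (e.g. too few depth windows)."""


class ConfigurationError(BalscanError):
    """A simulation or pipeline configuration cannot be satisfied."""
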