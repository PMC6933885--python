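"""Exception hierarchy.

Every error the library raises derives from :class:`SegGrmError`, so callers
(including the CLI, which maps subclasses to distinct exit codes) can catch one
base class.
"""


class SegGrmError(Exception):
    """Base class for all seggrm errors."""


class GenotypeParseError(SegGrmError):
    """A genotype input file could not be parsed under the named format."""


class DuplicateIdError(GenotypeParseError):
    """Duplicate individual or SNP identifier in an input file."""


class AlignmentError(SegGrmError):
    """Two SNP-aligned objects do not share the same ordered SNP list."""


class FrequencyError(SegGrmError):
    """Allele-frequency file problem: missing SNP, bad value, out of range."""


class WeightError(SegGrmError):
    """SNP-weight problem: missing SNP, negative weight, length mismatch."""


class DenominatorZeroError(SegGrmError):
    """2 * sum p_j (1 - p_j) is zero: every SNP considered is monomorphic."""


class CorruptSummaryError(SegGrmError):
    """A segment-summary file is truncated, has a bad magic or checksum."""


class UnsupportedVersionError(CorruptSummaryError):
    """A segment-summary file declares a format version this reader lacks."""


class IncompatibleSummariesError(SegGrmError):
    """Segment summaries cannot be combined (individuals, mode, or overlap)."""


class GrmFormatError(SegGrmError):
    """A GRM output file is inconsistent or cannot be read back."""
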