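"""Exception types shared across the package."""


class MitosignalError(Exception):
    """Base class for all package-specific errors."""


class AlignmentShapeError(MitosignalError):
    """Rows of an alignment have unequal lengths."""


class AlphabetError(MitosignalError):
    """A residue is not part of the declared alphabet."""


class TaxonSetError(MitosignalError):
    """Taxon sets of two alignments (or an alignment and a tree) disagree."""


class FrameError(MitosignalError):
    """A coding partition is not divisible into complete codons."""


class CoordinateError(MitosignalError):
    """Invalid genomic coordinates (e.g. end < start)."""


class DuplicateNameError(MitosignalError):
    """Two features or taxa share a name where uniqueness is required."""


class EmptyCompositionError(MitosignalError):
    """No countable residues remain after excluding gaps and ambiguity."""


class PartitionError(MitosignalError):
    """A partition map references unknown genes or overlapping columns."""


class TranslationWarning(UserWarning):
    """Non-fatal oddity during translation (e.g. internal stop codon)."""
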