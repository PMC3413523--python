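"""Exception hierarchy.

All data-level failures derive from :class:`DataError` so the CLI can map
them to a single exit code; usage errors are handled by click separately.
"""


class ConsalignError(Exception):
    """Base class for all package errors."""


class DataError(ConsalignError, ValueError):
    """Malformed or inconsistent input data."""


class EmptyInputError(DataError):
    """FASTA input contained no usable records."""


class RaggedAlignmentError(DataError):
    """Records of one alignment have unequal gapped lengths."""


class DuplicateIdError(DataError):
    """Two records in one alignment share an identifier."""


class HarmonizeError(DataError):
    """Alignments do not describe the same set of ungapped sequences."""


class GraphConsistencyError(DataError):
    """Constituent alignments produced incompatible graph terminals."""
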