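"""Exception hierarchy."""


class NtmapError(Exception):
    """Base class for all package errors."""


class FormatError(NtmapError):
    """Malformed external input (FASTA, coordinate list, annotation table)."""


class DuplicateIdError(FormatError):
    """Two records in one file or database share an id."""


class HeaderConventionError(FormatError):
    """A FASTA header does not follow the required naming convention."""


class CoordinateError(NtmapError):
    """A coordinate falls outside the reference it refers to."""


class KmerError(NtmapError):
    """Seed length incompatible with the reference collection."""


class QueryTooShortError(NtmapError):
    """Query shorter than the seed length."""


class ConsensusError(NtmapError):
    """No consensus obtainable (unequal lengths, or 100% threshold unmet)."""


class TsdAlertError(CoordinateError):
    """The TGN sits too close to a reference end for a full TSD/flank."""


class NotCallableError(NtmapError):
    """A composite alignment does not support an insertion call."""
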