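"""Exception hierarchy for mitoskew."""


class MitoskewError(Exception):
    """Base class for all package errors."""


class InputFormatError(MitoskewError):
    """A file could not be parsed in the expected format."""


class MissingSequenceError(InputFormatError):
    """A record carries no nucleotide sequence."""


class FrameError(MitoskewError):
    """A coding sequence is not a whole number of codons."""


class TooShortError(MitoskewError):
    """An extracted CDS is shorter than one codon."""


class UndeterminedCRError(MitoskewError):
    """Control-region polarity could not be established."""


class SimulationSpecError(MitoskewError):
    """A synthetic-genome specification is inconsistent."""
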