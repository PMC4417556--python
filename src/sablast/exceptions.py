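"""Exception hierarchy for sablast.

Every error raised by the library derives from :class:`SablastError`, so
callers (and the CLI) can distinguish user-input problems from genuine bugs
with a single ``except`` clause.
"""


class SablastError(Exception):
    """Base class for all sablast errors."""


class FastaParseError(SablastError):
    """A FASTA file could not be parsed; the message names the record."""


class SequenceValidationError(SablastError):
    """A residue string violates its declared alphabet."""


class CapacityError(SablastError):
    """The query does not fit in the configured systolic array."""


class StreamOrderError(SablastError):
    """A hits FIFO violated the stream-flow ordering contract."""


class MatrixFormatError(SablastError):
    """A substitution-matrix file is malformed, incomplete, or asymmetric."""
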