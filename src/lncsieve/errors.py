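"""Exception hierarchy for lncsieve."""


class LncsieveError(Exception):
    """Base class for all lncsieve-specific errors."""


class SequenceAlphabetError(LncsieveError, ValueError):
    """A sequence contains a character outside the {A, C, G, T, N} alphabet."""


class FastaParseError(LncsieveError, ValueError):
    """A FASTA file is malformed (reported with the offending line number)."""


class SchemaMismatchError(LncsieveError, ValueError):
    """Feature schema of a model and an extractor (or two tables) disagree."""


class ModelIOError(LncsieveError, OSError):
    """A model archive could not be read back (corrupt or truncated file)."""


class GenerationError(LncsieveError, RuntimeError):
    """The synthetic-sequence generator could not satisfy its constraints."""
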