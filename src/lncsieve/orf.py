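"""Open-reading-frame detection in the three forward frames.

An ORF is an ATG start codon followed by in-frame codons up to and
including the first in-frame stop codon (TAA, TAG or TGA).  Only the
three forward frames are scanned — no reverse-complement frames, no
alternative start codons.  The stop codon counts toward the ORF length,
so the minimal ORF (ATG directly followed by a stop) has length 6.

Coordinates are 0-based half-open internally; human-facing reports
(see :mod:`lncsieve.io`) convert to 1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import SequenceAlphabetError

ALPHABET = frozenset("ACGTN")
START_CODON = "ATG"
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


@dataclass(frozen=True)
class Sequence:
    """A nucleotide transcript, normalized to uppercase DNA.

    Lowercase input is uppercased and U is transliterated to T on
    construction, so RNA FASTA records are accepted transparently.
    Characters outside {A, C, G, T, N} raise
    :class:`~lncsieve.errors.SequenceAlphabetError`.
    """

    id: str
    bases: str

    def __post_init__(self) -> None:
        normalized = self.bases.upper().replace("U", "T")
        if not normalized:
            raise ValueError(f"sequence {self.id!r} is empty")
        for pos, ch in enumerate(normalized):
            if ch not in ALPHABET:
                raise SequenceAlphabetError(
                    f"sequence {self.id!r}: invalid character {ch!r} "
                    f"at position {pos + 1} (allowed: A, C, G, T, N)"
                )
        object.__setattr__(self, "bases", normalized)

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def length(self) -> int:
        return len(self.bases)


@dataclass(frozen=True, order=True)
class OrfRecord:
    """One open reading frame.

    ``frame`` is the forward-frame offset (0, 1 or 2), ``start`` the
    0-based index of the A of ATG, ``end`` the 0-based exclusive index
    one past the last base of the stop codon.  ``length`` includes both
    the start and the stop codon.
    """

    frame: int = field(compare=False)
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


def _as_sequence(seq: Sequence | str) -> Sequence:
    if isinstance(seq, Sequence):
        return seq
    return Sequence("query", seq)


def find_orfs(seq: Sequence | str) -> list[OrfRecord]:
    """Enumerate every maximal ORF in the three forward frames.

    For each frame, every ATG is paired with the first in-frame stop
    codon at or after it; an ATG with no downstream in-frame stop yields
    no ORF.  Codons containing N are neither start nor stop codons.

    The result is sorted by descending length, ties broken by ascending
    start position, then ascending frame.
    """
    seq = _as_sequence(seq)
    bases = seq.bases
    n = len(bases)
    orfs: list[OrfRecord] = []
    for frame in range(3):
        open_starts: list[int] = []
        for pos in range(frame, n - 2, 3):
            codon = bases[pos : pos + 3]
            if codon == START_CODON:
                open_starts.append(pos)
            elif codon in STOP_CODONS and open_starts:
                end = pos + 3
                orfs.extend(OrfRecord(frame, s, end) for s in open_starts)
                open_starts.clear()
            elif codon in STOP_CODONS:
                open_starts.clear()
    orfs.sort(key=lambda o: (-o.length, o.start, o.frame))
    return orfs


def longest_orf(seq: Sequence | str) -> OrfRecord | None:
    """The longest ORF of ``seq`` (deterministic tie-break), or None."""
    orfs = find_orfs(seq)
    return orfs[0] if orfs else None


def orf_features(seq: Sequence | str) -> tuple[int, float]:
    """The two ORF features: longest-ORF length and ORF coverage.

    Coverage is the longest-ORF length divided by the transcript
    length.  Both are 0 when the sequence contains no ORF.
    """
    seq = _as_sequence(seq)
    best = longest_orf(seq)
    if best is None:
        return 0, 0.0
    return best.length, best.length / seq.length
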