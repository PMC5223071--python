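"""ORF-restricted k-mer frequency features and composition contrasts.

The feature vector of a transcript has 1,366 entries: the longest-ORF
length, the ORF coverage, and the frequencies of all k-mers for
k = 1..5 (4 + 16 + 64 + 256 + 1024 = 1,364 of them), counted with
overlapping windows *inside the longest ORF* and normalized by
l − k + 1, where l is the length of the counted region.  Restricting
the counts to the ORF removes the diluting effect of UTRs, which make
coding transcripts look noncoding when whole-sequence composition is
used.

The k-mer ordering (k ascending, lexicographic over A < C < G < T
within each k) is a frozen schema; its version string is stored in
trained models so extractor and model cannot drift apart.
"""

from __future__ import annotations

import warnings
from itertools import product

import numpy as np
import pandas as pd

from .errors import SchemaMismatchError
from .orf import Sequence, longest_orf, _as_sequence

ALPHABET = ("A", "C", "G", "T")

#: Frozen identifier of the feature layout; recorded in model archives.
SCHEMA_VERSION = "orf+kmer[k=1..5,lex]/1"


class KmerSpec:
    """The ordered k-mer index: a bijection k-mer string <-> position.

    Positions run over k ascending and, within each k, lexicographic
    order of the k-mer over the alphabet (A, C, G, T).
    """

    def __init__(self, k_values: tuple[int, ...] = (1, 2, 3, 4, 5)):
        self.k_values = tuple(k_values)
        self.kmers: tuple[str, ...] = tuple(
            "".join(p) for k in self.k_values for p in product(ALPHABET, repeat=k)
        )
        self._index = {m: i for i, m in enumerate(self.kmers)}

    @staticmethod
    def size_for_k(k: int) -> int:
        """Number of distinct k-mers over a 4-letter alphabet."""
        return 4**k

    @property
    def n_kmers(self) -> int:
        return len(self.kmers)

    def index(self, kmer: str) -> int:
        return self._index[kmer]


DEFAULT_SPEC = KmerSpec()

#: Names of all 1,366 features in schema order.
FEATURE_NAMES: tuple[str, ...] = ("orf_length", "orf_coverage") + DEFAULT_SPEC.kmers
N_FEATURES = len(FEATURE_NAMES)

# base -> lexicographic code; anything else (N) -> -1
_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(ALPHABET):
    _CODE[ord(_b)] = _i


def _encode(region: str) -> np.ndarray:
    return _CODE[np.frombuffer(region.encode("ascii"), dtype=np.uint8)]


def kmer_frequencies(region: str, k: int) -> np.ndarray:
    """Overlapping-window k-mer frequencies of ``region``.

    Entry i holds count(k-mer i) / (l − k + 1) with l = len(region).
    Windows containing N are skipped in the numerator while the
    denominator stays l − k + 1, keeping the formula literal.  A region
    shorter than k yields an all-zero vector with a warning.
    """
    if not 1 <= k <= 5:
        raise ValueError(f"k must be in 1..5, got {k}")
    codes = _encode(region.upper())
    n_windows = codes.size - k + 1
    out = np.zeros(KmerSpec.size_for_k(k), dtype=np.float64)
    if n_windows <= 0:
        warnings.warn(
            f"region of length {codes.size} is shorter than k={k}; "
            "returning all-zero frequencies",
            stacklevel=2,
        )
        return out
    valid = codes >= 0
    idx = np.zeros(n_windows, dtype=np.int64)
    ok = np.ones(n_windows, dtype=bool)
    for j in range(k):
        idx = idx * 4 + np.where(valid[j : j + n_windows], codes[j : j + n_windows], 0)
        ok &= valid[j : j + n_windows]
    counts = np.bincount(idx[ok], minlength=out.size)
    return counts / n_windows


def extract_features(seq: Sequence | str, region: str = "orf") -> np.ndarray:
    """The full 1,366-element feature vector of a transcript.

    With ``region="orf"`` (the default) the k-mer block is counted on
    the longest-ORF substring; when the sequence has no ORF the whole
    sequence is used as fallback so every input stays classifiable.
    ``region="full"`` always counts on the whole sequence (the
    whole-transcript comparison mode).
    """
    if region not in ("orf", "full"):
        raise ValueError(f"region must be 'orf' or 'full', got {region!r}")
    seq = _as_sequence(seq)
    best = longest_orf(seq)
    if best is None:
        orf_len, coverage = 0, 0.0
        counted = seq.bases
    else:
        orf_len, coverage = best.length, best.length / seq.length
        counted = seq.bases[best.start : best.end] if region == "orf" else seq.bases
    if region == "full":
        counted = seq.bases
    blocks = [kmer_frequencies(counted, k) for k in DEFAULT_SPEC.k_values]
    return np.concatenate([[float(orf_len), coverage], *blocks])


def feature_frame(seqs: list[Sequence], region: str = "orf") -> pd.DataFrame:
    """Feature matrix for a list of sequences, one row per transcript."""
    matrix = np.vstack([extract_features(s, region=region) for s in seqs]) if seqs else (
        np.empty((0, N_FEATURES))
    )
    index = pd.Index([s.id for s in seqs], name="id")
    return pd.DataFrame(matrix, index=index, columns=list(FEATURE_NAMES))


def class_mean_frequencies(features: pd.DataFrame) -> pd.Series:
    """Per-k-mer mean frequencies of a feature matrix (ORF features dropped)."""
    return features[list(DEFAULT_SPEC.kmers)].mean(axis=0)


def log2_ratio(mean_a: pd.Series, mean_b: pd.Series) -> pd.DataFrame:
    """Elementwise log2(mean_a / mean_b) composition contrast.

    Conventionally ``mean_a`` holds the lncRNA class and ``mean_b`` the
    coding class, so positive ratios mark k-mers enriched in lncRNAs.
    Pairs where either mean is 0 are reported as NaN (undefined), never
    as ±infinity.
    """
    if not mean_a.index.equals(mean_b.index):
        raise SchemaMismatchError("k-mer sets of the two tables differ")
    a = mean_a.to_numpy(dtype=float)
    b = mean_b.to_numpy(dtype=float)
    defined = (a > 0) & (b > 0)
    ratio = np.full(a.shape, np.nan)
    ratio[defined] = np.log2(a[defined] / b[defined])
    return pd.DataFrame(
        {"mean_a": a, "mean_b": b, "log2_ratio": ratio}, index=mean_a.index
    )
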