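"""Seeded two-class synthetic transcript generator.

The generator emulates the structural contrast the classifier exploits:
coding-like transcripts carry one long planted ORF (ATG + stop-free
internal codons drawn from a biased codon table + stop codon) flanked
by UTR-like segments of noncoding composition, while noncoding-like
transcripts are sampled from a distinct nucleotide bias and rejected
whenever their longest ORF exceeds a cap.  All transcripts are longer
than 200 nt, matching the usual lncRNA length definition.

Every draw is derived from the config seed, so a config generates the
same FASTA byte-for-byte on every run.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from itertools import product
from pathlib import Path

import numpy as np
import yaml

from .errors import GenerationError
from .orf import STOP_CODONS, Sequence, longest_orf

_BASES = ("A", "C", "G", "T")
SENSE_CODONS = tuple(
    "".join(c) for c in product(_BASES, repeat=3) if "".join(c) not in STOP_CODONS
)


def _check_weights(name: str, w: tuple[float, ...], n: int) -> np.ndarray:
    arr = np.asarray(w, dtype=float)
    if arr.shape != (n,) or (arr < 0).any() or arr.sum() <= 0:
        raise ValueError(f"{name}: need {n} nonnegative weights with positive sum")
    return arr / arr.sum()


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic two-class transcript set.

    ``min_codons``/``max_codons`` count the *internal* codons of the
    planted coding ORF (total ORF length is 3·(codons + 2) nt including
    start and stop).  ``max_orf_codons`` caps the longest ORF of a
    noncoding transcript the same way.  Base weights are multinomial
    probabilities over (A, C, G, T); the coding codon table is the
    product measure of the coding base weights restricted to the 61
    sense codons.
    """

    n_per_class: int = 400
    seed: int = 42
    min_codons: int = 80
    max_codons: int = 300
    utr5_range: tuple[int, int] = (20, 150)
    utr3_range: tuple[int, int] = (50, 300)
    coding_base_weights: tuple[float, float, float, float] = (0.18, 0.32, 0.32, 0.18)
    noncoding_base_weights: tuple[float, float, float, float] = (0.32, 0.18, 0.18, 0.32)
    noncoding_length_range: tuple[int, int] = (300, 1500)
    max_orf_codons: int = 30
    max_retries: int = 1000

    def __post_init__(self) -> None:
        if self.n_per_class < 0:
            raise ValueError("n_per_class must be nonnegative")
        if self.min_codons < 1 or self.min_codons > self.max_codons:
            raise ValueError("need 1 <= min_codons <= max_codons")
        for name, rng in (
            ("utr5_range", self.utr5_range),
            ("utr3_range", self.utr3_range),
            ("noncoding_length_range", self.noncoding_length_range),
        ):
            lo, hi = rng
            if lo < 0 or lo > hi:
                raise ValueError(f"{name}: need 0 <= min <= max")
        if self.max_orf_codons < 0:
            raise ValueError("max_orf_codons must be nonnegative")
        if self.noncoding_length_range[0] <= 200:
            raise ValueError("noncoding transcripts must be longer than 200 nt")
        _check_weights("coding_base_weights", self.coding_base_weights, 4)
        _check_weights("noncoding_base_weights", self.noncoding_base_weights, 4)

    def codon_weights(self) -> np.ndarray:
        """Sense-codon probabilities induced by the coding base weights."""
        base = _check_weights("coding_base_weights", self.coding_base_weights, 4)
        per_base = dict(zip(_BASES, base))
        w = np.array(
            [per_base[c[0]] * per_base[c[1]] * per_base[c[2]] for c in SENSE_CODONS]
        )
        return w / w.sum()


def _random_bases(rng: np.random.Generator, n: int, weights) -> str:
    if n == 0:
        return ""
    picks = rng.choice(4, size=n, p=np.asarray(weights, dtype=float))
    return "".join(_BASES[i] for i in picks)


def generate_coding(config: GeneratorConfig) -> list[Sequence]:
    """Coding-like transcripts: UTR + planted long ORF + UTR.

    The planted ORF uses stop-free internal codons, so its own frame
    contains no premature stop and the longest ORF of every transcript
    is at least 3·(min_codons + 2) nt.
    """
    rng = np.random.default_rng([config.seed, 0])
    nc_w = _check_weights("noncoding_base_weights", config.noncoding_base_weights, 4)
    codon_w = config.codon_weights()
    seqs = []
    for i in range(config.n_per_class):
        utr5 = _random_bases(rng, rng.integers(*config.utr5_range, endpoint=True), nc_w)
        utr3 = _random_bases(rng, rng.integers(*config.utr3_range, endpoint=True), nc_w)
        n_codons = int(rng.integers(config.min_codons, config.max_codons, endpoint=True))
        codons = rng.choice(len(SENSE_CODONS), size=n_codons, p=codon_w)
        orf = "ATG" + "".join(SENSE_CODONS[c] for c in codons) + (
            ("TAA", "TAG", "TGA")[rng.integers(3)]
        )
        seqs.append(Sequence(f"coding_{i:04d}", utr5 + orf + utr3))
    return seqs


def generate_noncoding(config: GeneratorConfig) -> list[Sequence]:
    """Noncoding-like transcripts with all ORFs below the cap.

    Candidates are sampled from the noncoding base bias and rejected
    while their longest ORF exceeds 3·(max_orf_codons + 2) nt, keeping
    the composition model clean (no post-editing of stops).  Exceeding
    the retry budget raises GenerationError.
    """
    rng = np.random.default_rng([config.seed, 1])
    return _rejection_sample(rng, config, "noncoding")


def _rejection_sample(
    rng: np.random.Generator, config: GeneratorConfig, prefix: str
) -> list[Sequence]:
    nc_w = _check_weights("noncoding_base_weights", config.noncoding_base_weights, 4)
    cap_nt = 3 * (config.max_orf_codons + 2)
    seqs = []
    for i in range(config.n_per_class):
        for _ in range(config.max_retries):
            n = int(rng.integers(*config.noncoding_length_range, endpoint=True))
            candidate = _random_bases(rng, n, nc_w)
            best = longest_orf(candidate)
            if best is None or best.length <= cap_nt:
                seqs.append(Sequence(f"{prefix}_{i:04d}", candidate))
                break
        else:
            raise GenerationError(
                f"could not sample a transcript with longest ORF <= {cap_nt} nt "
                f"within {config.max_retries} tries; relax max_orf_codons"
            )
    return seqs


def generate_dataset(config: GeneratorConfig) -> tuple[list[Sequence], list[Sequence]]:
    """The default two-class set: (coding-like, noncoding-like)."""
    return generate_coding(config), generate_noncoding(config)


def generate_null_dataset(
    config: GeneratorConfig,
) -> tuple[list[Sequence], list[Sequence]]:
    """Null control: both classes drawn from the same noncoding model.

    The two arms use different child seeds, so the sets differ but
    share one distribution — a classifier should sit at chance level.
    """
    rng_a = np.random.default_rng([config.seed, 2])
    rng_b = np.random.default_rng([config.seed, 3])
    a = _rejection_sample(rng_a, config, "nullA")
    b = _rejection_sample(rng_b, config, "nullB")
    return a, b


def load_config(path: str | Path) -> GeneratorConfig:
    """Read a GeneratorConfig from a YAML mapping (missing keys default)."""
    with open(path) as fh:
        payload = yaml.safe_load(fh) or {}
    for key in ("utr5_range", "utr3_range", "noncoding_length_range",
                "coding_base_weights", "noncoding_base_weights"):
        if key in payload:
            payload[key] = tuple(payload[key])
    return GeneratorConfig(**payload)


def save_config(config: GeneratorConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=False)
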