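"""Deterministic k-mer signature-image encoder.

A character sequence (a molecule SMILES string or a protein amino-acid
sequence) is mapped to a square image in six steps:

1. tokenize the raw text against a fixed ordered alphabet of n symbols;
2. enumerate the n^k possible k-mers in lexicographic order by alphabet
   position;
3. slide a length-k window over the cleaned sequence, yielding l = c - k + 1
   words;
4. count the occurrences of every possible k-mer into a vector of length n^k;
5. divide by the maximum count, producing a profile with values in [0, 1] and
   maximum exactly 1;
6. pad the profile with e = m^2 - n^k trailing zeros, m = ceil(sqrt(n^k)),
   and reshape row-major into an m-by-m matrix.

With the defaults used throughout the package — k=2 over the 36-symbol SMILES
alphabet and k=3 over the 21-symbol protein alphabet — the images are 36x36
(no padding) and 97x97 (148 padding cells) respectively.  The encoder is a
pure function: identical input always yields a bit-identical image.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .alphabets import MOLECULE_ALPHABET, PROTEIN_ALPHABET, Alphabet

Policy = Literal["error", "drop"]

#: default k-mer length per sequence type
DEFAULT_K = {"molecule": 2, "protein": 3}


class EncodingError(ValueError):
    """Raised when a sequence cannot be encoded under the active policy."""


@dataclass(frozen=True)
class SequenceRecord:
    """A tokenized sequence: raw text, in-alphabet characters, drop count."""

    identifier: str
    raw: str
    cleaned: str
    dropped_count: int

    def __post_init__(self) -> None:
        if len(self.cleaned) + self.dropped_count != len(self.raw):
            raise ValueError("cleaned length + dropped_count must equal raw length")

    def __len__(self) -> int:
        return len(self.cleaned)


@dataclass(frozen=True)
class KmerSpace:
    """The indexing geometry of all k-mers over an alphabet.

    Attributes
    ----------
    nk : total number of possible k-mers, n^k.
    m : side of the square signature image, ceil(sqrt(nk)).
    e : number of zero cells padded after the profile, m^2 - nk.
    """

    alphabet: Alphabet
    k: int

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be a positive integer")

    @property
    def n(self) -> int:
        return self.alphabet.size

    @property
    def nk(self) -> int:
        return self.n**self.k

    @property
    def m(self) -> int:
        r = math.isqrt(self.nk)
        return r if r * r == self.nk else r + 1

    @property
    def e(self) -> int:
        return self.m**2 - self.nk


#: default spaces for the two branches of the affinity model
MOLECULE_SPACE = KmerSpace(MOLECULE_ALPHABET, DEFAULT_K["molecule"])
PROTEIN_SPACE = KmerSpace(PROTEIN_ALPHABET, DEFAULT_K["protein"])


@dataclass(frozen=True)
class KmerCountVector:
    """Raw occurrence counts of every possible k-mer of a sequence."""

    space: KmerSpace
    counts: np.ndarray  # int64, length space.nk

    @property
    def l(self) -> int:
        """Number of windows counted (= cleaned length - k + 1)."""
        return int(self.counts.sum())


@dataclass(frozen=True)
class SignatureImage:
    """The m-by-m max-normalized k-mer frequency image of one sequence."""

    space: KmerSpace
    pixels: np.ndarray  # float64, shape (m, m), values in [0, 1]


def tokenize(
    raw: str,
    alphabet: Alphabet,
    policy: Policy = "drop",
    identifier: str = "",
) -> SequenceRecord:
    """Clean *raw* against *alphabet*, preserving order.

    Under ``policy="drop"`` characters outside the alphabet are removed and
    counted; under ``policy="error"`` the first foreign character aborts with
    its position (1-based).  An input that is empty after cleaning is
    rejected either way.
    """
    if policy not in ("error", "drop"):
        raise ValueError(f"unknown policy {policy!r}")
    kept: list[str] = []
    dropped = 0
    for pos, ch in enumerate(raw, start=1):
        if ch in alphabet:
            kept.append(ch)
        elif policy == "error":
            raise EncodingError(
                f"character {ch!r} at position {pos} is not in the {alphabet.name}"
            )
        else:
            dropped += 1
    if not kept:
        raise EncodingError("sequence is empty after cleaning")
    return SequenceRecord(
        identifier=identifier, raw=raw, cleaned="".join(kept), dropped_count=dropped
    )


def kmer_index(word: str, space: KmerSpace) -> int:
    """Rank of *word* among all k-mers, in lexicographic order by alphabet
    position (base-n positional value).  Bijective onto ``[0, nk)``."""
    if len(word) != space.k:
        raise EncodingError(f"word {word!r} does not have length k={space.k}")
    idx = 0
    for ch in word:
        idx = idx * space.n + space.alphabet.index(ch)
    return idx


def count_kmers(seq: SequenceRecord, space: KmerSpace) -> KmerCountVector:
    """Count every overlapping k-mer of ``seq.cleaned`` into a length-nk vector.

    The sum of the counts equals the number of windows l = c - k + 1.
    """
    c = len(seq.cleaned)
    if c < space.k:
        raise EncodingError(
            f"sequence of length {c} is shorter than k={space.k}"
        )
    codes = np.fromiter(
        (space.alphabet.index(ch) for ch in seq.cleaned), dtype=np.int64, count=c
    )
    # base-n positional value of each window, vectorized over all l windows
    idx = np.zeros(c - space.k + 1, dtype=np.int64)
    for j in range(space.k):
        idx = idx * space.n + codes[j : c - space.k + 1 + j]
    counts = np.bincount(idx, minlength=space.nk)
    return KmerCountVector(space=space, counts=counts)


def normalize(counts: KmerCountVector) -> np.ndarray:
    """Divide the count vector by its maximum; output has max 1, zeros kept."""
    f = counts.counts.max()
    if f <= 0:
        raise EncodingError("cannot normalize an all-zero count vector")
    return counts.counts.astype(np.float64) / float(f)


def to_image(normalized: np.ndarray, space: KmerSpace) -> SignatureImage:
    """Pad the length-nk profile with e trailing zeros and reshape to m x m."""
    normalized = np.asarray(normalized, dtype=np.float64)
    if normalized.ndim != 1 or normalized.shape[0] != space.nk:
        raise EncodingError(
            f"profile has length {normalized.size}, expected nk={space.nk}"
        )
    flat = np.concatenate([normalized, np.zeros(space.e, dtype=np.float64)])
    return SignatureImage(space=space, pixels=flat.reshape(space.m, space.m))


def encode(
    raw: str,
    alphabet: Alphabet,
    k: int,
    policy: Policy = "drop",
    identifier: str = "",
) -> SignatureImage:
    """Full pipeline: tokenize -> count k-mers -> max-normalize -> reshape."""
    space = KmerSpace(alphabet, k)
    seq = tokenize(raw, alphabet, policy=policy, identifier=identifier)
    return to_image(normalize(count_kmers(seq, space)), space)


def encode_molecule(smiles: str, k: int = 2, policy: Policy = "drop") -> SignatureImage:
    """Encode a SMILES string with the 36-symbol molecule alphabet (36x36 at k=2)."""
    return encode(smiles, MOLECULE_ALPHABET, k, policy=policy)


def encode_protein(sequence: str, k: int = 3, policy: Policy = "drop") -> SignatureImage:
    """Encode an amino-acid sequence with the 21-symbol alphabet (97x97 at k=3)."""
    return encode(sequence, PROTEIN_ALPHABET, k, policy=policy)


def to_grayscale_png(image: SignatureImage, path: str) -> None:
    """Export an 8-bit grayscale PNG (pixel*255, rounded). Lossy; for viewing only."""
    from PIL import Image

    arr = np.round(image.pixels * 255.0).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(path)
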