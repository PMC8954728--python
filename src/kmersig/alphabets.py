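"""Fixed, ordered symbol sets for molecule SMILES and protein sequences.

The ordering is load-bearing: a k-mer's index in the count vector is its rank
in row-major lexicographic order by alphabet position, so the printed order of
the symbols below defines the pixel layout of every signature image.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class Alphabet:
    """An ordered set of single-character symbols.

    Parameters
    ----------
    symbols
        The symbols in their canonical order. Must be unique single characters.
    name
        Human-readable label used in error messages and manifests.
    """

    symbols: tuple[str, ...]
    name: str = "alphabet"
    _index: dict[str, int] = field(init=False, repr=False, compare=False, hash=False)

    def __post_init__(self) -> None:
        if len(set(self.symbols)) != len(self.symbols):
            raise ValueError(f"{self.name}: symbols must be unique")
        if any(len(s) != 1 for s in self.symbols):
            raise ValueError(f"{self.name}: symbols must be single characters")
        object.__setattr__(self, "_index", {s: i for i, s in enumerate(self.symbols)})

    @property
    def size(self) -> int:
        return len(self.symbols)

    def index(self, symbol: str) -> int:
        """Position of *symbol* in the canonical order (0-based)."""
        try:
            return self._index[symbol]
        except KeyError:
            raise KeyError(f"{symbol!r} is not in the {self.name}") from None

    def __contains__(self, symbol: str) -> bool:
        return symbol in self._index

    def __len__(self) -> int:
        return self.size


#: 36-symbol SMILES character set: element symbols (upper and aromatic
#: lowercase), ring-closure digits, branches, brackets, bonds and charges.
#: Character-level: "Cl" tokenizes as 'C','l' and "Br" as 'B','r'.
MOLECULE_ALPHABET = Alphabet(
    symbols=tuple("BCHNOSPFIbclnospr0123456789()[]=.+-#"),
    name="molecule alphabet",
)

#: 21-symbol amino-acid set: the 20 standard residues plus the ambiguity
#: code X, in alphabetical order.
PROTEIN_ALPHABET = Alphabet(
    symbols=tuple("ACDEFGHIKLMNPQRSTVWXY"),
    name="protein alphabet",
)
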