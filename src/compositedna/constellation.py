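"""The composite-letter constellation: a 15-point tetrahedral alphabet over {A,T,G,C}.

A composite letter is a synthesis position at which several phosphoramidite
monomers are mixed, so the molecular population at that position carries a base
*distribution* sigma = (sigma_A, sigma_T, sigma_G, sigma_C) rather than a single
base.  Restricting mixtures to equimolar combinations of 1, 2, 3 or 4 natural
bases yields exactly 15 letters — the vertices, edge centres, face centres and
centroid of the base tetrahedron — which coincide with the 15 IUPAC nucleotide
codes.  The 15 letters fall into four subsets by their theoretical Shannon
entropy (0, 1, log2 3 and 2 bits); this discreteness is what the two-stage
set-partitioning detector in :mod:`compositedna.detection` exploits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "BASES",
    "BASE_INDEX",
    "IUPAC_COMPOSITION",
    "CompositeLetter",
    "Alphabet",
    "ALPHABET_1",
    "ALPHABET_2",
    "ALPHABET_3",
    "ALPHABET_4",
    "BUILTIN_ALPHABETS",
    "letter_sigma",
    "shannon_entropy",
    "distinct_entropy_levels",
    "letter_distance",
    "ENTROPY_LEVELS",
]

#: Fixed base-axis order used for every sigma vector in the package.
BASES = ("A", "T", "G", "C")
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: Constituent natural bases of each IUPAC code (equimolar mixtures).
IUPAC_COMPOSITION: dict[str, str] = {
    "A": "A", "T": "T", "G": "G", "C": "C",
    "R": "AG", "Y": "CT", "M": "AC", "K": "GT", "S": "CG", "W": "AT",
    "H": "ACT", "B": "CGT", "V": "ACG", "D": "AGT",
    "N": "ACGT",
}

#: Theoretical per-letter entropies of the four subsets, in bits.
ENTROPY_LEVELS = (0.0, 1.0, math.log2(3.0), 2.0)


class AlphabetError(ValueError):
    """Unknown symbol or malformed alphabet."""


def letter_sigma(symbol: str, epsilon: float = 0.0) -> np.ndarray:
    """Probability 4-vector of a composite letter over (A, T, G, C).

    The letter is an equimolar mixture of its constituent bases.  With
    ``epsilon > 0``, exact zeros are replaced by ``epsilon`` and the vector is
    renormalised to sum to one (smoothing keeps log-likelihoods finite).

    Parameters
    ----------
    symbol : str
        One of the 15 IUPAC letters.
    epsilon : float
        Smoothing probability, ``0 <= epsilon < 0.25``.
    """
    comp = IUPAC_COMPOSITION.get(symbol)
    if comp is None:
        raise AlphabetError(f"unknown composite letter {symbol!r}")
    if not 0.0 <= epsilon < 0.25:
        raise ValueError("epsilon must lie in [0, 0.25)")
    sigma = np.zeros(4)
    for b in comp:
        sigma[BASE_INDEX[b]] = 1.0 / len(comp)
    if epsilon > 0.0:
        sigma[sigma == 0.0] = epsilon
        sigma /= sigma.sum()
    return sigma


def shannon_entropy(p: Sequence[float] | np.ndarray) -> float:
    """Shannon entropy of a base-probability vector, in bits (0·log 0 := 0)."""
    p = np.asarray(p, dtype=float)
    if np.any(p < -1e-12):
        raise ValueError("probability components must be non-negative")
    if abs(float(p.sum()) - 1.0) > 1e-6:
        raise ValueError("probability vector must sum to 1")
    pos = p[p > 0.0]
    return float(-(pos * np.log2(pos)).sum())


@dataclass(frozen=True)
class CompositeLetter:
    """One point of the constellation.

    ``sigma`` is the pre-smoothing (exact) composition vector; ``subset`` is
    the number of constituent bases (1..4); ``theoretical_entropy`` is
    ``log2(subset support size)`` in bits.
    """

    symbol: str
    sigma: tuple[float, float, float, float] = field(init=False)
    subset: int = field(init=False)
    theoretical_entropy: float = field(init=False)

    def __post_init__(self) -> None:
        sig = letter_sigma(self.symbol, 0.0)
        support = int((sig > 0).sum())
        object.__setattr__(self, "sigma", tuple(float(x) for x in sig))
        object.__setattr__(self, "subset", support)
        object.__setattr__(self, "theoretical_entropy", math.log2(support))

    def sigma_smoothed(self, epsilon: float = 1e-6) -> np.ndarray:
        return letter_sigma(self.symbol, epsilon)


@dataclass(frozen=True)
class Alphabet:
    """An ordered composite-letter alphabet with its bit-group geometry.

    ``bits_per_group`` bits are mapped onto ``letters_per_group`` letters by
    :func:`compositedna.mapping.bits_to_letters`: 3 bits -> 1 letter for the
    8-letter alphabets, 15 bits -> 4 base-15 digits for the full 15-letter set.
    """

    name: str
    letters: tuple[CompositeLetter, ...]
    bits_per_group: int
    letters_per_group: int

    def __post_init__(self) -> None:
        symbols = [l.symbol for l in self.letters]
        if len(set(symbols)) != len(symbols):
            raise AlphabetError("alphabet symbols must be distinct")

    def __len__(self) -> int:
        return len(self.letters)

    @property
    def symbols(self) -> tuple[str, ...]:
        return tuple(l.symbol for l in self.letters)

    def index(self, symbol: str) -> int:
        try:
            return self.symbols.index(symbol)
        except ValueError:
            raise AlphabetError(f"{symbol!r} not in alphabet {self.name}") from None

    def sigma_matrix(self, epsilon: float = 0.0) -> np.ndarray:
        """(n_letters, 4) matrix of composition vectors."""
        return np.stack([letter_sigma(s, epsilon) for s in self.symbols])

    def to_table(self) -> str:
        """Plain-text table: symbol, sigma_A, sigma_T, sigma_G, sigma_C."""
        lines = ["symbol\tsigma_A\tsigma_T\tsigma_G\tsigma_C"]
        for l in self.letters:
            lines.append(l.symbol + "\t" + "\t".join(f"{x:.10g}" for x in l.sigma))
        return "\n".join(lines) + "\n"

    @classmethod
    def from_symbols(
        cls,
        name: str,
        symbols: Iterable[str],
        bits_per_group: int | None = None,
        letters_per_group: int | None = None,
    ) -> "Alphabet":
        letters = tuple(CompositeLetter(s) for s in symbols)
        if bits_per_group is None or letters_per_group is None:
            if len(letters) == 8:
                bits_per_group, letters_per_group = 3, 1
            elif len(letters) == 15:
                bits_per_group, letters_per_group = 15, 4
            else:
                raise AlphabetError(
                    "bits_per_group/letters_per_group required for "
                    f"{len(letters)}-letter alphabet"
                )
        return cls(name, letters, bits_per_group, letters_per_group)

    @classmethod
    def from_table(cls, text: str, name: str = "custom", **kw) -> "Alphabet":
        """Inverse of :meth:`to_table` (compositions re-derived from symbols)."""
        rows = [ln.split("\t") for ln in text.strip().splitlines()[1:]]
        return cls.from_symbols(name, [r[0] for r in rows], **kw)


def distinct_entropy_levels(alphabet: Alphabet) -> list[float]:
    """Sorted unique theoretical entropies of the alphabet's letters, in bits."""
    if len(alphabet) == 0:
        raise AlphabetError("alphabet is empty")
    return sorted({l.theoretical_entropy for l in alphabet.letters})


def letter_distance(a: CompositeLetter | str, b: CompositeLetter | str) -> float:
    """Euclidean distance between two letters' exact composition vectors."""
    sa = letter_sigma(a.symbol if isinstance(a, CompositeLetter) else a)
    sb = letter_sigma(b.symbol if isinstance(b, CompositeLetter) else b)
    return float(np.linalg.norm(sa - sb))


# The four built-in alphabets, in their canonical printed order.  The order
# fixes the bit/digit -> letter tables used by the mapping layer.
ALPHABET_1 = Alphabet.from_symbols("alphabet1", "ATGCRYMK")
ALPHABET_2 = Alphabet.from_symbols("alphabet2", "ATRYMKSW")
ALPHABET_3 = Alphabet.from_symbols("alphabet3", "ATGCHBVD")
ALPHABET_4 = Alphabet.from_symbols("alphabet4", "ATGCRMYKSWHBVDN")

BUILTIN_ALPHABETS = {
    a.name: a for a in (ALPHABET_1, ALPHABET_2, ALPHABET_3, ALPHABET_4)
}
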