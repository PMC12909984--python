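"""Bit <-> composite-letter mapping, strand framing, and layout arithmetic.

Two mapping schemes are supported, fixed by the alphabet's group geometry:

* 8-letter alphabets: every 3 bits select one letter from the alphabet's
  printed order (mapping efficiency 3/3 = 100%).
* 15-letter alphabet: every 15 bits are read as an integer and written as four
  base-15 digits, most significant first; each digit selects a letter
  (efficiency 15 / (4 log2 15) ~ 96%).

The encoded letter stream is cut into 60-letter payloads, each framed by an
address index and a PCR primer at both ends.  All density / capacity / strand
count arithmetic for a configuration lives in :func:`frame_stats`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .constellation import (
    ALPHABET_1,
    ALPHABET_4,
    Alphabet,
    AlphabetError,
)
from .index_coding import DoubleEndIndexCodec

__all__ = [
    "CodeConfig",
    "StrandFrame",
    "FrameStats",
    "bits_to_letters",
    "letters_to_bits",
    "mapping_efficiency",
    "frame_stats",
    "build_frames",
    "PRESETS",
    "DEFAULT_PRIMER_5P",
    "DEFAULT_PRIMER_3P",
    "ERASURE_MARK",
]

#: Default 20-nt amplification primers (natural bases only).
DEFAULT_PRIMER_5P = "ACACGACGCTCTTCCGATCT"
DEFAULT_PRIMER_3P = "AGATCGGAAGAGCACACGTC"

#: Symbol used for an undetectable (erased) letter in string form.
ERASURE_MARK = "?"


class CapacityError(ValueError):
    """File exceeds the configuration's payload capacity."""


@dataclass(frozen=True)
class CodeConfig:
    """Everything that determines strand layout and code geometry.

    ``ecc`` selects the outer code: ``"rs"`` (full encode/decode support) or
    ``"nbldpc"`` (layout arithmetic only; decoding such codes is delegated to
    an external plug-in decoder).
    """

    name: str
    alphabet: Alphabet
    rs_n: int
    rs_k: int
    field_bits: int
    n_blocks: int = 1
    payload_letters: int = 60
    index_len_5p: int = 8
    index_len_3p: int = 8
    primer_5p: str = DEFAULT_PRIMER_5P
    primer_3p: str = DEFAULT_PRIMER_3P
    interleaver_seed: int = 2024
    ecc: str = "rs"

    def __post_init__(self):
        bpg = self.alphabet.bits_per_group
        if (self.field_bits * self.rs_n) % bpg or (self.field_bits * self.rs_k) % bpg:
            if self.field_bits % bpg:
                raise ValueError(
                    f"field_bits={self.field_bits} incompatible with "
                    f"{bpg}-bit letter groups"
                )
        letters = self.n_blocks * self.rs_n * self.letters_per_symbol
        if letters % self.payload_letters:
            raise ValueError("total letters not divisible by payload_letters")

    @property
    def primer_len_5p(self) -> int:
        return len(self.primer_5p)

    @property
    def primer_len_3p(self) -> int:
        return len(self.primer_3p)

    @property
    def letters_per_symbol(self) -> float:
        a = self.alphabet
        ls = self.field_bits * a.letters_per_group / a.bits_per_group
        return int(ls) if ls == int(ls) else ls

    @property
    def capacity_bytes(self) -> float:
        """Maximum file size, in bytes (may be fractional for odd geometries)."""
        bits = self.n_blocks * self.rs_k * self.field_bits
        return bits / 8

    @property
    def strand_count(self) -> int:
        letters = self.n_blocks * self.rs_n * self.letters_per_symbol
        return int(round(letters / self.payload_letters))

    @property
    def total_strand_length(self) -> int:
        return (
            self.primer_len_5p
            + self.index_len_5p
            + self.payload_letters
            + self.index_len_3p
            + self.primer_len_3p
        )


@dataclass(frozen=True)
class StrandFrame:
    """One synthesis unit: primer5 | index5 | payload | index3 | primer3."""

    address: int
    primer5: str
    index5: str
    payload: str
    index3: str
    primer3: str

    @property
    def sequence(self) -> str:
        """Full strand in IUPAC letters (composite payload, natural flanks)."""
        return self.primer5 + self.index5 + self.payload + self.index3 + self.primer3

    def __len__(self) -> int:
        return len(self.sequence)


# ---------------------------------------------------------------------------
# bit <-> letter mapping
# ---------------------------------------------------------------------------

def _as_bit_array(bits) -> np.ndarray:
    if isinstance(bits, str):
        return np.frombuffer(bits.encode(), dtype=np.uint8) - ord("0")
    return np.asarray(bits, dtype=np.uint8)


def bits_to_letters(bits, alphabet: Alphabet) -> tuple[str, int]:
    """Map a bit sequence to composite letters; returns (letters, pad_bits).

    The tail is zero-padded to a whole number of ``bits_per_group`` groups;
    the number of padding bits is returned so decoding can truncate.
    """
    b = _as_bit_array(bits)
    bpg = alphabet.bits_per_group
    pad = (-len(b)) % bpg
    if pad:
        b = np.concatenate([b, np.zeros(pad, dtype=np.uint8)])
    groups = b.reshape(-1, bpg)
    weights = (1 << np.arange(bpg - 1, -1, -1)).astype(np.int64)
    values = groups @ weights
    idx = _values_to_letter_indices(values, alphabet)
    symbols = np.frombuffer("".join(alphabet.symbols).encode(), dtype=np.uint8)
    return symbols[idx].tobytes().decode(), pad


def _values_to_letter_indices(values: np.ndarray, alphabet: Alphabet) -> np.ndarray:
    """Group values -> flat letter-index stream (MSB digit first)."""
    lpg = alphabet.letters_per_group
    if lpg == 1:
        return values.astype(np.int64)
    base = len(alphabet)
    digits = np.empty((len(values), lpg), dtype=np.int64)
    v = values.astype(np.int64)
    for d in range(lpg - 1, -1, -1):
        digits[:, d] = v % base
        v //= base
    return digits.reshape(-1)


def letters_to_bits(letters, alphabet: Alphabet) -> tuple[np.ndarray, np.ndarray]:
    """Inverse mapping; returns (bits, group_erased flags).

    ``letters`` may be a symbol string (``?`` marks an erased position) or an
    integer index array (-1 marks erasure).  A group is erased when it
    contains an erased letter or its base-15 value exceeds the 15-bit range;
    erased groups contribute zero bits and a True flag, feeding downstream
    errors-and-erasures decoding.
    """
    idx = _letters_to_indices(letters, alphabet)
    lpg = alphabet.letters_per_group
    bpg = alphabet.bits_per_group
    if len(idx) % lpg:
        raise ValueError("letter stream length not a multiple of letters_per_group")
    groups = idx.reshape(-1, lpg)
    erased = (groups < 0).any(axis=1)
    base = len(alphabet)
    vals = np.zeros(len(groups), dtype=np.int64)
    safe = np.where(groups < 0, 0, groups)
    for d in range(lpg):
        vals = vals * base + safe[:, d]
    over = vals >= (1 << bpg)
    erased |= over
    vals[erased] = 0
    shifts = np.arange(bpg - 1, -1, -1)
    bits = ((vals[:, None] >> shifts[None, :]) & 1).astype(np.uint8)
    return bits.reshape(-1), erased


def _letters_to_indices(letters, alphabet: Alphabet) -> np.ndarray:
    if isinstance(letters, np.ndarray):
        idx = letters.astype(np.int64)
        if np.any(idx >= len(alphabet)):
            raise AlphabetError("letter index outside alphabet")
        return idx
    lut = np.full(256, -2, dtype=np.int64)
    for i, s in enumerate(alphabet.symbols):
        lut[ord(s)] = i
    lut[ord(ERASURE_MARK)] = -1
    idx = lut[np.frombuffer(str(letters).encode(), dtype=np.uint8)]
    if np.any(idx == -2):
        raise AlphabetError("symbol outside alphabet in letter stream")
    return idx


def mapping_efficiency(alphabet: Alphabet) -> float:
    """Fraction of the alphabet's information capacity used by the bit mapping."""
    return alphabet.bits_per_group / (
        alphabet.letters_per_group * math.log2(len(alphabet))
    )


# ---------------------------------------------------------------------------
# layout arithmetic
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FrameStats:
    """Printed-layout numbers of a configuration (densities in bits/letter)."""

    strand_count: int
    n_codewords: int
    capacity_bytes: float
    payload_density: float
    payload_index_density: float
    total_strand_length: int
    mapping_efficiency: float
    alphabet_ceiling_bits: float
    file_bytes: int | None = None
    pad_bits: int | None = None


def frame_stats(config: CodeConfig, file_bytes: int | None = None) -> FrameStats:
    """Capacity, density and strand-count arithmetic for a configuration."""
    a = config.alphabet
    if file_bytes is not None and file_bytes > config.capacity_bytes:
        needed = math.ceil(file_bytes / config.capacity_bytes)
        raise CapacityError(
            f"{file_bytes} bytes exceed capacity {config.capacity_bytes:.1f}; "
            f"split into {needed} parts or add blocks"
        )
    density = (a.bits_per_group / a.letters_per_group) * (config.rs_k / config.rs_n)
    pid = (
        config.payload_letters
        * density
        / (config.payload_letters + config.index_len_5p + config.index_len_3p)
    )
    pad_bits = None
    if file_bytes is not None:
        pad_bits = config.n_blocks * config.rs_k * config.field_bits - 8 * file_bytes
    return FrameStats(
        strand_count=config.strand_count,
        n_codewords=config.n_blocks,
        capacity_bytes=config.capacity_bytes,
        payload_density=density,
        payload_index_density=pid,
        total_strand_length=config.total_strand_length,
        mapping_efficiency=mapping_efficiency(a),
        alphabet_ceiling_bits=math.log2(len(a)),
        file_bytes=file_bytes,
        pad_bits=pad_bits,
    )


# ---------------------------------------------------------------------------
# framing
# ---------------------------------------------------------------------------

class FramingError(ValueError):
    pass


def build_frames(
    payload_stream: str | Sequence[int],
    config: CodeConfig,
    index_codec,
) -> list[StrandFrame]:
    """Cut a letter stream into addressed, primer-flanked strand frames.

    Strand ``i`` (0-based) receives address ``i + 1`` encoded at both ends.
    """
    if not isinstance(payload_stream, str):
        symbols = np.frombuffer("".join(config.alphabet.symbols).encode(), np.uint8)
        payload_stream = symbols[np.asarray(payload_stream)].tobytes().decode()
    L = config.payload_letters
    if len(payload_stream) % L:
        raise FramingError("letter stream not divisible by payload_letters")
    n = len(payload_stream) // L
    if n > getattr(index_codec, "max_address", np.inf):
        raise FramingError(
            f"{n} strands exceed the index codec address space "
            f"({index_codec.max_address})"
        )
    frames = []
    for i in range(n):
        address = i + 1
        i5, i3 = index_codec.encode(address)
        frames.append(
            StrandFrame(
                address=address,
                primer5=config.primer_5p,
                index5=i5,
                payload=payload_stream[i * L : (i + 1) * L],
                index3=i3,
                primer3=config.primer_3p,
            )
        )
    return frames


# ---------------------------------------------------------------------------
# built-in presets
# ---------------------------------------------------------------------------

PRESETS: dict[str, CodeConfig] = {
    # 126-strand column-synthesis pool, high-rate RS over GF(2^12)
    "8col": CodeConfig(
        name="8col", alphabet=ALPHABET_1, rs_n=1890, rs_k=1575, field_bits=12,
        n_blocks=1, index_len_5p=8, index_len_3p=8,
    ),
    # 126-strand pool with the low-rate NB-LDPC outer code (layout only)
    "8col-ldpc": CodeConfig(
        name="8col-ldpc", alphabet=ALPHABET_1, rs_n=3780, rs_k=1260, field_bits=6,
        n_blocks=1, index_len_5p=8, index_len_3p=8, ecc="nbldpc",
    ),
    # 10,000-strand array-synthesis pools
    "8array": CodeConfig(
        name="8array", alphabet=ALPHABET_1, rs_n=3750, rs_k=3125, field_bits=12,
        n_blocks=40, index_len_5p=12, index_len_3p=12,
    ),
    "15array": CodeConfig(
        name="15array", alphabet=ALPHABET_4, rs_n=30000, rs_k=25000, field_bits=15,
        n_blocks=5, index_len_5p=12, index_len_3p=12,
    ),
    # 32,767-strand simulation-scale configuration
    "15sim": CodeConfig(
        name="15sim", alphabet=ALPHABET_4, rs_n=32767, rs_k=27767, field_bits=15,
        n_blocks=15, index_len_5p=12, index_len_3p=12,
    ),
}


def preset(name: str, **overrides) -> CodeConfig:
    """Fetch a built-in preset, optionally overriding fields."""
    cfg = PRESETS[name]
    return replace(cfg, **overrides) if overrides else cfg
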