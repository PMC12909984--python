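"""Double-end strand indices: BCH-protected addresses at both strand ends.

Each strand carries its 7-bit address twice, encoded differently at the two
ends so that a read can only be accepted when both ends agree:

* 5' index (8 nt): BCH(15,7) codeword of the address plus one even-parity bit
  over the codeword, 16 bits mapped to bases two at a time.
* 3' index (8 nt): ``p | address | p | rotl1(address)`` where ``p`` is the even
  parity of the address and ``rotl1`` is a circular left shift by one bit.

Requiring both observed ends to decode to the same address (with at most
``max_sub`` substituted nucleotides per end) eliminates crosstalk between
synthesis sites: a read whose two ends disagree is discarded rather than
polluting another strand's pileup.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from .ecc import bch15_7_decode, bch15_7_encode

__all__ = [
    "bits_to_bases",
    "bases_to_bits",
    "encode_index5",
    "encode_index3",
    "decode_index_pair",
    "IndexReject",
    "DoubleEndIndexCodec",
]

#: 2-bit -> base rule (MSB first within each pair).
_PAIR_TO_BASE = {0b00: "A", 0b01: "T", 0b10: "G", 0b11: "C"}
_BASE_TO_PAIR = {v: k for k, v in _PAIR_TO_BASE.items()}


def bits_to_bases(bits: str) -> str:
    """Map an even-length bit string to DNA: 00->A, 01->T, 10->G, 11->C."""
    if len(bits) % 2:
        raise ValueError("bit string must have even length")
    return "".join(
        _PAIR_TO_BASE[(int(bits[i]) << 1) | int(bits[i + 1])]
        for i in range(0, len(bits), 2)
    )


def bases_to_bits(seq: str) -> str:
    """Inverse of :func:`bits_to_bases`."""
    out = []
    for b in seq:
        try:
            out.append(f"{_BASE_TO_PAIR[b]:02b}")
        except KeyError:
            raise ValueError(f"non-natural base {b!r}") from None
    return "".join(out)


def _parity(value: int, width: int = 7) -> int:
    """Even-parity bit of a value's low ``width`` bits."""
    return bin(value & ((1 << width) - 1)).count("1") & 1


def _rotl7(value: int) -> int:
    return ((value << 1) | (value >> 6)) & 0x7F


def encode_index5(address: int) -> str:
    """8-nt 5' index: BCH(15,7)(address) followed by an even-parity bit."""
    if not 0 <= address <= 127:
        raise ValueError("address must fit 7 bits")
    cw = bch15_7_encode(address)
    bits = f"{cw:015b}" + str(_parity(cw, 15))
    return bits_to_bases(bits)


def encode_index3(address: int) -> str:
    """8-nt 3' index: parity | address | parity | address rotated left by 1."""
    if not 0 <= address <= 127:
        raise ValueError("address must fit 7 bits")
    p = _parity(address)
    bits = f"{p}{address:07b}{p}{_rotl7(address):07b}"
    return bits_to_bases(bits)


@lru_cache(maxsize=8)
def _index_tables(max_address: int = 127):
    idx5 = {a: encode_index5(a) for a in range(max_address + 1)}
    idx3 = {a: encode_index3(a) for a in range(max_address + 1)}
    return idx5, idx3


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


@dataclass(frozen=True)
class IndexReject:
    """A read whose index pair could not be trusted; ``reason`` explains why."""

    reason: str  # bad-length | bch-failure | parity | end-mismatch | distance


def decode_index_pair(obs5: str, obs3: str, max_sub: int = 1):
    """Recover a strand address from its two observed 8-nt indices.

    The 5' index is BCH-decoded (up to 2 bit corrections) and its parity bit
    checked; the reference indices of the candidate address are then compared
    to both observations, requiring at most ``max_sub`` substituted
    nucleotides per end.  Returns the address or an :class:`IndexReject`.
    """
    if len(obs5) != 8 or len(obs3) != 8:
        return IndexReject("bad-length")
    try:
        bits5 = bases_to_bits(obs5)
    except ValueError:
        return IndexReject("bad-length")
    dec = bch15_7_decode(int(bits5[:15], 2))
    if dec is None:
        return IndexReject("bch-failure")
    address, _ = dec
    # The nucleotide-distance checks against the reconstructed reference
    # indices subsume the parity bit: a wrong parity bit is a substitution in
    # the final nucleotide and counts toward the distance budget.
    idx5, idx3 = _index_tables()
    if _hamming(obs5, idx5[address]) > max_sub:
        return IndexReject("distance")
    if _hamming(obs3, idx3[address]) > max_sub:
        return IndexReject("end-mismatch")
    return address


@dataclass(frozen=True)
class DoubleEndIndexCodec:
    """Pluggable index codec interface used by framing and readout.

    The default is the small-pool 7-bit double-end construction (addresses
    1..126, 8 nt per end).  ``index_len_5p``/``index_len_3p`` are fixed at 8
    for this codec; pools needing longer or different index codes can provide
    another object with the same three methods.
    """

    max_sub: int = 1

    index_len_5p: int = 8
    index_len_3p: int = 8
    max_address: int = 127

    def encode(self, address: int) -> tuple[str, str]:
        return encode_index5(address), encode_index3(address)

    def decode(self, obs5: str, obs3: str):
        return decode_index_pair(obs5, obs3, self.max_sub)

    def reference_table(self) -> str:
        """CSV audit table: address, index5, index3."""
        lines = ["address,index5,index3"]
        for a in range(1, self.max_address):
            i5, i3 = self.encode(a)
            lines.append(f"{a},{i5},{i3}")
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Large-pool indices (generic, length-configurable)
# ---------------------------------------------------------------------------

@lru_cache(maxsize=4)
def _wide_end_table(index_len: int, address_bits: int) -> dict[str, int]:
    codec = WideIndexCodec(index_len, address_bits, max_sub=0)
    return {
        bits_to_bases(codec._end_bits(v)): v for v in range(codec.max_address + 1)
    }


def _crc8(value: int, width: int) -> int:
    """CRC-8 (poly 0x07) over the low ``width`` bits, MSB first."""
    reg = 0
    for i in range(width - 1, -1, -1):
        reg ^= ((value >> i) & 1) << 7
        reg = ((reg << 1) ^ 0x07) & 0xFF if reg & 0x80 else (reg << 1) & 0xFF
    return reg


@dataclass(frozen=True)
class WideIndexCodec:
    """Double-end index codec for pools larger than 126 strands.

    Layout per end (``2 * index_len`` bits): ``address | crc8(address) |
    even parity | zero pad``; the 3' end carries the address circularly
    left-shifted by one bit so the two ends are never interchangeable.  The
    CRC-8 (0x07) plus parity give the per-end code a minimum bit distance of
    4, so a single substituted nucleotide (at most 2 bit flips) is corrected
    by nearest-codeword search over the 3*index_len single-substitution
    candidates, rejecting ambiguous hits; both ends must then agree on the
    address.  This is a generic construction, not a reconstruction of any
    particular synthesized pool's index set.
    """

    index_len: int = 12
    address_bits: int = 15
    max_sub: int = 1  # per-end substituted-nucleotide budget (0 or 1)

    def __post_init__(self):
        if 2 * self.index_len < self.address_bits + 9:
            raise ValueError("index too short for address + CRC + parity")

    @property
    def index_len_5p(self) -> int:
        return self.index_len

    @property
    def index_len_3p(self) -> int:
        return self.index_len

    @property
    def max_address(self) -> int:
        return (1 << self.address_bits) - 1

    def _end_bits(self, value: int) -> str:
        w = self.address_bits
        body = f"{value:0{w}b}" + f"{_crc8(value, w):08b}"
        body += str(bin(int(body, 2)).count("1") & 1)
        return body + "0" * (2 * self.index_len - len(body))

    def _rotl(self, value: int) -> int:
        w = self.address_bits
        return ((value << 1) | (value >> (w - 1))) & ((1 << w) - 1)

    def encode(self, address: int) -> tuple[str, str]:
        if not 0 <= address <= self.max_address:
            raise ValueError("address out of range")
        return (
            bits_to_bases(self._end_bits(address)),
            bits_to_bases(self._end_bits(self._rotl(address))),
        )

    def _table(self) -> dict[str, int]:
        return _wide_end_table(self.index_len, self.address_bits)

    def _decode_end(self, obs: str):
        if len(obs) != self.index_len:
            return None
        table = self._table()
        hit = table.get(obs)
        if hit is not None or self.max_sub < 1:
            return hit
        matches = set()
        for pos in range(self.index_len):
            for b in "ATGC":
                if b == obs[pos]:
                    continue
                cand = table.get(obs[:pos] + b + obs[pos + 1 :])
                if cand is not None:
                    matches.add(cand)
        return matches.pop() if len(matches) == 1 else None

    def decode(self, obs5: str, obs3: str):
        a5 = self._decode_end(obs5)
        if a5 is None:
            return IndexReject("bch-failure")
        a3 = self._decode_end(obs3)
        if a3 is None or a3 != self._rotl(a5):
            return IndexReject("end-mismatch")
        return a5
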