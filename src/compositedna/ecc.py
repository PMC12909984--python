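"""Error-correcting codes: GF(2^m) Reed-Solomon, BCH(15,7), symbol interleaving.

The outer code protecting strand payloads is a (possibly shortened) systematic
Reed-Solomon code over GF(2^m) with m = 12 or 15, decoded with the classical
errors-and-erasures machinery: syndromes, Forney (erasure-modified) syndromes,
Berlekamp-Massey LFSR synthesis, Chien root search and the Forney magnitude
formula.  A codeword is recovered whenever ``2*errors + erasures <= n - k``.
Strand addresses are protected separately by a small binary BCH(15,7) code
(double-error-correcting, d = 5) decoded by syndrome table lookup.

Field arithmetic uses log/antilog tables held in numpy arrays so that the
inner loops of encoding and syndrome evaluation are vectorised; codes as large
as RS(32767, 27767) are practical in pure Python this way.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

__all__ = [
    "GF",
    "RSCode",
    "RSDecodeFailure",
    "Interleaver",
    "bch15_7_encode",
    "bch15_7_decode",
    "BCH15_7_GENERATOR",
]

# Primitive polynomials (as integers, MSB = highest power) for the field sizes
# used by the built-in presets; standard table entries.
PRIMITIVE_POLYS = {
    2: 0b111,
    3: 0b1011,
    4: 0b10011,          # x^4 + x + 1
    5: 0b100101,
    6: 0b1000011,        # x^6 + x + 1
    7: 0b10001001,
    8: 0b100011101,      # x^8 + x^4 + x^3 + x^2 + 1
    10: 0b10000001001,
    12: 0b1000001010011,  # x^12 + x^6 + x^4 + x + 1
    15: 0b1000000000000011,  # x^15 + x + 1
}


class GF:
    """GF(2^m) with numpy log/antilog tables (alpha = root of the primitive poly)."""

    def __init__(self, m: int, primitive_poly: int | None = None):
        if primitive_poly is None:
            try:
                primitive_poly = PRIMITIVE_POLYS[m]
            except KeyError:
                raise ValueError(f"no built-in primitive polynomial for m={m}")
        self.m = m
        self.primitive_poly = primitive_poly
        self.order = (1 << m) - 1  # multiplicative group order
        exp = np.zeros(2 * self.order, dtype=np.int64)
        log = np.zeros(1 << m, dtype=np.int64)
        x = 1
        for i in range(self.order):
            exp[i] = x
            log[x] = i
            x <<= 1
            if x & (1 << m):
                x ^= primitive_poly
            if x == 1 and i < self.order - 1:  # root order divides 2^m - 1
                raise ValueError(f"0x{primitive_poly:x} is not primitive for m={m}")
        if x != 1:
            raise ValueError(f"0x{primitive_poly:x} is not primitive for m={m}")
        exp[self.order:] = exp[: self.order]  # wraparound spares one mod
        self.exp = exp
        self.log = log

    # All operations accept scalars or numpy integer arrays and broadcast.
    def mul(self, a, b):
        a = np.asarray(a, dtype=np.int64)
        b = np.asarray(b, dtype=np.int64)
        out = self.exp[self.log[a] + self.log[b]]
        out = np.where((a == 0) | (b == 0), 0, out)
        return out if out.ndim else int(out)

    def inv(self, a):
        a = np.asarray(a, dtype=np.int64)
        if np.any(a == 0):
            raise ZeroDivisionError("inverse of 0 in GF(2^m)")
        out = self.exp[self.order - self.log[a]]
        return out if out.ndim else int(out)

    def div(self, a, b):
        return self.mul(a, self.inv(b))

    def pow_alpha(self, e):
        """alpha**e for integer exponent(s) e (any sign)."""
        e = np.asarray(e, dtype=np.int64) % self.order
        out = self.exp[e]
        return out if out.ndim else int(out)

    # -- polynomial helpers (coefficient arrays, lowest degree first) --------
    def poly_mul(self, p, q):
        p = np.asarray(p, dtype=np.int64)
        q = np.asarray(q, dtype=np.int64)
        if np.count_nonzero(q) < np.count_nonzero(p):
            p, q = q, p  # loop over the sparser operand
        out = np.zeros(len(p) + len(q) - 1, dtype=np.int64)
        for i in np.nonzero(p)[0]:
            out[i : i + len(q)] ^= self.mul(p[i], q)
        return out

    def poly_eval(self, p, x):
        """Evaluate poly (lowest-first coefficients) at point(s) x, vectorised."""
        p = np.asarray(p, dtype=np.int64)
        x = np.asarray(x, dtype=np.int64)
        logx = self.log[x]
        acc = np.zeros(x.shape, dtype=np.int64)
        for j in np.nonzero(p)[0]:
            term = self.exp[(self.log[p[j]] + j * logx) % self.order]
            acc ^= np.where(x == 0, p[j] if j == 0 else 0, term)
        return acc if acc.ndim else int(acc)


@lru_cache(maxsize=None)
def _field(m: int, primitive_poly: int | None = None) -> GF:
    return GF(m, primitive_poly)


@dataclass(frozen=True)
class RSDecodeFailure:
    """Returned when a codeword is beyond the errors-and-erasures bound."""

    reason: str
    n_erasures: int = 0


@dataclass
class RSCode:
    """Systematic (shortened) Reed-Solomon code over GF(2^m).

    Generator roots are alpha^1 .. alpha^(n-k) (narrow sense).  Codewords are
    ``[message | parity]`` with array index 0 holding the highest-degree
    coefficient; shortening to n < 2^m - 1 is implicit leading zeros.
    """

    n: int
    k: int
    m: int
    primitive_poly: int | None = None
    gf: GF = field(init=False, repr=False)
    _gen: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        if not (0 < self.k < self.n <= (1 << self.m) - 1):
            raise ValueError(f"invalid RS parameters n={self.n}, k={self.k}, m={self.m}")
        self.gf = _field(self.m, self.primitive_poly)
        gf = self.gf
        # g(x) = prod_{j=1..n-k} (x + alpha^j), built incrementally: multiplying
        # by (x + root) maps g -> shift(g) + root*g, one vector op per root.
        nsym = self.n - self.k
        g = np.zeros(nsym + 1, dtype=np.int64)  # lowest-first
        g[0] = 1
        for j in range(1, nsym + 1):
            root = gf.pow_alpha(j)
            scaled = gf.mul(root, g[: j + 1])
            g[1 : j + 1] = g[:j] ^ scaled[1 : j + 1]
            g[0] = scaled[0]
        self._gen = g  # degree n-k, monic

    @property
    def nsym(self) -> int:
        return self.n - self.k

    @property
    def min_distance(self) -> int:
        return self.n - self.k + 1

    @property
    def shortening(self) -> int:
        return (1 << self.m) - 1 - self.n

    # ------------------------------------------------------------------ encode
    def encode(self, message: np.ndarray) -> np.ndarray:
        """Systematic encode: parity = (message(x) * x^(n-k)) mod g(x)."""
        msg = np.asarray(message, dtype=np.int64)
        if msg.shape != (self.k,):
            raise ValueError(f"message must have length k={self.k}")
        if np.any((msg < 0) | (msg >= (1 << self.m))):
            raise ValueError("message symbols out of field range")
        gf = self.gf
        nsym = self.nsym
        # LFSR division; taps are g without its leading (monic) coefficient,
        # ordered from x^(n-k-1) down to x^0 to match the register layout.
        taps_log = gf.log[self._gen[:-1][::-1]]
        reg = np.zeros(nsym, dtype=np.int64)
        exp, log = gf.exp, gf.log
        for s in msg:
            fb = int(s) ^ int(reg[0])
            reg[:-1] = reg[1:]
            reg[-1] = 0
            if fb:
                reg ^= exp[taps_log + log[fb]]
        return np.concatenate([msg, reg])

    # ---------------------------------------------------------------- decode
    def syndromes(self, received: np.ndarray) -> np.ndarray:
        """S_j = r(alpha^j) for j = 1..n-k (all zero iff r is a codeword)."""
        gf = self.gf
        r = np.asarray(received, dtype=np.int64)
        nsym = self.nsym
        nz = np.nonzero(r)[0]
        if len(nz) == 0:
            return np.zeros(nsym, dtype=np.int64)
        j = np.arange(1, nsym + 1, dtype=np.int64)
        logr = gf.log[r[nz]]
        e = (self.n - 1 - nz).astype(np.int64)  # x-power of each position
        S = np.zeros(nsym, dtype=np.int64)
        chunk = max(1, 2_000_000 // nsym)
        for lo in range(0, len(nz), chunk):
            ee = e[lo : lo + chunk]
            ll = logr[lo : lo + chunk]
            expo = (np.outer(ee, j) + ll[:, None]) % gf.order
            S ^= np.bitwise_xor.reduce(gf.exp[expo], axis=0)
        return S

    def _berlekamp_massey(self, seq: np.ndarray) -> np.ndarray:
        """Massey LFSR synthesis over GF(2^m); returns Lambda, lowest-first."""
        gf = self.gf
        lam = np.array([1], dtype=np.int64)
        B = np.array([1], dtype=np.int64)
        L, shift, b = 0, 1, 1
        for nn in range(len(seq)):
            # discrepancy = seq[nn] + sum_{i=1..L} lam_i seq[nn-i]
            upto = min(L, nn, len(lam) - 1)
            d = int(seq[nn])
            if upto > 0:
                idx = np.arange(1, upto + 1)
                d ^= int(np.bitwise_xor.reduce(gf.mul(lam[idx], seq[nn - idx])))
            if d == 0:
                shift += 1
            elif 2 * L <= nn:
                old = lam.copy()
                coef = gf.div(d, b)
                term = np.zeros(shift + len(B), dtype=np.int64)
                term[shift:] = gf.mul(coef, B)
                size = max(len(lam), len(term))
                lam = np.pad(lam, (0, size - len(lam))) ^ np.pad(term, (0, size - len(term)))
                L = nn + 1 - L
                B = old
                b = d
                shift = 1
            else:
                coef = gf.div(d, b)
                term = np.zeros(shift + len(B), dtype=np.int64)
                term[shift:] = gf.mul(coef, B)
                size = max(len(lam), len(term))
                lam = np.pad(lam, (0, size - len(lam))) ^ np.pad(term, (0, size - len(term)))
                shift += 1
        return np.trim_zeros(lam, "b")

    def decode(
        self, received: np.ndarray, erasures: np.ndarray | list[int] | None = None
    ):
        """Errors-and-erasures decode.

        Parameters
        ----------
        received : array of n symbols; erased positions may hold any value
            (they are zeroed internally).
        erasures : array indices in [0, n) whose symbols are unreliable.

        Returns
        -------
        (message, n_errors, n_erasures) on success, else :class:`RSDecodeFailure`.
        """
        gf = self.gf
        r = np.asarray(received, dtype=np.int64).copy()
        if r.shape != (self.n,):
            raise ValueError(f"received word must have length n={self.n}")
        era = np.unique(np.asarray(erasures if erasures is not None else [], dtype=np.int64))
        if len(era) and (era.min() < 0 or era.max() >= self.n):
            raise ValueError("erasure positions out of range")
        nsym = self.nsym
        f = len(era)
        if f > nsym:
            return RSDecodeFailure("more erasures than parity symbols", f)
        r[era] = 0
        S = self.syndromes(r)
        if not np.any(S) and f == 0:
            return r[: self.k].copy(), 0, 0

        # Erasure locator Gamma(x) = prod (1 - X_l x), X_l = alpha^(n-1-pos).
        gamma = np.array([1], dtype=np.int64)
        X_era = gf.pow_alpha(self.n - 1 - era) if f else np.array([], dtype=np.int64)
        for X in X_era:
            gamma = gf.poly_mul(gamma, np.array([1, X], dtype=np.int64))

        # Forney syndromes T(x) = S(x)*Gamma(x) mod x^nsym; BM on T_{f+1..nsym}.
        T = gf.poly_mul(S, gamma)[:nsym]
        lam_err = self._berlekamp_massey(T[f:nsym])
        e_deg = len(lam_err) - 1
        if 2 * e_deg + f > nsym:
            return RSDecodeFailure("errata beyond correction bound", f)

        psi = gf.poly_mul(lam_err, gamma)  # errata locator
        # Chien search over the n valid positions: Psi(alpha^-(n-1-i)) == 0.
        epow = (self.n - 1 - np.arange(self.n, dtype=np.int64)) % gf.order
        vals = gf.poly_eval(psi, gf.pow_alpha(-epow.astype(np.int64)))
        roots = np.nonzero(vals == 0)[0]
        if len(roots) != len(psi) - 1:
            return RSDecodeFailure("errata locator degree/root mismatch", f)

        # Forney magnitudes: Omega = S*Psi mod x^nsym; e = Omega(X^-1)/Psi'(X^-1).
        omega = gf.poly_mul(S, psi)[:nsym]
        X = gf.pow_alpha(self.n - 1 - roots)
        Xinv = gf.inv(X)
        num = gf.poly_eval(omega, Xinv)
        dpsi = psi[1::2]  # formal derivative in char 2: odd coefficients
        dxpow = np.arange(len(dpsi)) * 2  # Psi'(x) = sum psi_{2j+1} x^{2j}
        den = np.zeros(len(roots), dtype=np.int64)
        for jj, c in zip(dxpow, dpsi):
            if c:
                den ^= gf.mul(c, gf.exp[(jj * gf.log[Xinv]) % gf.order])
        if np.any(den == 0):
            return RSDecodeFailure("Forney denominator zero", f)
        mags = gf.div(num, den)
        r[roots] ^= mags

        # Verify by updating syndromes with the applied errata (cheap check).
        j = np.arange(1, nsym + 1, dtype=np.int64)
        Scheck = S.copy()
        nzm = np.nonzero(mags)[0]
        if len(nzm):
            expo = (np.outer((self.n - 1 - roots[nzm]).astype(np.int64), j)
                    + gf.log[mags[nzm]][:, None]) % gf.order
            Scheck ^= np.bitwise_xor.reduce(gf.exp[expo], axis=0)
        if np.any(Scheck):
            return RSDecodeFailure("post-correction syndromes nonzero", f)
        n_err = int(np.sum(~np.isin(roots, era)))
        return r[: self.k].copy(), n_err, f


# ---------------------------------------------------------------------------
# Seeded random symbol interleaving
# ---------------------------------------------------------------------------

@dataclass
class Interleaver:
    """Seeded uniform permutation of the symbols of one codeword block.

    Spreads the burst of erasures caused by a lost strand across the whole
    codeword, so the errors-and-erasures budget is consumed evenly.
    """

    length: int
    seed: int
    permutation: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        rng = np.random.default_rng(self.seed)
        self.permutation = rng.permutation(self.length)

    def interleave(self, symbols: np.ndarray) -> np.ndarray:
        x = np.asarray(symbols)
        if len(x) != self.length:
            raise ValueError("length mismatch")
        return x[self.permutation]

    def deinterleave(self, symbols: np.ndarray) -> np.ndarray:
        x = np.asarray(symbols)
        if len(x) != self.length:
            raise ValueError("length mismatch")
        out = np.empty_like(x)
        out[self.permutation] = x
        return out

    def deinterleave_positions(self, positions: np.ndarray) -> np.ndarray:
        """Map interleaved-stream positions back to codeword positions."""
        return self.permutation[np.asarray(positions, dtype=np.int64)]


# ---------------------------------------------------------------------------
# BCH(15,7), t = 2, d = 5 — the strand-address code
# ---------------------------------------------------------------------------

#: Generator polynomial x^8 + x^7 + x^6 + x^4 + 1 (integer, MSB = x^8).
BCH15_7_GENERATOR = 0b111010001


def _gf2_mod(value: int, divisor: int) -> int:
    dlen = divisor.bit_length()
    while value.bit_length() >= dlen:
        value ^= divisor << (value.bit_length() - dlen)
    return value


def bch15_7_encode(message: int) -> int:
    """Encode a 7-bit message into a systematic 15-bit BCH codeword.

    The message occupies the 7 high bits of the codeword (coefficients of
    x^14..x^8); the 8 low bits are the remainder of m(x)*x^8 by g(x).
    """
    if not 0 <= message < 128:
        raise ValueError("message must be a 7-bit integer")
    shifted = message << 8
    return shifted | _gf2_mod(shifted, BCH15_7_GENERATOR)


@lru_cache(maxsize=1)
def _bch_syndrome_table() -> dict[int, int]:
    """remainder -> error pattern, for all weight <= 2 patterns (distinct by d=5)."""
    table: dict[int, int] = {}
    patterns = [0] + [1 << i for i in range(15)] + [
        (1 << i) | (1 << j) for i in range(15) for j in range(i)
    ]
    for e in patterns:
        table[_gf2_mod(e, BCH15_7_GENERATOR)] = e
    return table


def bch15_7_decode(word: int):
    """Decode a 15-bit word, correcting up to 2 bit errors.

    Returns ``(message, corrected_bits)`` or ``None`` beyond the radius.
    """
    if not 0 <= word < (1 << 15):
        raise ValueError("word must be a 15-bit integer")
    syn = _gf2_mod(word, BCH15_7_GENERATOR)
    err = _bch_syndrome_table().get(syn)
    if err is None:
        return None
    return (word ^ err) >> 8, bin(err).count("1")
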