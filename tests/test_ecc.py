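import itertools

import numpy as np
import pytest

from compositedna.ecc import (
    BCH15_7_GENERATOR,
    GF,
    Interleaver,
    RSCode,
    RSDecodeFailure,
    bch15_7_decode,
    bch15_7_encode,
)


@pytest.fixture(scope="module")
def rs15():
    return RSCode(15, 11, 4)


def corrupt(cw, positions, rng, field_max=16):
    r = cw.copy()
    for p in positions:
        r[p] ^= int(rng.integers(1, field_max))
    return r


class TestReedSolomon:
    def test_systematic_and_zero_codeword(self, rs15):
        assert not rs15.encode(np.zeros(11, dtype=np.int64)).any()
        msg = np.arange(11) % 16
        cw = rs15.encode(msg)
        assert np.array_equal(cw[:11], msg)
        assert not rs15.syndromes(cw).any()

    def test_round_trip_random_messages(self, rs15, rng):
        for _ in range(300):
            msg = rng.integers(0, 16, 11)
            out = rs15.decode(rs15.encode(msg))
            assert np.array_equal(out[0], msg) and out[1:] == (0, 0)

    def test_two_errors_exhaustive_positions(self, rs15, rng):
        msg = rng.integers(0, 16, 11)
        cw = rs15.encode(msg)
        for i, j in itertools.combinations(range(15), 2):
            out = rs15.decode(corrupt(cw, (i, j), rng))
            assert not isinstance(out, RSDecodeFailure)
            assert np.array_equal(out[0], msg)
            assert out[1] <= 2

    def test_full_erasure_budget(self, rs15, rng):
        # f = n-k erasures, e = 0: exact recovery (MDS property)
        for _ in range(100):
            msg = rng.integers(0, 16, 11)
            cw = rs15.encode(msg)
            era = rng.choice(15, 4, replace=False)
            r = cw.copy()
            r[era] = rng.integers(0, 16, 4)
            out = rs15.decode(r, era)
            assert np.array_equal(out[0], msg)

    def test_errors_and_erasures_bound(self, rs15, rng):
        # every (e, f) with 2e + f <= n - k = 4 must decode
        for e, f in [(0, 4), (1, 2), (1, 1), (2, 0), (1, 0), (0, 3)]:
            for _ in range(50):
                msg = rng.integers(0, 16, 11)
                cw = rs15.encode(msg)
                pos = rng.choice(15, e + f, replace=False)
                r = corrupt(cw, pos[:e], rng)
                r[pos[e:]] = rng.integers(0, 16, f)
                out = rs15.decode(r, pos[e:])
                assert not isinstance(out, RSDecodeFailure), (e, f)
                assert np.array_equal(out[0], msg), (e, f)

    def test_beyond_capability_flagged_or_miscorrected_to_codeword(self, rs15, rng):
        # 3 errors exceed t=2: either a failure value, or a decode to some
        # *other* valid codeword (standard bounded-distance behaviour)
        for _ in range(200):
            msg = rng.integers(0, 16, 11)
            cw = rs15.encode(msg)
            pos = rng.choice(15, 3, replace=False)
            out = rs15.decode(corrupt(cw, pos, rng))
            if not isinstance(out, RSDecodeFailure):
                re_encoded = rs15.encode(out[0])
                assert not rs15.syndromes(re_encoded).any()

    def test_too_many_erasures_is_failure_value(self, rs15):
        out = rs15.decode(np.zeros(15, dtype=np.int64), list(range(5)))
        assert isinstance(out, RSDecodeFailure)

    def test_shortened_equals_parent_with_leading_zeros(self, rng):
        short = RSCode(10, 6, 4)
        parent = RSCode(15, 11, 4)
        for _ in range(50):
            msg = rng.integers(0, 16, 6)
            cs = short.encode(msg)
            cp = parent.encode(np.concatenate([np.zeros(5, dtype=np.int64), msg]))
            assert np.array_equal(cs[-4:], cp[-4:])

    def test_midsize_randomized_trials(self, rng):
        rs = RSCode(255, 213, 8)
        msg = rng.integers(0, 256, 213)
        cw = rs.encode(msg)
        for _ in range(25):
            e = int(rng.integers(0, 22))
            f = int(rng.integers(0, 42 - 2 * e + 1))
            pos = rng.choice(255, e + f, replace=False)
            r = corrupt(cw, pos[:e], rng, 256)
            r[pos[e:]] = rng.integers(0, 256, f)
            out = rs.decode(r, pos[e:])
            assert np.array_equal(out[0], msg), (e, f)

    def test_shortened_production_code_spot_check(self, rng):
        rs = RSCode(1890, 1575, 12)
        msg = rng.integers(0, 4096, 1575)
        cw = rs.encode(msg)
        pos = rng.choice(1890, 200, replace=False)
        r = corrupt(cw, pos[:100], rng, 4096)
        r[pos[100:]] = 0
        out = rs.decode(r, pos[100:])
        assert np.array_equal(out[0], msg)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            RSCode(16, 11, 4)  # n > 2^m - 1
        with pytest.raises(ValueError):
            RSCode(15, 15, 4)


class TestGF:
    def test_field_axioms_sampled(self, rng):
        gf = GF(12)
        a = rng.integers(1, 1 << 12, 100)
        b = rng.integers(1, 1 << 12, 100)
        assert np.array_equal(gf.mul(a, b), gf.mul(b, a))
        assert np.array_equal(gf.mul(a, gf.inv(a)), np.ones(100, dtype=np.int64))
        assert np.array_equal(gf.div(gf.mul(a, b), b), a)

    def test_non_primitive_poly_rejected(self):
        with pytest.raises(ValueError):
            GF(4, 0b11111)  # x^4+x^3+x^2+x+1 has order 5, not primitive


class TestInterleaver:
    def test_inverse_identity_and_determinism(self, rng):
        il = Interleaver(500, seed=7)
        x = rng.integers(0, 100, 500)
        assert np.array_equal(il.deinterleave(il.interleave(x)), x)
        assert np.array_equal(il.permutation, Interleaver(500, seed=7).permutation)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            Interleaver(10, 0).interleave(np.arange(9))

    def test_burst_dispersal(self):
        # a burst of B consecutive positions should land far apart on average
        B, n = 40, 2000
        spreads = []
        for seed in range(100):
            il = Interleaver(n, seed)
            where = np.sort(il.deinterleave_positions(np.arange(B)))
            spreads.append(np.diff(where).mean())
        assert np.mean(spreads) > B / 2


def gf2_polydiv_remainder(value: int, divisor: int) -> int:
    """Independent long-division oracle over GF(2)."""
    dlen = divisor.bit_length()
    while value.bit_length() >= dlen:
        value ^= divisor << (value.bit_length() - dlen)
    return value


class TestBCH15_7:
    def test_zero_message(self):
        assert bch15_7_encode(0) == 0
        assert bch15_7_decode(0) == (0, 0)

    def test_systematic_against_long_division_oracle(self):
        for m in range(128):
            cw = bch15_7_encode(m)
            assert cw >> 8 == m
            assert cw & 0xFF == gf2_polydiv_remainder(m << 8, BCH15_7_GENERATOR)
            assert gf2_polydiv_remainder(cw, BCH15_7_GENERATOR) == 0

    def test_minimum_distance_is_five(self):
        cws = [bch15_7_encode(m) for m in range(128)]
        dmin = min(
            bin(a ^ b).count("1") for a, b in itertools.combinations(cws, 2)
        )
        assert dmin == 5

    def test_exhaustive_decode_within_radius_two(self):
        patterns = [1 << i for i in range(15)] + [
            (1 << i) | (1 << j) for i, j in itertools.combinations(range(15), 2)
        ]
        for m in range(128):
            cw = bch15_7_encode(m)
            assert bch15_7_decode(cw) == (m, 0)
            for e in patterns:
                out = bch15_7_decode(cw ^ e)
                assert out == (m, bin(e).count("1"))

    def test_weight_three_never_silently_returns_truth_unflagged(self):
        # beyond the radius: either failure or a decode to a different message
        rng = np.random.default_rng(0)
        for _ in range(300):
            m = int(rng.integers(128))
            cw = bch15_7_encode(m)
            pos = rng.choice(15, 3, replace=False)
            e = int(np.sum(1 << pos))
            out = bch15_7_decode(cw ^ e)
            # the corrupted word is at distance 3 from the truth, outside the
            # radius-2 ball, so a non-failure decode must land elsewhere
            assert out is None or out[0] != m
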