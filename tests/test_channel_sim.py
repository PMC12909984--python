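import math

import numpy as np
import pytest

from compositedna.channel_sim import (
    ChannelParams,
    fit_copy_distribution,
    inject_errors,
    instantiate_strand,
    sample_copy_counts,
    simulate_pool,
)
from compositedna.mapping import PRESETS, StrandFrame, build_frames
from compositedna.index_coding import DoubleEndIndexCodec


def make_frames(payloads):
    return build_frames("".join(payloads), PRESETS["8col"], DoubleEndIndexCodec())


class TestCopyCounts:
    def test_mean_matches_coverage(self):
        p = ChannelParams(coverage_mean=30, dispersion=4, seed=1)
        counts = sample_copy_counts(100_000, p)
        assert counts.mean() == pytest.approx(30, rel=0.01)

    def test_poisson_limit(self):
        p = ChannelParams(coverage_mean=30, dispersion=math.inf, seed=2)
        counts = sample_copy_counts(100_000, p)
        se = math.sqrt(2 * 30**2 / 100_000)  # rough SE of the variance
        assert abs(counts.var() - counts.mean()) < 3 * max(se, 0.5)

    def test_deterministic_under_seed(self):
        p = ChannelParams(seed=7)
        assert np.array_equal(sample_copy_counts(1000, p), sample_copy_counts(1000, p))

    def test_overdispersion(self):
        p = ChannelParams(coverage_mean=30, dispersion=4, seed=3)
        counts = sample_copy_counts(50_000, p)
        assert counts.var() > 2 * counts.mean()  # var = M + M^2/r = 255 >> 30

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            ChannelParams(coverage_mean=0)
        with pytest.raises(ValueError):
            ChannelParams(p_sub=0.6, p_del=0.5)


class TestCopyFit:
    def test_parameter_recovery_within_ten_percent(self):
        p = ChannelParams(coverage_mean=30, dispersion=4, seed=11)
        counts = sample_copy_counts(100_000, p)
        fit = fit_copy_distribution(counts)
        assert not fit.poisson_fallback
        assert fit.r == pytest.approx(4, rel=0.10)
        assert fit.mean == pytest.approx(counts.mean(), abs=1e-6)

    def test_poisson_fallback_flag(self):
        counts = np.random.default_rng(0).poisson(20, 50_000)
        fit = fit_copy_distribution(counts)
        # Poisson data: either the fallback flag, or a very large fitted shape
        assert fit.poisson_fallback or fit.r > 100

    def test_degenerate_input(self):
        fit = fit_copy_distribution(np.full(200, 30))
        assert fit.poisson_fallback

    def test_requires_enough_observations(self):
        with pytest.raises(ValueError):
            fit_copy_distribution(np.arange(50))


class TestInstantiate:
    def test_natural_payload_is_deterministic(self):
        frames = make_frames(["A" * 60, "T" * 60])
        out = instantiate_strand(frames[0], np.random.default_rng(0))
        assert out == frames[0].sequence

    def test_two_base_letter_frequency(self):
        frame = make_frames(["R" * 60])[0]
        rng = np.random.default_rng(5)
        n_a = 0
        total = 2000 * 60
        for _ in range(2000):
            seq = instantiate_strand(frame, rng)
            n_a += seq[20 + 8 : 20 + 8 + 60].count("A")
        # binomial CI: 120k draws at p=0.5
        assert n_a / total == pytest.approx(0.5, abs=0.005)

    def test_flanks_identical_across_copies(self):
        frame = make_frames(["N" * 60])[0]
        rng = np.random.default_rng(6)
        seqs = [instantiate_strand(frame, rng) for _ in range(5)]
        for s in seqs:
            assert s[:28] == frame.primer5 + frame.index5
            assert s[-28:] == frame.index3 + frame.primer3


class TestInjectErrors:
    def test_zero_rates_identity(self):
        p = ChannelParams(p_ins=0, p_del=0, p_sub=0)
        seq = "ACGTACGTAC" * 100
        out, events = inject_errors(seq, p, np.random.default_rng(0))
        assert out == seq and events == []

    def test_expected_event_count(self):
        # k * (P_ins + P_del + P_sub) = 1e4 * 0.004 = 40 events per read
        p = ChannelParams(p_ins=0.001, p_del=0.001, p_sub=0.002)
        rng = np.random.default_rng(1)
        seq = "".join(np.random.default_rng(2).choice(list("ATGC"), 10_000))
        n = 500
        total = sum(len(inject_errors(seq, p, rng)[1]) for _ in range(n))
        se = math.sqrt(40 / n)  # events ~ Binomial, variance ~ mean
        assert total / n == pytest.approx(40, abs=3 * se)

    def test_length_conservation(self):
        p = ChannelParams(p_ins=0.01, p_del=0.01, p_sub=0.01)
        rng = np.random.default_rng(3)
        seq = "ATGC" * 500
        for _ in range(50):
            out, events = inject_errors(seq, p, rng)
            ni = sum(1 for e in events if e[1] == "ins")
            nd = sum(1 for e in events if e[1] == "del")
            assert len(out) == len(seq) + ni - nd


class TestSimulatePool:
    def test_read_count_conservation(self):
        frames = make_frames(["R" * 60, "N" * 60, "A" * 60])
        pool = simulate_pool(frames, ChannelParams(coverage_mean=20, seed=4))
        assert len(pool.reads) == pool.copy_counts.sum()
        assert len(pool.addresses) == len(pool.reads)

    def test_noiseless_reads_match_composition(self):
        frames = make_frames(["A" * 60])
        p = ChannelParams(p_ins=0, p_del=0, p_sub=0, coverage_mean=50,
                          dispersion=math.inf, seed=5)
        pool = simulate_pool(frames, p)
        for r in pool.reads:
            assert r == frames[0].sequence

    def test_deterministic_under_seed(self):
        frames = make_frames(["H" * 60, "B" * 60])
        p = ChannelParams(coverage_mean=10, seed=9)
        a = simulate_pool(frames, p)
        b = simulate_pool(frames, p)
        assert a.reads == b.reads

    def test_breakage_leaves_single_primer(self):
        frames = make_frames(["N" * 60] * 10)
        p = ChannelParams(p_ins=0, p_del=0, p_sub=0, coverage_mean=100,
                          break_rate=0.14, seed=10)
        pool = simulate_pool(frames, p)
        p5, p3 = frames[0].primer5, frames[0].primer3
        single = sum(
            (p5 in r) != (p3 in r) for r in pool.reads
        )
        frac = single / len(pool.reads)
        se = math.sqrt(0.14 * 0.86 / len(pool.reads))
        assert frac == pytest.approx(0.14, abs=3 * se)
        # every broken read keeps exactly one intact primer
        broken_frac = pool.broken.mean()
        assert frac == pytest.approx(broken_frac, abs=1e-12)

    def test_paired_end_mode(self):
        frames = make_frames(["V" * 60])
        p = ChannelParams(coverage_mean=10, paired_end=True, seed=11)
        pool = simulate_pool(frames, p)
        for r1, r2 in pool.reads:
            assert len(r1) <= 150 and len(r2) <= 150

    def test_empty_frames_rejected(self):
        with pytest.raises(ValueError):
            simulate_pool([], ChannelParams())


class TestFrequencyConvergence:
    def test_pileup_converges_to_sigma_at_high_coverage(self):
        # KL(observed || sigma) -> 0 as coverage grows (no channel errors)
        frames = make_frames(["R" * 60])
        p = ChannelParams(p_ins=0, p_del=0, p_sub=0, coverage_mean=10_000,
                          dispersion=math.inf, seed=12)
        pool = simulate_pool(frames, p)
        counts = np.zeros(4)
        pos = 28  # first payload position
        for r in pool.reads:
            counts["ATGC".index(r[pos])] += 1
        p_hat = counts / counts.sum()
        sigma = np.array([0.5, 0, 0.5, 0])
        mask = sigma > 0
        kl = float((p_hat[mask] * np.log(p_hat[mask] / sigma[mask])).sum())
        assert 0 <= kl < 0.01
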