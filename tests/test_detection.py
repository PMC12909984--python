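import math

import numpy as np
import pytest

from compositedna.constellation import ALPHABET_1, ALPHABET_4, ENTROPY_LEVELS, letter_sigma
from compositedna.detection import (
    DECISION_LEVELS,
    Pileup,
    assign_subset,
    kl_detect,
    loglik,
    map_detect,
    pileup_frequencies,
    sp_detect,
)


def entropy_oracle(counts):
    p = np.asarray(counts, dtype=float)
    p = p / p.sum()
    return float(-(p[p > 0] * np.log2(p[p > 0])).sum())


class TestPileupFrequencies:
    def test_uniform_counts(self):
        prof = pileup_frequencies(np.array([[10, 10, 10, 10]]))
        assert np.allclose(prof.p, 0.25)
        assert prof.entropy[0] == pytest.approx(2.0)

    def test_pure_base(self):
        prof = pileup_frequencies(np.array([[20, 0, 0, 0]]))
        assert prof.entropy[0] == pytest.approx(0.0)

    def test_skewed_counts_against_direct_evaluation(self):
        counts = [6, 2, 1, 1]
        prof = pileup_frequencies(np.array([counts]))
        assert prof.entropy[0] == pytest.approx(entropy_oracle(counts), abs=1e-9)
        assert prof.entropy[0] == pytest.approx(1.5710, abs=5e-4)

    def test_zero_support_flagged_not_raised(self):
        prof = pileup_frequencies(np.array([[0, 0, 0, 0], [1, 0, 0, 0]]))
        assert prof.zero_support.tolist() == [True, False]
        assert np.isnan(prof.entropy[0])

    def test_pileup_validation(self):
        with pytest.raises(ValueError):
            Pileup(np.array([[1, 2, 3]]))
        with pytest.raises(ValueError):
            Pileup(np.array([[-1, 0, 0, 0]]))


class TestAssignSubset:
    @pytest.mark.parametrize("h,expected", [(0.0, 1), (1.99, 4), (0.4, 1), (0.6, 2)])
    def test_nearest_level(self, h, expected):
        assert assign_subset(h) == expected

    def test_tie_breaks_toward_lower_level(self):
        # exact midpoint of the working levels 1 and 1.5
        assert assign_subset(1.25) == 2
        assert assign_subset(0.5) == 1

    def test_exact_levels_available(self):
        mid = (1 + math.log2(3)) / 2
        assert assign_subset(mid, levels=ENTROPY_LEVELS) == 2
        assert assign_subset(mid + 1e-9, levels=ENTROPY_LEVELS) == 3

    def test_vectorised(self):
        out = assign_subset(np.array([0.0, 1.0, 1.5, 2.0]))
        assert out.tolist() == [1, 2, 3, 4]


class TestLoglik:
    def test_uniform_sigma(self):
        assert loglik([0.25] * 4, [5, 5, 5, 5]) == pytest.approx(20 * math.log(0.25))

    def test_smoothed_two_base_letter(self):
        sigma = letter_sigma("R", 1e-6)
        val = loglik(sigma, [2, 0, 2, 0])
        assert val == pytest.approx(4 * math.log(0.5 / (1 + 2e-6)), abs=1e-9)
        assert val == pytest.approx(-2.77259, abs=1e-4)

    def test_zero_sigma_rejected(self):
        with pytest.raises(ValueError):
            loglik([0.5, 0, 0.5, 0], [1, 1, 1, 1])

    def test_count_on_near_zero_component_penalises(self):
        sigma = letter_sigma("A", 1e-6)
        base = loglik(sigma, [10, 0, 0, 0])
        hit = loglik(sigma, [10, 1, 0, 0])
        assert hit - base == pytest.approx(math.log(sigma[1]), abs=1e-9)


class TestDetectors:
    def test_sp_two_stage_examples(self):
        det = sp_detect(np.array([[30, 0, 30, 0]]))
        assert det.symbols == "R" and det.subsets[0] == 2
        det = sp_detect(np.array([[12, 12, 12, 12]]))
        assert det.symbols == "N" and det.subsets[0] == 4
        det = sp_detect(np.array([[50, 1, 1, 0]]))  # h ~ 0.286 -> S1 -> A
        assert det.symbols == "A" and det.subsets[0] == 1

    def test_zero_support_is_erasure(self):
        det = sp_detect(np.array([[0, 0, 0, 0], [10, 0, 0, 0]]))
        assert det.symbols == "?A"
        assert det.erasures.tolist() == [True, False]

    @pytest.mark.parametrize("scale", [20, 60, 300])
    @pytest.mark.parametrize("detector", [sp_detect, map_detect, kl_detect])
    def test_exact_composition_recovers_every_letter(self, scale, detector):
        sig = ALPHABET_4.sigma_matrix()
        counts = np.round(sig * scale)
        det = detector(counts)
        assert det.symbols == "".join(ALPHABET_4.symbols)

    def test_map_equals_bruteforce_argmax(self, rng):
        counts = rng.integers(0, 40, size=(10_000, 4))
        counts = counts[counts.sum(axis=1) > 0]
        det = map_detect(counts)
        logsig = np.log(ALPHABET_4.sigma_matrix(1e-6))
        brute = np.argmax(counts @ logsig.T, axis=1)
        assert np.array_equal(det.letters, brute)

    def test_map_prior_flips_near_tied_call(self):
        # a single A read: 'A' wins under a uniform prior (ll ~ 0 vs ln 0.5
        # for 'M'), but a prior concentrated on 'M' overturns the ~0.69-nat gap
        counts = np.array([[1, 0, 0, 0]])
        assert map_detect(counts).symbols == "A"
        prior = np.full(15, 1e-9)
        prior[ALPHABET_4.index("M")] = 1.0
        assert map_detect(counts, prior=prior).symbols == "M"

    def test_kl_properties(self, rng):
        counts = rng.integers(0, 30, size=(2000, 4))
        counts = counts[counts.sum(axis=1) > 0]
        det = kl_detect(counts)
        assert (det.scores[~np.isnan(det.scores)] <= 1e-12).all()  # -KL <= 0
        # counts proportional to sigma -> KL ~ 0 and the true letter wins
        sig = ALPHABET_4.sigma_matrix()
        det2 = kl_detect(np.round(sig * 60))
        assert det2.symbols == "".join(ALPHABET_4.symbols)

    def test_kl_agrees_with_map_at_fixed_totals(self, rng):
        # with a shared pileup the entropy term is constant per position, so
        # argmin KL = argmax loglik up to smoothing wrinkles
        counts = rng.multinomial(60, [0.3, 0.3, 0.2, 0.2], size=10_000)
        km = kl_detect(counts)
        mp = map_detect(counts)
        agree = (km.letters == mp.letters).mean()
        assert agree > 0.99

    def test_sp_map_consistency_theorem(self, rng):
        # whenever stage 1 picks the subset of MAP's winner, SP == MAP
        counts = rng.integers(0, 50, size=(100_000, 4))
        counts = counts[counts.sum(axis=1) > 0]
        sp = sp_detect(counts)
        mp = map_detect(counts)
        subset_of = np.array([l.subset for l in ALPHABET_4.letters])
        agree_subset = subset_of[mp.letters] == sp.subsets
        assert np.array_equal(sp.letters[agree_subset], mp.letters[agree_subset])

    def test_sub_alphabet_fallback(self):
        # Alphabet 1 has no subset-3/4 letters: a clearly 3-base pileup must
        # fall back to full-alphabet MLE instead of failing
        det = sp_detect(np.array([[20, 20, 20, 0]]), alphabet=ALPHABET_1)
        assert det.fallback_positions == 1
        assert det.symbols in set(ALPHABET_1.symbols)

    def test_decision_levels_constant(self):
        assert DECISION_LEVELS == (0.0, 1.0, 1.5, 2.0)


def test_calls_table_export():
    from compositedna.detection import calls_table

    counts = np.array([[30, 0, 30, 0], [0, 0, 0, 0]])
    det = sp_detect(counts)
    table = calls_table(counts, det, address=5)
    lines = table.strip().splitlines()
    assert lines[0].split("\t") == [
        "address", "position", "A", "T", "G", "C", "entropy", "subset", "call", "score",
    ]
    row = lines[1].split("\t")
    assert row[:7] == ["5", "0", "30", "0", "30", "0", "1.0000"]
    assert row[8] == "R"
    assert lines[2].split("\t")[8] == "?"  # zero support -> erasure
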