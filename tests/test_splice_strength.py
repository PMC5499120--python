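import math

import numpy as np
import pytest
from scipy.stats import spearmanr

from polyasym.genome_io import GeneModel, sense_sequence
from polyasym.splice_strength import (FIVE_PRIME_LEN, SpliceWindow,
                                      extract_site_windows, fit_maxent,
                                      load_model_text, log2_model_probability,
                                      save_model_text, score_window,
                                      strength_quartiles)
from polyasym.synthetic_data import (FIVE_EXONIC_CONSENSUS,
                                     FIVE_INTRONIC_CONSENSUS, _sample_consensus)


def _genome(n=2000, seed=5):
    rng = np.random.default_rng(seed)
    return {"c1": "".join(rng.choice(list("ACGT"), n))}


def _random_windows(n, L, rng, probs=None):
    out = []
    for _ in range(n):
        if probs is None:
            out.append("".join(rng.choice(list("ACGT"), L)))
        else:
            out.append("".join(rng.choice(list("ACGT"), L, p=probs)))
    return out


class TestExtractWindows:
    def test_plus_strand_coordinates(self):
        g = _genome()
        m = GeneModel("g", "g.t1", "c1", "+", ((1, 100), (201, 260), (401, 500)))
        wins = extract_site_windows(m, g)
        five = [w for w in wins if w.site_type == "five_prime"]
        three = [w for w in wins if w.site_type == "three_prime"]
        # first intron is 101-200: donor window spans genomic 98-106
        assert five[0].seq == g["c1"][97:106]
        assert three[0].seq == g["c1"][180:203]
        assert len(five) == 2 and len(three) == 2

    def test_minus_strand_windows_are_revcomp_side(self):
        g = _genome()
        m = GeneModel("g", "g.t1", "c1", "-", ((231, 300), (101, 200)))
        wins = extract_site_windows(m, g)  # intron genomic 201-230
        five = next(w for w in wins if w.site_type == "five_prime")
        three = next(w for w in wins if w.site_type == "three_prime")
        assert five.seq == sense_sequence(g["c1"], 225, 233, "-")
        assert three.seq == sense_sequence(g["c1"], 198, 220, "-")

    def test_short_intron_skipped(self):
        g = _genome()
        m = GeneModel("g", "g.t1", "c1", "+", ((1, 100), (106, 200)))
        assert extract_site_windows(m, g) == []  # 5-nt intron fits no window


class TestFitMaxent:
    def test_too_few_windows_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            fit_maxent(_random_windows(10, 9, rng), order=1,
                       canonical_filter=False)

    def test_bad_order_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            fit_maxent(_random_windows(200, 9, rng), order=3,
                       canonical_filter=False)

    def test_order1_equals_positional_product(self):
        """Order-1 max-ent is exactly the positional-frequency product model."""
        rng = np.random.default_rng(1)
        wins = _random_windows(500, 9, rng, probs=[.4, .1, .2, .3])
        m = fit_maxent(wins, order=1, pseudocount=0.0, canonical_filter=False)
        # independent frequency computation
        freq = np.zeros((9, 4))
        for w in wins:
            for i, c in enumerate(w):
                freq[i, "ACGT".index(c)] += 1
        freq /= len(wins)
        for w in wins[:50]:
            expected = sum(math.log2(freq[i, "ACGT".index(c)])
                           for i, c in enumerate(w))
            assert log2_model_probability(m, w) == pytest.approx(expected, abs=1e-12)

    def test_single_window_uniform_background_scores_18_bits(self):
        wins = ["CAGGTAAGT"] * 100
        m = fit_maxent(wins, order=1, pseudocount=0.0,
                       background=np.full(4, 0.25))
        assert score_window(m, "CAGGTAAGT").score == 18.0

    def test_duplicating_training_set_is_idempotent(self):
        rng = np.random.default_rng(2)
        wins = _random_windows(300, 9, rng)
        m1 = fit_maxent(wins, order=1, pseudocount=0.0, canonical_filter=False)
        m2 = fit_maxent(wins * 2, order=1, pseudocount=0.0, canonical_filter=False)
        for w in wins[:20]:
            assert score_window(m1, w).score == pytest.approx(
                score_window(m2, w).score, abs=1e-12)

    def test_order2_satisfies_pairwise_constraints(self):
        """IPF on a planted pairwise-coupled model matches every dinucleotide
        marginal and yields a normalized distribution."""
        rng = np.random.default_rng(3)
        wins = []
        for _ in range(2000):
            c0 = rng.integers(0, 4)
            c1 = c0 if rng.random() < 0.6 else rng.integers(0, 4)
            rest = rng.choice(4, 7, p=[.4, .1, .2, .3])
            wins.append("".join("ACGT"[c] for c in [c0, c1, *rest]))
        m = fit_maxent(wins, order=2, tolerance=1e-7, max_iterations=400,
                       canonical_filter=False)
        assert m.diagnostics.converged
        assert m.diagnostics.max_violation < 1e-7
        assert abs(m.log2_z) < 1e-6  # distribution sums to 1
        # independent reconstruction of the joint table from returned factors
        table = np.ones((4,) * 9)
        for i in range(9):
            shape = [1] * 9
            shape[i] = 4
            table = table * m.positional[i].reshape(shape)
        for (i, j), f in m.pair_factors.items():
            shape = [1] * 9
            shape[i] = 4
            shape[j] = 4
            table = table * f.reshape(shape)
        # empirical smoothed pairwise marginal, computed by the test itself
        for (i, j) in [(0, 1), (2, 7), (4, 5)]:
            emp = np.full((4, 4), 0.5)
            for w in wins:
                emp["ACGT".index(w[i]), "ACGT".index(w[j])] += 1
            emp /= emp.sum()
            got = table.sum(axis=tuple(k for k in range(9) if k not in (i, j)))
            assert np.abs(got - emp).max() < 1e-6

    def test_order2_acceptor_23mer_blocked_fit(self):
        rng = np.random.default_rng(4)
        wins = []
        for _ in range(400):
            s = rng.uniform(0.2, 0.9)
            w = _sample_consensus("T" * 17 + "CAG", s, rng, forced={18: "A", 19: "G"})
            wins.append(w + _sample_consensus("GTC", s, rng))
        m = fit_maxent(wins, order=2, site_type="three_prime")
        assert m.length == 23 and m.blocks
        assert m.diagnostics.converged
        assert m.diagnostics.max_violation < 1e-4
        assert m.log2_z == 0.0  # chained conditionals are exactly normalized
        scores = [score_window(m, w).score for w in wins[:50]]
        assert all(math.isfinite(s) for s in scores)

    def test_blocked_model_exactly_normalized(self):
        """The chained block model sums to 1 over the full window space
        (checked exhaustively on an 11-mer)."""
        rng = np.random.default_rng(10)
        wins = []
        for _ in range(300):
            s = rng.uniform(0, 1)
            wins.append(_sample_consensus("ACGTACGTACG", s, rng))
        m = fit_maxent(wins, order=2, canonical_filter=False)
        assert m.blocks and len(m.blocks) == 2
        L = 11
        logp = np.zeros((4,) * L)
        for blk in m.blocks:
            shape = [1] * L
            for k in range(blk.length):
                shape[blk.start + k] = 4
            logp = logp + blk.log2_table.reshape(shape)
            if blk.overlap:
                oshape = [1] * L
                for k in range(blk.overlap):
                    oshape[blk.start + k] = 4
                logp = logp - blk.log2_overlap.reshape(oshape)
        total = np.exp2(logp).sum()
        assert total == pytest.approx(1.0, abs=1e-9)
        # a constrained within-block pair marginal matches the smoothed
        # empirical marginal
        emp = np.full((4, 4), 0.5)
        for w in wins:
            emp["ACGT".index(w[2]), "ACGT".index(w[6])] += 1
        emp /= emp.sum()
        got = np.exp2(logp).sum(axis=tuple(k for k in range(L) if k not in (2, 6)))
        assert np.abs(got - emp).max() < 1e-4

    def test_canonical_filter_drops_noncanonical(self):
        rng = np.random.default_rng(5)
        good = ["CAGGTAAGT"] * 150
        bad = ["CAGCCAAGT"] * 50  # no GT
        m = fit_maxent(good + bad, order=1, pseudocount=0.0)
        assert m.positional[3, "ACGT".index("G")] == 1.0

    def test_monotonicity_toward_consensus(self):
        """Replacing a letter with the positional mode never lowers the
        order-1 score against a uniform background."""
        rng = np.random.default_rng(6)
        wins = _random_windows(500, 9, rng, probs=[.4, .3, .2, .1])
        m = fit_maxent(wins, order=1, background=np.full(4, 0.25),
                       canonical_filter=False)
        consensus = "".join("ACGT"[i] for i in m.positional.argmax(axis=1))
        for w in wins[:50]:
            base = score_window(m, w).score
            for i in range(9):
                better = w[:i] + consensus[i] + w[i + 1:]
                assert score_window(m, better).score >= base - 1e-12

    def test_nonacgt_window_unscorable(self):
        rng = np.random.default_rng(7)
        m = fit_maxent(_random_windows(200, 9, rng), order=1,
                       canonical_filter=False)
        sc = score_window(m, "CAGGTANGT")
        assert sc.unscorable and math.isnan(sc.score)


class TestQuartiles:
    def test_octet_example(self):
        labels, degenerate = strength_quartiles([1, 2, 3, 4, 5, 6, 7, 8])
        assert not degenerate
        assert labels[:2] == ["low", "low"]
        assert labels[-2:] == ["high", "high"]
        assert set(labels[2:6]) == {"mid"}

    def test_degenerate_all_equal(self):
        labels, degenerate = strength_quartiles([5.0] * 10)
        assert degenerate and set(labels) == {"mid"}

    def test_too_few_rejected(self):
        with pytest.raises(ValueError):
            strength_quartiles([1, 2, 3])

    def test_latent_strength_recovery(self):
        """Scores of windows sampled at latent strength s rank with s."""
        rng = np.random.default_rng(8)
        s = rng.uniform(0, 1, 2000)
        wins = [_sample_consensus(FIVE_EXONIC_CONSENSUS, si, rng)
                + _sample_consensus(FIVE_INTRONIC_CONSENSUS, si, rng,
                                    forced={0: "G", 1: "T"})
                for si in s]
        m = fit_maxent(wins, order=1, site_type="five_prime")
        scores = [score_window(m, w).score for w in wins]
        rho = spearmanr(s, scores).statistic
        assert rho > 0.7
        labels, _ = strength_quartiles(scores)
        low_mean = np.mean([si for si, l in zip(s, labels) if l == "low"])
        high_mean = np.mean([si for si, l in zip(s, labels) if l == "high"])
        assert high_mean > low_mean + 0.3


class TestSerialization:
    def test_roundtrip_preserves_scores(self):
        rng = np.random.default_rng(9)
        wins = _random_windows(300, 9, rng)
        m = fit_maxent(wins, order=2, tolerance=1e-5, canonical_filter=False)
        back = load_model_text(save_model_text(m))
        for w in wins[:20]:
            assert score_window(back, w).score == pytest.approx(
                score_window(m, w).score, abs=1e-9)

    def test_blocked_roundtrip_preserves_scores(self):
        rng = np.random.default_rng(10)
        wins = []
        for _ in range(200):
            s = rng.uniform(0.2, 0.9)
            w = _sample_consensus("T" * 17 + "CAG", s, rng, forced={18: "A", 19: "G"})
            wins.append(w + _sample_consensus("GTC", s, rng))
        m = fit_maxent(wins, order=2, site_type="three_prime")
        back = load_model_text(save_model_text(m))
        for w in wins[:20]:
            assert score_window(back, w).score == pytest.approx(
                score_window(m, w).score, abs=1e-9)
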