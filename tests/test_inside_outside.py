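"""Inside/outside charts, pair probabilities, and entropy."""

import math
import time

import numpy as np
import pytest

from triple_entropy import (
    PairProbabilityMatrix,
    RnaSequence,
    entropy_of_sequence,
    inside,
    outside,
    pair_probabilities,
    shannon_entropy,
)
from triple_entropy.enumeration import enumerate_derivations, oracle_pair_probabilities
from triple_entropy.inside_outside import ChartMismatchError


class TestInside:
    def test_single_base(self, params, em):
        chart = inside(RnaSequence("a", "A"), params, em)
        assert chart.total_probability() == pytest.approx(params.p1 * 0.25, rel=1e-12)

    def test_unpaired_chain_aaaa(self, params, em):
        # only one derivation: rule 2 three times then rule 1
        chart = inside(RnaSequence("a4", "AAAA"), params, em)
        expected = (params.p2 * 0.25) ** 3 * (params.p1 * 0.25)
        assert chart.total_probability() == pytest.approx(expected, rel=1e-12)

    def test_short_sequences_have_no_pair_terms(self, params, em):
        # below span 7 no derivation can contain a pair, so the total inside
        # probability is exactly the unpaired-chain product
        x = RnaSequence("s", "GGGCCC")  # plenty of complementarity, n = 6
        chart = inside(x, params, em)
        expected = math.prod(
            params.p2 * em.u(b) for b in x.residues[:-1]
        ) * params.p1 * em.u(x.residues[-1])
        assert chart.total_probability() == pytest.approx(expected, rel=1e-12)

    def test_total_probability_matches_enumeration(self, params, em, oracle_panel):
        for x in oracle_panel[:40]:
            total = sum(
                s.probability for s in enumerate_derivations(x, params, em)
            )
            chart = inside(x, params, em)
            assert chart.total_probability() == pytest.approx(total, rel=1e-12)


class TestOutside:
    def test_full_span_context_is_one(self, params, em):
        x = RnaSequence("s", "GGGAAACCCC")
        out = outside(inside(x, params, em))
        assert out.beta("X", 1, x.n) == 1.0

    def test_aaaa_suffix_context(self, params, em):
        out = outside(inside(RnaSequence("a4", "AAAA"), params, em))
        assert out.beta("X", 2, 4) == pytest.approx(params.p2 * 0.25, rel=1e-12)

    def test_alpha_beta_products_match_enumeration(self, params, em, oracle_panel):
        """α(S,i,j)·β(S,i,j) equals the summed probability of derivations
        in which S spans (i, j), from exhaustive enumeration."""
        for x in oracle_panel[:10]:
            chart = inside(x, params, em)
            out = outside(chart)
            lhs = {1: "X", 2: "X", 3: "X", 4: "X", 5: "H", 6: "H", 7: "Y"}
            spans = {}
            for s in enumerate_derivations(x, params, em):
                for key in {(lhs[r], sp) for r, sp in s.derivation}:
                    spans[key] = spans.get(key, 0.0) + s.probability
            for (sym, (i, j)), total in spans.items():
                got = chart.alpha(sym, i, j) * out.beta(sym, i, j)
                assert got == pytest.approx(total, rel=1e-9), (sym, i, j)

    def test_chart_mismatch_rejected(self, params, em):
        a = inside(RnaSequence("a", "GGGAAACCCC"), params, em)
        b = outside(inside(RnaSequence("b", "GGGAAAACCC"), params, em))
        with pytest.raises(ChartMismatchError):
            pair_probabilities(a, b)


class TestPairProbabilities:
    def test_matches_oracle_on_example(self, params, em):
        x = RnaSequence("ex", "GGGAAACCCC")
        got = pair_probabilities(inside(x, params, em))
        want = oracle_pair_probabilities(x, params, em)
        np.testing.assert_allclose(got.matrix, want.matrix, rtol=1e-9, atol=1e-15)

    def test_short_or_pairless_sequences_all_zero(self, params, em):
        for seq in ("ACGUAC", "AAAAAAAAAA", "CCCCCCCCC"):
            P = pair_probabilities(inside(RnaSequence("s", seq), params, em))
            assert np.all(P.matrix == 0.0)

    def test_row_sums_bounded(self, params, em, oracle_panel):
        for x in oracle_panel[:30]:
            P = pair_probabilities(inside(x, params, em))
            assert np.all(P.matrix >= 0.0)
            assert np.all(P.matrix <= 1.0 + 1e-9)
            assert np.all(P.row_sums() <= 1.0 + 1e-9)

    def test_scaled_and_linear_space_agree(self, params, em):
        rng = np.random.default_rng(77)
        for n in (20, 40, 60):
            x = RnaSequence("s", "".join(rng.choice(list("ACGU"), size=n)))
            p_scaled = pair_probabilities(inside(x, params, em, scale=0.125))
            p_linear = pair_probabilities(inside(x, params, em, scale=1.0))
            np.testing.assert_allclose(
                p_scaled.matrix, p_linear.matrix, rtol=1e-9, atol=1e-15
            )

    def test_long_sequence_stays_finite(self, params, em):
        rng = np.random.default_rng(8)
        x = RnaSequence("long", "".join(rng.choice(list("ACGU"), size=400)))
        P = pair_probabilities(inside(x, params, em))
        assert np.all(np.isfinite(P.matrix))
        assert np.all(P.row_sums() <= 1.0 + 1e-9)

    def test_cubic_runtime_scaling(self, params, em):
        """Doubling n multiplies runtime by roughly 8 (O(n^3)); generous
        bounds guard against quadratic or exponential behaviour."""
        rng = np.random.default_rng(9)

        def timed(n):
            x = RnaSequence("t", "".join(rng.choice(list("ACGU"), size=n)))
            t0 = time.perf_counter()
            pair_probabilities(inside(x, params, em))
            return time.perf_counter() - t0

        timed(100)  # warm-up
        t200 = min(timed(200) for _ in range(2))
        t400 = min(timed(400) for _ in range(2))
        assert 2.5 < t400 / t200 < 20.0


class TestEntropy:
    def test_zero_matrix_zero_entropy(self):
        P = PairProbabilityMatrix("z", np.zeros((8, 8)))
        assert shannon_entropy(P).Q == 0.0

    def test_certain_pair_zero_entropy(self):
        m = np.zeros((8, 8))
        m[0, 7] = 1.0
        assert shannon_entropy(PairProbabilityMatrix("c", m)).Q == 0.0

    def test_half_probability_entry(self):
        m = np.zeros((10, 10))
        m[0, 9] = 0.5
        q = shannon_entropy(PairProbabilityMatrix("h", m)).Q
        assert q == pytest.approx(-(0.5 * math.log(0.5)) / 10, rel=1e-12)
        assert q == pytest.approx(0.034657, abs=1e-6)

    def test_log_base_rescales_entropy(self, params, em):
        x = RnaSequence("s", "GGGGAAAACCCCC")
        chart = inside(x, params, em)
        P = pair_probabilities(chart)
        q_e = shannon_entropy(P).Q
        q_2 = shannon_entropy(P, log_base=2.0).Q
        assert q_2 == pytest.approx(q_e / math.log(2.0), rel=1e-12)

    def test_convenience_wrapper_consistent(self, params, em):
        x = RnaSequence("s", "GGGGAAAACCCCC")
        direct = shannon_entropy(pair_probabilities(inside(x, params, em)))
        assert entropy_of_sequence(x, params, em) == direct
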