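"""Emission model, q_bp, the maximum-entropy rule-probability solve, and
forward sampling from the grammar."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from triple_entropy import (
    EmissionModel,
    GrammarParams,
    compute_qbp,
    sample_structure,
    solve_rule_probabilities,
)
from triple_entropy.grammar import InvalidEmissionError
from triple_entropy.sequences import CANONICAL_PAIRS


def pair_distribution(weights):
    pairs = sorted(CANONICAL_PAIRS)
    total = sum(weights)
    return {p: w / total for p, w in zip(pairs, weights)}


class TestQbp:
    def test_default_value(self, em):
        # sixth root of 0.25^2 * 0.17^2 * 0.08^2
        assert compute_qbp(em) == pytest.approx(0.15037, abs=1e-4)

    def test_equal_pair_probabilities_give_that_probability(self):
        em = EmissionModel(paired=pair_distribution([1] * 6))
        assert compute_qbp(em) == pytest.approx(1 / 6, rel=1e-12)

    def test_zero_pair_probability_rejected(self):
        em = EmissionModel(paired=pair_distribution([0, 1, 1, 1, 1, 1]))
        with pytest.raises(InvalidEmissionError):
            compute_qbp(em)

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0.01, 10.0), min_size=6, max_size=6))
    def test_qbp_is_geometric_mean(self, weights):
        em = EmissionModel(paired=pair_distribution(weights))
        expected = math.exp(
            sum(math.log(p) for p in em.paired.values()) / 6.0
        )
        assert compute_qbp(em) == pytest.approx(expected, rel=1e-12)


class TestSolveRuleProbabilities:
    def test_default_matches_printed_values(self, params):
        assert round(params.p1, 3) == 0.499
        assert round(params.p2, 3) == 0.499
        assert round(params.p3, 3) == 0.001
        assert round(params.p4, 3) == 0.001
        assert round(params.p5, 3) == 0.103
        assert round(params.p6, 3) == 0.897
        assert params.p7 == 1.0

    def test_constraint_residuals(self, params, em):
        u = 0.25
        q = params.qbp
        r1 = q**3 * params.p3 * params.p6 * params.p7 - (u * params.p1) ** 6
        r2 = (
            q**4 * params.p3 * params.p5 * params.p6 * params.p7
            - (u * params.p1) ** 8
        )
        assert abs(r1) < 1e-9
        assert abs(r2) < 1e-9
        assert params.p1 + params.p2 + params.p3 + params.p4 == pytest.approx(1.0)
        assert params.p5 + params.p6 == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "weights", [[1, 1, 1, 1, 1, 1], [25, 25, 17, 17, 8, 8], [40, 40, 9, 9, 1, 1]]
    )
    def test_against_bisection_oracle(self, weights):
        """The fixed point agrees with an independent root-find on the
        scalar equation p1 = 1/2 - p3(p1)."""
        em = EmissionModel(paired=pair_distribution(weights))
        qbp = compute_qbp(em)
        u = 0.25

        def p3_of(p1):
            p5 = (u * p1) ** 2 / qbp
            return (u * p1) ** 6 / (qbp**3 * (1 - p5))

        root = brentq(lambda p1: p1 - (0.5 - p3_of(p1)), 1e-9, 0.5, xtol=1e-14)
        params = solve_rule_probabilities(em)
        assert params.p1 == pytest.approx(root, abs=1e-10)

    def test_symmetry_forced_by_constraints(self):
        em = EmissionModel(paired=pair_distribution([3, 1, 2, 2, 1, 3]))
        p = solve_rule_probabilities(em)
        assert p.p1 == p.p2
        assert p.p3 == p.p4
        assert p.p7 == 1.0

    def test_invariant_violations_rejected(self):
        with pytest.raises(ValueError):
            GrammarParams(p1=0.6, p2=0.6, p3=0.0, p4=0.0, p5=0.1, p6=0.9, p7=1.0, qbp=0.15)
        with pytest.raises(ValueError):
            GrammarParams(p1=0.5, p2=0.5, p3=0.0, p4=0.0, p5=0.1, p6=0.9, p7=0.5, qbp=0.15)


class TestSampleStructure:
    def test_deterministic_given_seed(self, params, em):
        a = sample_structure(params, em, max_length=50, rng_seed=11)
        b = sample_structure(params, em, max_length=50, rng_seed=11)
        assert a[0].residues == b[0].residues
        assert a[1] == b[1]

    def test_stems_have_at_least_three_pairs_and_canonical(self, em):
        # structure-rich parameters so pairs actually occur in the samples
        from triple_entropy.enumeration import STRUCTURED_SAMPLING_PARAMS

        sp = STRUCTURED_SAMPLING_PARAMS()
        rng = np.random.default_rng(3)
        seen_pairs = 0
        for _ in range(1000):
            seq, struct = sample_structure(sp, em, max_length=80, rng=rng)
            for run in struct.stems():
                assert len(run) >= 3
            for i, j in struct.pairs:
                assert seq.can_pair(i, j)
                seen_pairs += 1
        assert seen_pairs > 0

    def test_rule_choice_frequencies_match_probabilities(self, params, em):
        """At X-expansions, rule 1 vs rule 2 empirical frequencies match
        p1 : p2 within 3 standard errors (multinomial check)."""
        rng = np.random.default_rng(1)
        counts = {1: 0, 2: 0, 3: 0, 4: 0}
        for _ in range(10_000):
            _, struct = sample_structure(params, em, max_length=400, rng=rng)
            for rule, _span in struct.derivation:
                if rule <= 4:
                    counts[rule] += 1
        total = sum(counts.values())
        for rule, p in [(1, params.p1), (2, params.p2)]:
            se = math.sqrt(p * (1 - p) * total)
            assert abs(counts[rule] - p * total) < 3 * se

    def test_derivation_probability_is_product_of_factors(self, params, em):
        seq, struct = sample_structure(params, em, max_length=30, rng_seed=5)
        paired = {i for p in struct.pairs for i in p}
        logp = 0.0
        for rule, _span in struct.derivation:
            logp += math.log(params.rule(rule))
        for pos in range(1, seq.n + 1):
            if pos not in paired:
                logp += math.log(em.u(seq.base(pos)))
        for i, j in struct.pairs:
            logp += math.log(em.pi(seq.base(i), seq.base(j)))
        assert struct.probability == pytest.approx(math.exp(logp), rel=1e-9)
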