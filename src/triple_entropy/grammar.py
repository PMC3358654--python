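"""The stem-constrained stochastic context-free grammar.

The structure model is a three-nonterminal SCFG over {X, H, Y} with X the
start symbol and seven production rules::

    (1) X -> a        (2) X -> aX       (3) X -> aHb
    (4) X -> aHbX     (5) H -> aHb      (6) H -> aYb
    (7) Y -> aXb

Lower-case letters are emitted nucleotides; in rules (3)-(7) the flanking
``a``/``b`` form a base pair.  Opening a stem must pass through X -> aHb
(or aHbX), then H, then Y, so every stem carries at least three directly
nested pairs; non-canonical pairs have emission probability zero and can
never occur.  The minimum span of a pair-carrying X expansion is 7
nucleotides (Y spans >= 3, H spans >= 5).

Rule probabilities are not trained from data.  They are derived from the
emission model by a maximum-entropy argument: the probability contribution
of a base pair should match the contribution of unpaired bases, which
yields a small nonlinear system solved here by a fixed-point iteration.
"""

from __future__ import annotations

import math
import sys
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .sequences import CANONICAL_PAIRS, ALPHABET, RnaSequence
from .structure import RuleApplication, SecondaryStructure

__all__ = [
    "EmissionModel",
    "GrammarParams",
    "Grammar",
    "GRAMMAR",
    "compute_qbp",
    "solve_rule_probabilities",
    "sample_structure",
    "InvalidEmissionError",
    "SolverError",
    "SampleError",
]

#: Default paired-base distribution over the six canonical ordered pairs.
DEFAULT_PAIRED: Dict[Tuple[str, str], float] = {
    ("G", "C"): 0.25,
    ("C", "G"): 0.25,
    ("A", "U"): 0.17,
    ("U", "A"): 0.17,
    ("G", "U"): 0.08,
    ("U", "G"): 0.08,
}

DEFAULT_UNPAIRED: Dict[str, float] = {b: 0.25 for b in ALPHABET}


class InvalidEmissionError(ValueError):
    """Emission model violates its probability-distribution invariants."""


class SolverError(RuntimeError):
    """Rule-probability solve failed to converge or left (0, 1)."""


class SampleError(RuntimeError):
    """Forward sampling exhausted its rejection budget."""


@dataclass(frozen=True)
class EmissionModel:
    """Terminal emission distributions: unpaired bases and ordered base pairs.

    ``paired`` assigns probability only to the six canonical ordered pairs
    (G-C, C-G, A-U, U-A, G-U, U-G); every other ordered pair implicitly has
    probability zero.
    """

    unpaired: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_UNPAIRED))
    paired: Dict[Tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_PAIRED)
    )

    def __post_init__(self) -> None:
        if set(self.unpaired) != set(ALPHABET):
            raise InvalidEmissionError("unpaired must cover exactly A, C, G, U")
        if any(p < 0 for p in self.unpaired.values()):
            raise InvalidEmissionError("negative unpaired probability")
        if abs(sum(self.unpaired.values()) - 1.0) > 1e-9:
            raise InvalidEmissionError("unpaired probabilities must sum to 1")
        for pair, p in self.paired.items():
            if pair not in CANONICAL_PAIRS:
                if p != 0:
                    raise InvalidEmissionError(
                        f"non-canonical pair {pair} must have probability 0"
                    )
            elif p < 0:
                raise InvalidEmissionError("negative pair probability")
        total = sum(self.paired.get(pair, 0.0) for pair in CANONICAL_PAIRS)
        if abs(total - 1.0) > 1e-9:
            raise InvalidEmissionError("canonical pair probabilities must sum to 1")

    @classmethod
    def default(cls) -> "EmissionModel":
        return cls()

    def u(self, base: str) -> float:
        """Unpaired emission probability of ``base``."""
        return self.unpaired[base]

    def pi(self, a: str, b: str) -> float:
        """Pair emission probability of the ordered pair (a, b); 0 if non-canonical."""
        return self.paired.get((a, b), 0.0)


@dataclass(frozen=True)
class GrammarParams:
    """Probabilities p1..p7 of the seven production rules, plus q_bp.

    Invariants: p1+p2+p3+p4 = 1, p5+p6 = 1, p7 = 1, all in [0, 1].
    ``qbp`` is the geometric mean of the six canonical pair probabilities.
    """

    p1: float
    p2: float
    p3: float
    p4: float
    p5: float
    p6: float
    p7: float
    qbp: float

    def __post_init__(self) -> None:
        ps = (self.p1, self.p2, self.p3, self.p4, self.p5, self.p6, self.p7)
        if any(not (0.0 <= p <= 1.0) for p in ps):
            raise ValueError("rule probabilities must lie in [0, 1]")
        if abs(self.p1 + self.p2 + self.p3 + self.p4 - 1.0) > 1e-9:
            raise ValueError("p1 + p2 + p3 + p4 must equal 1")
        if abs(self.p5 + self.p6 - 1.0) > 1e-9:
            raise ValueError("p5 + p6 must equal 1")
        if self.p7 != 1.0:
            raise ValueError("p7 must equal 1")

    def rule(self, number: int) -> float:
        return (self.p1, self.p2, self.p3, self.p4, self.p5, self.p6, self.p7)[
            number - 1
        ]


@dataclass(frozen=True)
class Grammar:
    """Symbolic description of the seven rules (left-hand side, shape, children).

    Shapes: ``a`` emit-unpaired, ``aX`` emit-unpaired-then-continue,
    ``aHb``/``aYb``/``aXb`` emit-pair-around-child, ``aHbX``
    emit-pair-around-child-then-continue.
    """

    nonterminals: Tuple[str, ...] = ("X", "H", "Y")
    start: str = "X"
    #: rule number -> (lhs, rhs shape string)
    rules: Tuple[Tuple[int, str, str], ...] = (
        (1, "X", "a"),
        (2, "X", "aX"),
        (3, "X", "aHb"),
        (4, "X", "aHbX"),
        (5, "H", "aHb"),
        (6, "H", "aYb"),
        (7, "Y", "aXb"),
    )


GRAMMAR = Grammar()


def compute_qbp(em: EmissionModel) -> float:
    """Geometric mean of the six canonical pair probabilities.

    Raises :class:`InvalidEmissionError` if any canonical pair has
    probability <= 0 (the geometric mean would degenerate).
    """
    logs = []
    for pair in sorted(CANONICAL_PAIRS):
        p = em.pi(*pair)
        if p <= 0:
            raise InvalidEmissionError(f"canonical pair {pair} has probability {p}")
        logs.append(math.log(p))
    return math.exp(sum(logs) / 6.0)


def solve_rule_probabilities(
    em: EmissionModel,
    tol: float = 1e-12,
    max_iter: int = 10_000,
) -> GrammarParams:
    """Solve the maximum-entropy constraint system for the rule probabilities.

    The constraints are p1 = p2, p3 = p4, p1+p2+p3+p4 = 1, p5+p6 = 1,
    p7 = 1, together with the two pairing/unpaired balance equations

        qbp^3 * p3 * p6 * p7 = (u * p1)^6
        qbp^4 * p3 * p5 * p6 * p7 = (u * p1)^8

    where ``u`` is the geometric-mean unpaired-base probability (0.25 for
    the uniform default).  Dividing the second by the first gives
    p5 = (u*p1)^2 / qbp, and the first then gives p3; iterating
    p1 = 1/2 - p3 converges rapidly because p3 << 1.
    """
    qbp = compute_qbp(em)
    # geometric-mean unpaired probability; equals 0.25 for the default
    if any(p <= 0 for p in em.unpaired.values()):
        raise InvalidEmissionError("unpaired probabilities must be positive")
    u = math.exp(sum(math.log(p) for p in em.unpaired.values()) / 4.0)

    p1 = 0.5
    p3 = p5 = 0.0
    for _ in range(max_iter):
        p5 = (u * p1) ** 2 / qbp
        if not 0.0 < p5 < 1.0:
            raise SolverError(f"p5 = {p5} outside (0, 1)")
        p3 = (u * p1) ** 6 / (qbp**3 * (1.0 - p5))
        p1_new = 0.5 - p3
        if abs(p1_new - p1) < tol:
            p1 = p1_new
            break
        p1 = p1_new
    else:
        raise SolverError(f"no convergence after {max_iter} iterations")

    p5 = (u * p1) ** 2 / qbp
    p3 = (u * p1) ** 6 / (qbp**3 * (1.0 - p5))
    p6 = 1.0 - p5
    params = GrammarParams(p1=p1, p2=p1, p3=p3, p4=p3, p5=p5, p6=p6, p7=1.0, qbp=qbp)

    r1 = qbp**3 * p3 * p6 * 1.0 - (u * p1) ** 6
    r2 = qbp**4 * p3 * p5 * p6 * 1.0 - (u * p1) ** 8
    if abs(r1) > 1e-9 or abs(r2) > 1e-9:
        raise SolverError(f"constraint residuals too large: {r1}, {r2}")
    return params


class _TooLong(Exception):
    pass


class _Sampler:
    """Forward sampler: one derivation drawn from the grammar's joint law."""

    def __init__(
        self,
        params: GrammarParams,
        em: EmissionModel,
        rng: np.random.Generator,
        max_length: int,
    ):
        self.params = params
        self.rng = rng
        self.max_length = max_length
        self.bases = list(ALPHABET)
        self.u_probs = np.array([em.u(b) for b in self.bases])
        self.pairs = sorted(CANONICAL_PAIRS)
        self.pair_probs = np.array([em.pi(a, b) for a, b in self.pairs])
        self.x_probs = np.array([params.p1, params.p2, params.p3, params.p4])
        self.h_probs = np.array([params.p5, params.p6])
        self.residues: List[str] = []
        self.pairs_out: List[Tuple[int, int]] = []
        self.rules_out: List[RuleApplication] = []
        self.logp = 0.0

    def _emit_unpaired(self) -> None:
        k = self.rng.choice(4, p=self.u_probs)
        self.residues.append(self.bases[k])
        self.logp += math.log(self.u_probs[k])
        if len(self.residues) > self.max_length:
            raise _TooLong

    def _draw_pair(self) -> Tuple[str, str]:
        k = self.rng.choice(len(self.pairs), p=self.pair_probs)
        self.logp += math.log(self.pair_probs[k])
        return self.pairs[k]

    def _record(self, rule: int, start: int) -> None:
        # span end patched once the expansion completes
        self.rules_out.append((rule, (start + 1, -1)))

    def expand_x(self) -> None:
        start = len(self.residues)
        idx = len(self.rules_out)
        rule = int(self.rng.choice(4, p=self.x_probs)) + 1
        self._record(rule, start)
        self.logp += math.log(self.params.rule(rule))
        if rule == 1:
            self._emit_unpaired()
        elif rule == 2:
            self._emit_unpaired()
            self.expand_x()
        elif rule in (3, 4):
            a, b = self._draw_pair()
            i = len(self.residues)
            self.residues.append(a)
            self.expand_h()
            j = len(self.residues)
            self.residues.append(b)
            self.pairs_out.append((i + 1, j + 1))
            if len(self.residues) > self.max_length:
                raise _TooLong
            if rule == 4:
                self.expand_x()
        self.rules_out[idx] = (rule, (start + 1, len(self.residues)))

    def expand_h(self) -> None:
        start = len(self.residues)
        idx = len(self.rules_out)
        rule = int(self.rng.choice(2, p=self.h_probs)) + 5
        self._record(rule, start)
        self.logp += math.log(self.params.rule(rule))
        a, b = self._draw_pair()
        i = len(self.residues)
        self.residues.append(a)
        if rule == 5:
            self.expand_h()
        else:
            self.expand_y()
        j = len(self.residues)
        self.residues.append(b)
        self.pairs_out.append((i + 1, j + 1))
        if len(self.residues) > self.max_length:
            raise _TooLong
        self.rules_out[idx] = (rule, (start + 1, len(self.residues)))

    def expand_y(self) -> None:
        start = len(self.residues)
        idx = len(self.rules_out)
        self._record(7, start)
        self.logp += math.log(self.params.p7)
        a, b = self._draw_pair()
        i = len(self.residues)
        self.residues.append(a)
        self.expand_x()
        j = len(self.residues)
        self.residues.append(b)
        self.pairs_out.append((i + 1, j + 1))
        if len(self.residues) > self.max_length:
            raise _TooLong
        self.rules_out[idx] = (7, (start + 1, len(self.residues)))


def sample_structure(
    params: GrammarParams,
    em: EmissionModel,
    max_length: int,
    rng_seed: Optional[int] = None,
    *,
    min_length: int = 1,
    min_pairs: int = 0,
    rng: Optional[np.random.Generator] = None,
    max_attempts: int = 100_000,
    identifier: str = "sample",
) -> Tuple[RnaSequence, SecondaryStructure]:
    """Draw one (sequence, structure) pair from the grammar's joint distribution.

    Rejection-samples until the emitted sequence has length in
    [min_length, max_length] and at least ``min_pairs`` base pairs.  With
    the same seed the result is identical across calls.
    """
    if max_length < 1:
        raise ValueError("max_length must be >= 1")
    if rng is None:
        rng = np.random.default_rng(rng_seed)
    # derivation depth grows with sequence length on unpaired chains
    limit = 6 * max_length + 1000
    if sys.getrecursionlimit() < limit:
        sys.setrecursionlimit(limit)
    for _ in range(max_attempts):
        sampler = _Sampler(params, em, rng, max_length)
        try:
            sampler.expand_x()
        except _TooLong:
            continue
        if len(sampler.residues) < min_length or len(sampler.pairs_out) < min_pairs:
            continue
        seq = RnaSequence(identifier, "".join(sampler.residues))
        struct = SecondaryStructure(
            pairs=frozenset(sampler.pairs_out),
            derivation=tuple(sampler.rules_out),
            probability=math.exp(sampler.logp),
        )
        return seq, struct
    raise SampleError(f"rejection budget of {max_attempts} attempts exhausted")
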