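"""Exhaustive derivation enumeration for small sequences.

This is the independent reference for the inside-outside machinery: it
recursively enumerates every complete derivation of a sequence under the
seven-rule grammar, with its exact probability, and computes base-pair
marginals directly as

    P_ij = Σ_{derivations containing (i,j)} p(derivation) / Σ p(derivation).

Derivations (not deduplicated pair sets) are the unit of enumeration,
matching what inside-outside marginalises: a long helix that the grammar
can split between two stems in more than one way counts once per
derivation.  Enumeration is exponential and refuses sequences longer than
``MAX_ENUMERATION_LENGTH``.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .grammar import EmissionModel, GrammarParams, sample_structure
from .inside_outside import PairProbabilityMatrix
from .sequences import ALPHABET, RnaSequence
from .structure import SecondaryStructure

__all__ = [
    "MAX_ENUMERATION_LENGTH",
    "enumerate_derivations",
    "oracle_pair_probabilities",
    "make_fixture_panel",
    "EnumerationSizeError",
    "STRUCTURED_SAMPLING_PARAMS",
]

MAX_ENUMERATION_LENGTH = 14


class EnumerationSizeError(ValueError):
    """Sequence too long for exhaustive enumeration."""


#: Parameter set used only for *sampling* structure-rich fixtures (never for
#: scoring): long unpaired chains (high p2) and long stems (high p5) so that
#: forward samples of realistic ncRNA length routinely contain helices.
#: Under the maximum-entropy scoring parameters (p3 ≈ 0.001) such samples
#: are vanishingly rare.
def STRUCTURED_SAMPLING_PARAMS() -> GrammarParams:
    from .grammar import compute_qbp

    em = EmissionModel.default()
    return GrammarParams(
        p1=0.10, p2=0.80, p3=0.05, p4=0.05, p5=0.80, p6=0.20, p7=1.0,
        qbp=compute_qbp(em),
    )


#: One partial result: (pairs tuple, derivation steps tuple, probability)
_Partial = Tuple[Tuple[Tuple[int, int], ...], Tuple[Tuple[int, Tuple[int, int]], ...], float]


def _enumerate(
    x: RnaSequence, params: GrammarParams, em: EmissionModel
) -> List[_Partial]:
    """All complete derivations of x from the start symbol X."""
    res = x.residues
    u = [em.u(b) for b in res]

    def pi(i: int, j: int) -> float:  # 0-based
        return em.pi(res[i], res[j])

    cache: Dict[Tuple[str, int, int], List[_Partial]] = {}

    def derive(sym: str, i: int, j: int) -> List[_Partial]:
        # 0-based inclusive span
        key = (sym, i, j)
        if key in cache:
            return cache[key]
        out: List[_Partial] = []
        span1 = (i + 1, j + 1)
        if sym == "X":
            if i == j:
                out.append(((), ((1, span1),), params.p1 * u[i]))
            else:
                for pairs, deriv, prob in derive("X", i + 1, j):
                    out.append((pairs, ((2, span1),) + deriv, params.p2 * u[i] * prob))
                if j - i >= 6 and pi(i, j) > 0:
                    w = params.p3 * pi(i, j)
                    for pairs, deriv, prob in derive("H", i + 1, j - 1):
                        out.append(
                            (((i + 1, j + 1),) + pairs, ((3, span1),) + deriv, w * prob)
                        )
                for k in range(i + 6, j):
                    if pi(i, k) <= 0:
                        continue
                    w = params.p4 * pi(i, k)
                    left = derive("H", i + 1, k - 1)
                    right = derive("X", k + 1, j)
                    for lp, ld, lw in left:
                        for rp, rd, rw in right:
                            out.append(
                                (
                                    ((i + 1, k + 1),) + lp + rp,
                                    ((4, span1),) + ld + rd,
                                    w * lw * rw,
                                )
                            )
        elif sym == "H":
            if j - i >= 4 and pi(i, j) > 0:
                if j - i >= 6:
                    w = params.p5 * pi(i, j)
                    for pairs, deriv, prob in derive("H", i + 1, j - 1):
                        out.append(
                            (((i + 1, j + 1),) + pairs, ((5, span1),) + deriv, w * prob)
                        )
                w = params.p6 * pi(i, j)
                for pairs, deriv, prob in derive("Y", i + 1, j - 1):
                    out.append(
                        (((i + 1, j + 1),) + pairs, ((6, span1),) + deriv, w * prob)
                    )
        elif sym == "Y":
            if j - i >= 2 and pi(i, j) > 0:
                w = params.p7 * pi(i, j)
                for pairs, deriv, prob in derive("X", i + 1, j - 1):
                    out.append(
                        (((i + 1, j + 1),) + pairs, ((7, span1),) + deriv, w * prob)
                    )
        cache[key] = out
        return out

    return derive("X", 0, x.n - 1)


def enumerate_derivations(
    x: RnaSequence,
    params: GrammarParams,
    em: Optional[EmissionModel] = None,
    max_length: int = MAX_ENUMERATION_LENGTH,
) -> List[SecondaryStructure]:
    """Every complete derivation of x with its exact probability.

    Raises :class:`EnumerationSizeError` above ``max_length`` nucleotides
    (the count grows exponentially).
    """
    if x.n > max_length:
        raise EnumerationSizeError(
            f"n = {x.n} exceeds enumeration limit {max_length}"
        )
    if em is None:
        em = EmissionModel.default()
    return [
        SecondaryStructure(pairs=frozenset(pairs), derivation=deriv, probability=prob)
        for pairs, deriv, prob in _enumerate(x, params, em)
    ]


def oracle_pair_probabilities(
    x: RnaSequence,
    params: GrammarParams,
    em: Optional[EmissionModel] = None,
    max_length: int = MAX_ENUMERATION_LENGTH,
) -> PairProbabilityMatrix:
    """P_ij by direct summation over enumerated derivations."""
    structures = enumerate_derivations(x, params, em, max_length=max_length)
    n = x.n
    total = sum(s.probability for s in structures)
    mat = np.zeros((n, n))
    for s in structures:
        for i, j in s.pairs:
            mat[i - 1, j - 1] += s.probability
    mat /= total
    return PairProbabilityMatrix(identifier=x.identifier, matrix=mat)


def _structured_exact(
    rng: np.random.Generator,
    size: int,
    em: EmissionModel,
    sp: GrammarParams,
    identifier: str,
) -> RnaSequence:
    """A structured sequence of exactly ``size`` nucleotides.

    Concatenates independent grammar samples (the grammar's bifurcation
    rule makes a concatenation of X-derivations itself a valid derivation)
    and pads any sub-helix-sized remainder with unpaired random bases.
    """
    bases = np.array(list(ALPHABET))
    parts: List[str] = []
    remaining = size
    while remaining > 0:
        if remaining < 12:
            parts.append("".join(rng.choice(bases, size=remaining)))
            break
        x, _ = sample_structure(sp, em, max_length=remaining, rng=rng)
        parts.append(x.residues)
        remaining -= x.n
    return RnaSequence(identifier, "".join(parts))


def make_fixture_panel(
    seed: int,
    sizes: Sequence[int],
    structured_per_size: int = 1,
    random_per_size: int = 1,
) -> List[RnaSequence]:
    """Deterministic mixed test panel of sequences at the requested sizes.

    Contains, per size: uniform-random sequences, grammar-sampled
    structured sequences (length-rejected to the exact size where
    feasible), and the degenerate cases poly-A, alternating GC, and
    alternating GU once each at the largest size.
    """
    if any(s < 1 or s > 500 for s in sizes):
        raise ValueError("sizes must lie in [1, 500]")
    rng = np.random.default_rng(seed)
    em = EmissionModel.default()
    sp = STRUCTURED_SAMPLING_PARAMS()
    panel: List[RnaSequence] = []
    bases = np.array(list(ALPHABET))
    for size in sizes:
        for r in range(random_per_size):
            seq = "".join(rng.choice(bases, size=size))
            panel.append(RnaSequence(f"rand_n{size}_{r}", seq))
        for r in range(structured_per_size):
            panel.append(
                _structured_exact(rng, size, em, sp, f"struct_n{size}_{r}")
            )
    top = max(sizes)
    panel.append(RnaSequence(f"polyA_n{top}", "A" * top))
    gc = ("GC" * ((top + 1) // 2))[:top]
    panel.append(RnaSequence(f"altGC_n{top}", gc))
    gu = ("GU" * ((top + 1) // 2))[:top]
    panel.append(RnaSequence(f"altGU_n{top}", gu))
    return panel
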