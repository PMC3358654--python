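"""Inside-outside base-pair probabilities and Shannon base-pairing entropy.

For a sequence x of length n the inside probability α(S, i, j) is the total
probability that nonterminal S derives x_i..x_j; the outside probability
β(S, i, j) is the total probability that the start symbol derives
x_1..x_{i-1} S x_{j+1}..x_n.  Pair probabilities are posterior marginals of
the pair-emitting rule applications,

    P_ij = Σ_{S→aRbT} p(S→aRbT) · π(x_i, x_j) · γ(R, S, T, i, j) / α(X, 1, n)

with γ(R,S,T,i,j) = Σ_{j<k≤n} α(R,i+1,j-1)·β(S,i,k)·α(T,j+1,k); for the
rules without a trailing child T the sum collapses to k = j and the α(T,·)
factor is dropped.  The Shannon base-pairing entropy is

    Q(x) = -(1/n) Σ_{i<j} P_ij log P_ij        (natural log, 0·log 0 = 0).

Numerics: derivation probabilities decay geometrically in n (roughly
(p2/4)^n ≈ 0.125^n), so charts are computed with per-position rescaled
emissions u/s and π/s² (default s = 0.125).  Every chart entry is then the
true probability divided by s^(span length) (outside: s^(context length)),
all recurrences are unchanged, and s cancels exactly in P_ij.  Setting
s = 1 recovers plain linear space, used in tests for small n.  The whole
computation is O(n³) time and O(n²) memory and stays finite and accurate
for n up to several hundred.

All public indices are 1-based inclusive, matching the α(S, i, j) notation
above; storage is 0-based internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .grammar import EmissionModel, GrammarParams
from .sequences import RnaSequence

__all__ = [
    "InsideChart",
    "OutsideChart",
    "PairProbabilityMatrix",
    "EntropyResult",
    "DEFAULT_SCALE",
    "inside",
    "outside",
    "pair_probabilities",
    "shannon_entropy",
    "entropy_of_sequence",
    "ChartMismatchError",
]

DEFAULT_SCALE = 0.125


class ChartMismatchError(ValueError):
    """Inside/outside charts combined across different sequences or scales."""


@dataclass
class InsideChart:
    """Scaled inside probabilities for nonterminals X, H, Y.

    ``ax[i, j]`` etc. hold α(S, i+1, j+1) / scale^(j-i+1) on the upper
    triangle (0-based storage).  Use :meth:`alpha` / :meth:`log_alpha` for
    true values.
    """

    sequence: RnaSequence
    params: GrammarParams
    em: EmissionModel
    scale: float
    ax: np.ndarray
    ah: np.ndarray
    ay: np.ndarray
    u: np.ndarray = field(repr=False)  # scaled unpaired emissions per position
    pi: np.ndarray = field(repr=False)  # scaled pair emissions, n x n

    @property
    def n(self) -> int:
        return self.sequence.n

    def _arr(self, symbol: str) -> np.ndarray:
        return {"X": self.ax, "H": self.ah, "Y": self.ay}[symbol]

    def alpha(self, symbol: str, i: int, j: int) -> float:
        """True (unscaled) inside probability α(S, i, j), 1-based inclusive."""
        span = j - i + 1
        return float(self._arr(symbol)[i - 1, j - 1] * self.scale**span)

    def log_alpha(self, symbol: str, i: int, j: int) -> float:
        v = self._arr(symbol)[i - 1, j - 1]
        if v <= 0:
            return -np.inf
        return float(np.log(v) + (j - i + 1) * np.log(self.scale))

    def total_probability(self) -> float:
        """α(X, 1, n): total probability of the sequence under the model."""
        return self.alpha("X", 1, self.n)

    def log_total_probability(self) -> float:
        return self.log_alpha("X", 1, self.n)


@dataclass
class OutsideChart:
    """Scaled outside probabilities; ``bx[i, j]`` = β(X, i+1, j+1)/scale^(n-span)."""

    sequence: RnaSequence
    scale: float
    bx: np.ndarray
    bh: np.ndarray
    by: np.ndarray

    @property
    def n(self) -> int:
        return self.sequence.n

    def _arr(self, symbol: str) -> np.ndarray:
        return {"X": self.bx, "H": self.bh, "Y": self.by}[symbol]

    def beta(self, symbol: str, i: int, j: int) -> float:
        """True (unscaled) outside probability β(S, i, j), 1-based inclusive."""
        outside_len = self.n - (j - i + 1)
        return float(self._arr(symbol)[i - 1, j - 1] * self.scale**outside_len)


@dataclass
class PairProbabilityMatrix:
    """Upper-triangular matrix of base-pairing probabilities P_ij."""

    identifier: str
    matrix: np.ndarray  # n x n, strictly upper triangular

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def prob(self, i: int, j: int) -> float:
        """P_ij for 1-based i < j."""
        if not (1 <= i < j <= self.n):
            raise IndexError(f"need 1 <= i < j <= {self.n}")
        return float(self.matrix[i - 1, j - 1])

    def row_sums(self) -> np.ndarray:
        """Σ_{j≠i} P_ij per position i; ≤ 1 since pairing partners are disjoint."""
        full = self.matrix + self.matrix.T
        return full.sum(axis=1)

    def nonzero_entries(self):
        """Yield (i, j, P_ij) with 1-based indices for every positive entry."""
        rows, cols = np.nonzero(self.matrix)
        for r, c in zip(rows, cols):
            yield int(r) + 1, int(c) + 1, float(self.matrix[r, c])


@dataclass(frozen=True)
class EntropyResult:
    """Shannon base-pairing entropy Q and the expected number of pairs."""

    identifier: str
    n: int
    Q: float
    expected_pairs: float


def _scaled_emissions(x: RnaSequence, em: EmissionModel, scale: float):
    n = x.n
    u = np.array([em.u(b) for b in x.residues]) / scale
    pi = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pi[i, j] = em.pi(x.residues[i], x.residues[j])
    pi /= scale * scale
    return u, pi


def inside(
    x: RnaSequence,
    params: GrammarParams,
    em: Optional[EmissionModel] = None,
    scale: float = DEFAULT_SCALE,
) -> InsideChart:
    """Fill the inside chart by dynamic programming over increasing span length.

    Recurrences (1-based spans):

        α(X,i,i) = p1·u_i
        α(X,i,j) = p2·u_i·α(X,i+1,j) + p3·π_ij·α(H,i+1,j-1)
                   + p4·Σ_{i<k<j} π_ik·α(H,i+1,k-1)·α(X,k+1,j)
        α(H,i,j) = p5·π_ij·α(H,i+1,j-1) + p6·π_ij·α(Y,i+1,j-1)
        α(Y,i,j) = p7·π_ij·α(X,i+1,j-1)

    Span minima (Y ≥ 3, H ≥ 5, pair-bearing X ≥ 7) fall out of the zero
    initialisation; no special-casing is needed.
    """
    if em is None:
        em = EmissionModel.default()
    n = x.n
    u, pi = _scaled_emissions(x, em, scale)
    ax = np.zeros((n, n))
    ah = np.zeros((n, n))
    ay = np.zeros((n, n))
    p1, p2, p3, p4 = params.p1, params.p2, params.p3, params.p4
    p5, p6, p7 = params.p5, params.p6, params.p7

    idx0 = np.arange(n)
    ax[idx0, idx0] = p1 * u

    for L in range(2, n + 1):
        i = np.arange(0, n - L + 1)
        j = i + L - 1
        # X -> aX
        vals = p2 * u[i] * ax[i + 1, j]
        if L >= 3:
            # Y -> aXb
            ay[i, j] = p7 * pi[i, j] * ax[i + 1, j - 1]
        if L >= 5:
            # H -> aHb | aYb (aHb inner span L-2 ≥ 5 is zero below L = 7)
            ah[i, j] = pi[i, j] * (p5 * ah[i + 1, j - 1] + p6 * ay[i + 1, j - 1])
        if L >= 7:
            # X -> aHb
            vals = vals + p3 * pi[i, j] * ah[i + 1, j - 1]
        if L >= 8:
            # X -> aHbX, bifurcation over the paired partner k of position i
            for ii, jj in zip(i, j):
                ks = np.arange(ii + 6, jj)
                vals[ii - i[0]] += p4 * np.dot(
                    pi[ii, ks] * ah[ii + 1, ks - 1], ax[ks + 1, jj]
                )
        ax[i, j] = vals
    return InsideChart(
        sequence=x, params=params, em=em, scale=scale, ax=ax, ah=ah, ay=ay, u=u, pi=pi
    )


def outside(chart: InsideChart) -> OutsideChart:
    """Fill the outside chart top-down from β(X, 1, n) = 1.

    Each rule application at a parent span distributes its outside mass to
    its children weighted by rule probability, emissions, and the inside
    probabilities of sibling subtrees, so that α(S,i,j)·β(S,i,j) is the
    total probability of derivations in which S spans (i, j).
    """
    n = chart.n
    u, pi = chart.u, chart.pi
    ax, ah, ay = chart.ax, chart.ah, chart.ay
    p = chart.params
    bx = np.zeros((n, n))
    bh = np.zeros((n, n))
    by = np.zeros((n, n))
    bx[0, n - 1] = 1.0

    for L in range(n, 0, -1):
        for i in range(0, n - L + 1):
            j = i + L - 1
            b = bx[i, j]
            if b > 0.0:
                if L >= 2:
                    bx[i + 1, j] += p.p2 * u[i] * b
                if L >= 7:
                    bh[i + 1, j - 1] += p.p3 * pi[i, j] * b
                if L >= 8:
                    ks = np.arange(i + 6, j)
                    w = p.p4 * pi[i, ks] * b
                    bh[i + 1, ks - 1] += w * ax[ks + 1, j]
                    bx[ks + 1, j] += w * ah[i + 1, ks - 1]
            b = bh[i, j]
            if b > 0.0 and L >= 5:
                if L >= 7:
                    bh[i + 1, j - 1] += p.p5 * pi[i, j] * b
                by[i + 1, j - 1] += p.p6 * pi[i, j] * b
            b = by[i, j]
            if b > 0.0 and L >= 3:
                bx[i + 1, j - 1] += p.p7 * pi[i, j] * b
    return OutsideChart(sequence=chart.sequence, scale=chart.scale, bx=bx, bh=bh, by=by)


def pair_probabilities(
    chart: InsideChart, out: Optional[OutsideChart] = None
) -> PairProbabilityMatrix:
    """Posterior base-pair probabilities P_ij from the two charts.

    Sums, over the five pair-emitting rules, rule probability × pair
    emission × inside of the enclosed child × outside of the parent span
    (× inside of the trailing sibling for the bifurcation rule), normalised
    by the total inside probability α(X, 1, n).
    """
    if out is None:
        out = outside(chart)
    if out.sequence.residues != chart.sequence.residues or out.scale != chart.scale:
        raise ChartMismatchError("outside chart does not match inside chart")
    n = chart.n
    ax, ah, ay = chart.ax, chart.ah, chart.ay
    bx, bh, by = out.bx, out.bh, out.by
    pi = chart.pi
    p = chart.params
    z = ax[0, n - 1]
    if z <= 0.0:
        raise RuntimeError("total inside probability vanished")

    # child inside values re-indexed to the parent pair span: M_in[i, j] = M[i+1, j-1]
    def inner(m: np.ndarray) -> np.ndarray:
        shifted = np.zeros((n, n))
        shifted[: n - 1, 1:] = m[1:, : n - 1]
        return shifted

    ah_in, ay_in, ax_in = inner(ah), inner(ay), inner(ax)
    # γ for the bifurcation rule: G[i, j] = Σ_{k>j} β(X, i, k)·α(X, j+1, k)
    a_right = np.zeros((n, n))
    a_right[: n - 1, :] = ax[1:, :]
    G = bx @ a_right.T

    num = pi * (
        p.p3 * ah_in * bx
        + p.p4 * ah_in * G
        + p.p5 * ah_in * bh
        + p.p6 * ay_in * bh
        + p.p7 * ax_in * by
    )
    mat = np.triu(num, k=1) / z
    return PairProbabilityMatrix(identifier=chart.sequence.identifier, matrix=mat)


def shannon_entropy(P: PairProbabilityMatrix, log_base: float = np.e) -> EntropyResult:
    """Q = -(1/n) Σ_{i<j} P_ij log P_ij with the 0·log 0 = 0 convention.

    The logarithm base only rescales Q by a constant, which cancels in any
    Z-score; the natural log is the default.
    """
    m = P.matrix
    pos = m[m > 0.0]
    if pos.size:
        q = -float(np.sum(pos * np.log(pos))) / P.n
        if log_base != np.e:
            q /= np.log(log_base)
    else:
        q = 0.0
    return EntropyResult(
        identifier=P.identifier, n=P.n, Q=q, expected_pairs=float(m.sum())
    )


def entropy_of_sequence(
    x: RnaSequence,
    params: GrammarParams,
    em: Optional[EmissionModel] = None,
    scale: float = DEFAULT_SCALE,
    log_base: float = np.e,
) -> EntropyResult:
    """Convenience: inside → outside → P_ij → Q for one sequence."""
    chart = inside(x, params, em, scale=scale)
    return shannon_entropy(pair_probabilities(chart), log_base=log_base)
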