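"""Secondary structures as base-pair sets with their grammar derivations."""

from __future__ import annotations

from dataclasses import dataclass
from typing import FrozenSet, List, Tuple

#: One derivation step: (rule number 1..7, 1-based span (i, j) of the
#: expanded nonterminal).
RuleApplication = Tuple[int, Tuple[int, int]]


@dataclass(frozen=True)
class SecondaryStructure:
    """A pseudoknot-free secondary structure together with one derivation.

    ``pairs`` are 1-based (i, j) with i < j, non-crossing, each position in
    at most one pair.  ``probability`` is the joint probability of the
    derivation: the product of one rule probability per application and one
    emission probability per emitted unpaired base or base pair.
    """

    pairs: FrozenSet[Tuple[int, int]]
    derivation: Tuple[RuleApplication, ...]
    probability: float

    def stems(self) -> List[List[Tuple[int, int]]]:
        """Maximal runs of directly nested pairs (i,j),(i+1,j-1),...

        The structure model requires every such run to contain at least
        three pairs.
        """
        remaining = set(self.pairs)
        runs: List[List[Tuple[int, int]]] = []
        for i, j in sorted(self.pairs):
            if (i, j) not in remaining:
                continue
            # (i, j) starts a run only if it is not stacked on an outer pair
            if (i - 1, j + 1) in self.pairs:
                continue
            run = []
            a, b = i, j
            while (a, b) in remaining:
                run.append((a, b))
                remaining.discard((a, b))
                a, b = a + 1, b - 1
            runs.append(run)
        return runs

    def min_stem_length(self) -> int:
        """Length of the shortest stem, or a large sentinel if unpaired."""
        runs = self.stems()
        if not runs:
            return 10**9
        return min(len(r) for r in runs)
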