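"""Validated RNA sequences.

A sequence is kept as an upper-case string over the alphabet {A, C, G, U};
DNA input is accepted by silently mapping T to U.  Any other symbol
(ambiguity codes, gaps, ...) makes the sequence invalid, and callers are
expected to drop such records from analyses rather than guess at their
content.
"""

from __future__ import annotations

from dataclasses import dataclass, field

ALPHABET = "ACGU"

#: Watson-Crick plus wobble pairs, the only pairings the structure model allows.
CANONICAL_PAIRS = frozenset(
    [("G", "C"), ("C", "G"), ("A", "U"), ("U", "A"), ("G", "U"), ("U", "G")]
)


class InvalidSequenceError(ValueError):
    """Raised when a sequence contains symbols outside {A, C, G, U} (after T→U)."""

    def __init__(self, identifier: str, symbol: str):
        self.identifier = identifier
        self.symbol = symbol
        super().__init__(
            f"sequence {identifier!r} contains non-ACGU symbol {symbol!r}"
        )


@dataclass(frozen=True)
class RnaSequence:
    """An RNA sequence x = x_1 x_2 ... x_n over {A, C, G, U}.

    Positions in all public interfaces are 1-based and inclusive.
    """

    identifier: str
    residues: str = field(compare=True)

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise InvalidSequenceError(self.identifier, "<empty>")
        for ch in self.residues:
            if ch not in ALPHABET:
                raise InvalidSequenceError(self.identifier, ch)

    @classmethod
    def from_string(cls, identifier: str, raw: str) -> "RnaSequence":
        """Build a sequence from raw text: upper-cases and maps T→U.

        Raises :class:`InvalidSequenceError` on any other non-ACGU symbol.
        """
        cleaned = raw.strip().upper().replace("T", "U")
        return cls(identifier, cleaned)

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def n(self) -> int:
        return len(self.residues)

    def base(self, i: int) -> str:
        """Residue at 1-based position ``i``."""
        return self.residues[i - 1]

    def can_pair(self, i: int, j: int) -> bool:
        """True if positions i and j (1-based) hold a canonical pair."""
        return (self.base(i), self.base(j)) in CANONICAL_PAIRS

    def __str__(self) -> str:
        return self.residues
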