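"""Shuffled and sampled background sequence sets.

Z-scores compare a sequence's entropy against a null distribution of
entropies from composition-matched random sequences.  Three backgrounds
are supported:

* ``mono``  — uniformly random permutations of the residues (exact
  single-nucleotide composition preserved);
* ``dinuc`` — Altschul–Erickson Euler-path shuffles (exact ordered
  dinucleotide composition preserved; first and last residues are fixed
  as a consequence);
* ``external`` — fixed-length segments sampled from user-supplied
  background sequences, e.g. genomic context.

The random stream for a background set is derived from (seed, source
identifier), so per-sequence backgrounds do not depend on the order in
which sequences are processed.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .sequences import RnaSequence

__all__ = [
    "ShuffleSet",
    "mono_shuffle",
    "dinucleotide_shuffle",
    "load_background",
    "sample_background_segments",
    "rng_for",
    "InsufficientBackgroundError",
    "DEFAULT_SHUFFLE_COUNT",
]

DEFAULT_SHUFFLE_COUNT = 100


class InsufficientBackgroundError(ValueError):
    """No background segment of the required length is available."""


@dataclass(frozen=True)
class ShuffleSet:
    """A background set for one source sequence."""

    source_id: str
    mode: str  # "mono" | "dinuc" | "external"
    members: Tuple[RnaSequence, ...]
    seed: Optional[int]


def rng_for(seed: Optional[int], identifier: str) -> np.random.Generator:
    """Independent, order-insensitive random stream for one source sequence."""
    digest = hashlib.sha256(identifier.encode()).digest()
    ident_key = int.from_bytes(digest[:8], "big")
    if seed is None:
        return np.random.default_rng()
    return np.random.default_rng(np.random.SeedSequence([seed, ident_key]))


def mono_shuffle(
    x: RnaSequence, count: int = DEFAULT_SHUFFLE_COUNT, seed: Optional[int] = None
) -> ShuffleSet:
    """``count`` uniformly random permutations of the residues of x."""
    if count < 1:
        raise ValueError("count must be >= 1")
    rng = rng_for(seed, x.identifier)
    residues = np.array(list(x.residues))
    members = []
    for k in range(count):
        perm = rng.permutation(residues)
        members.append(
            RnaSequence(f"{x.identifier}.shuffle.{k}", "".join(perm))
        )
    return ShuffleSet(x.identifier, "mono", tuple(members), seed)


def _euler_shuffle(residues: str, rng: np.random.Generator) -> str:
    """One Altschul–Erickson dinucleotide-preserving shuffle.

    Builds the multigraph whose edges are the ordered dinucleotides, picks
    a random terminal edge for every vertex other than the final residue
    such that the terminal edges form paths leading to the final residue
    (a uniformly random in-tree), shuffles the remaining out-edges, and
    reads off the Eulerian walk from the first residue.  The result has
    exactly the source's dinucleotide multiset, hence also its
    mononucleotide counts and endpoints.
    """
    n = len(residues)
    s1, sn = residues[0], residues[-1]
    out_edges: Dict[str, List[str]] = {}
    for a, b in zip(residues, residues[1:]):
        out_edges.setdefault(a, []).append(b)
    vertices = list(out_edges)

    # choose last edges forming an in-tree toward sn (rejection over random picks)
    last_edge: Dict[str, str] = {}
    while True:
        last_edge = {
            v: out_edges[v][rng.integers(len(out_edges[v]))]
            for v in vertices
            if v != sn
        }
        ok = True
        for v in last_edge:
            seen = {v}
            w = v
            while w != sn:
                w = last_edge.get(w)
                if w is None or w in seen:
                    ok = False
                    break
                seen.add(w)
            if not ok:
                break
        if ok:
            break

    walk_edges: Dict[str, List[str]] = {}
    for v in vertices:
        edges = list(out_edges[v])
        if v in last_edge:
            edges.remove(last_edge[v])
        order = rng.permutation(len(edges))
        shuffled = [edges[i] for i in order]
        if v in last_edge:
            shuffled.append(last_edge[v])
        walk_edges[v] = shuffled

    pos = {v: 0 for v in vertices}
    out = [s1]
    v = s1
    for _ in range(n - 1):
        nxt = walk_edges[v][pos[v]]
        pos[v] += 1
        out.append(nxt)
        v = nxt
    return "".join(out)


def dinucleotide_shuffle(
    x: RnaSequence, count: int = DEFAULT_SHUFFLE_COUNT, seed: Optional[int] = None
) -> ShuffleSet:
    """``count`` Euler-path shuffles preserving ordered dinucleotide counts."""
    if x.n < 2:
        raise ValueError("dinucleotide shuffle requires n >= 2")
    if count < 1:
        raise ValueError("count must be >= 1")
    rng = rng_for(seed, x.identifier)
    members = tuple(
        RnaSequence(f"{x.identifier}.shuffle.{k}", _euler_shuffle(x.residues, rng))
        for k in range(count)
    )
    return ShuffleSet(x.identifier, "dinuc", members, seed)


def sample_background_segments(
    background: Sequence[RnaSequence],
    target: RnaSequence,
    count: int = DEFAULT_SHUFFLE_COUNT,
    seed: Optional[int] = None,
) -> ShuffleSet:
    """``count`` segments of length exactly n(target), drawn uniformly over
    all (record, start position) choices in the background set."""
    n = target.n
    eligible: List[Tuple[int, int]] = []  # (record index, #start positions)
    for idx, rec in enumerate(background):
        if rec.n >= n:
            eligible.append((idx, rec.n - n + 1))
    if not eligible:
        raise InsufficientBackgroundError(
            f"no background sequence of length >= {n}"
        )
    weights = np.array([c for _, c in eligible], dtype=float)
    weights /= weights.sum()
    rng = rng_for(seed, target.identifier)
    members = []
    for k in range(count):
        which = rng.choice(len(eligible), p=weights)
        rec = background[eligible[which][0]]
        start = int(rng.integers(eligible[which][1]))
        members.append(
            RnaSequence(
                f"{target.identifier}.bg.{k}",
                rec.residues[start : start + n],
            )
        )
    return ShuffleSet(target.identifier, "external", tuple(members), seed)


def load_background(
    path,
    target: RnaSequence,
    count: int = DEFAULT_SHUFFLE_COUNT,
    seed: Optional[int] = None,
) -> ShuffleSet:
    """Read a background FASTA and sample fixed-length segments from it."""
    from .io import read_fasta

    records = read_fasta(path)
    valid = [r.sequence for r in records if r.sequence is not None]
    return sample_background_segments(valid, target, count=count, seed=seed)
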