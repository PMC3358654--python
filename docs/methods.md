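# Methods

## The constrained structure ensemble

The model is a stochastic context-free grammar over three nonterminals,
X (start), H and Y:

```
(1) X → a     (2) X → aX     (3) X → aHb     (4) X → aHbX
(5) H → aHb   (6) H → aYb    (7) Y → aXb
```

A derivation generates a sequence left to right together with a
pseudoknot-free secondary structure; the flanking terminals of rules
(3)–(7) are base pairs. Because a stem can only be opened through
X → aHb(X), continued through H, and closed through H → aYb and Y → aXb,
every stem carries at least three directly nested pairs. Two consequences
used throughout the code: Y spans ≥ 3 nucleotides, H spans ≥ 5, and any
pair-carrying X expansion spans ≥ 7, so sequences shorter than 7
nucleotides have exactly one (fully unpaired) derivation; and a hairpin
loop always contains at least one position.

The grammar is derivationally ambiguous at the structure level: a helix of
six or more stacked pairs can be derived either as one stem or as two
stems separated by a zero-length loop (Y → aXb, X → aHb). All quantities
in this package marginalise over *derivations*, which is what the
inside–outside algorithm computes; the brute-force enumerator does the
same, so the two routes are comparable without deduplication. Structures
whose stems all have ≥ 6 pairs are therefore weighted by more than one
derivation — a property of the model, not an approximation.

## Probability parameters

Two separate parameter sets enter a derivation's probability, multiplied
one factor per event (standard SCFG semantics): an emission probability
for every terminal (0.25 per unpaired base; {0.25, 0.25, 0.17, 0.17,
0.08, 0.08} over G-C, C-G, A-U, U-A, G-U, U-G; zero for non-canonical
pairs) and a rule probability per production. Rule probabilities are not
estimated from structure databases. They solve the maximum-entropy
constraint system

```
p1 = p2,   p3 = p4,   p1+p2+p3+p4 = 1,   p5+p6 = 1,   p7 = 1,
qbp³·p3·p6·p7 = (u·p1)⁶,    qbp⁴·p3·p5·p6·p7 = (u·p1)⁸,
```

where `qbp` is the geometric mean of the six canonical pair probabilities
(0.15037 for the defaults) and `u` the geometric-mean unpaired probability
(the literal 0.25 generalised so that non-uniform emission models remain
solvable; identical for the defaults). Dividing the second balance
equation by the first gives `p5 = (u·p1)²/qbp`; substituting back gives
`p3`, and `p1 = 1/2 − p3` closes a fixed-point iteration started at
p1 = 0.5. Because p3 ≈ 10⁻³ the iteration contracts strongly and reaches
1e-12 within a handful of steps; the solution (p1 = p2 = 0.4987670,
p3 = p4 = 0.0012330, p5 = 0.1033989, p6 = 0.8966011, p7 = 1) is
cross-checked in the tests against an independent bracketing root-finder
and validated to residuals < 1e-9. Rule probabilities are recomputed from
the emission model at startup; the rounded values above serve as a
regression test, not as constants in the code.

## Inside–outside and the entropy

Pair probabilities are posterior marginals of pair-emitting rule
applications. With α the inside and β the outside chart,

```
P_ij = Σ_{S→aRbT} p(rule) · π(x_i, x_j) · γ(R,S,T,i,j) / α(X, 1, n),
γ = Σ_{j<k≤n} α(R, i+1, j−1) · β(S, i, k) · α(T, j+1, k),
```

where the k-sum and the α(T,·) factor exist only for the bifurcation rule
X → aHbX; for rules (3), (5), (6), (7) the sum collapses to k = j. The
computation is O(n³) time, O(n²) memory; the bifurcation terms of the
inside and outside passes are the only O(n³) loops, and the γ matrix for
the bifurcation rule is a single matrix product.

Numerical choices:

- **Rescaling, not log-space.** Derivation probabilities decay like
  ~0.125ⁿ, underflowing doubles near n ≈ 250. All emissions are divided
  by a per-position scale s (u → u/s, π → π/s², default s = 0.125) before
  the recurrences run. Every chart entry then equals the true value
  divided by s^(positions covered), the recurrences are algebraically
  unchanged, and s cancels exactly in P_ij. With s = 1 the computation is
  plain linear space; tests confirm bit-level-tight (1e-9 relative)
  agreement between the two for n ≤ 60, and finiteness plus mass
  invariants up to n = 500.
- **Logarithm base.** Q uses the natural logarithm. The base only rescales
  Q by a constant that cancels in the Z-score (asserted numerically in the
  tests), so the choice is immaterial downstream; `shannon_entropy` takes
  an optional base for reporting in bits.
- **Conventions.** 0·log 0 = 0; indices in every public interface are
  1-based inclusive spans; empty input is rejected at parse time; n < 7 is
  processed normally and yields Q = 0.

## Null models

- `mono` — uniformly random permutations; exact single-nucleotide counts.
- `dinuc` — Altschul–Erickson Euler-path shuffles: the ordered
  dinucleotide multiset is preserved exactly, which also fixes the first
  and last residues and all mononucleotide counts. A uniformly random
  in-tree toward the final residue is drawn by rejection, remaining
  out-edges are permuted, and the Eulerian walk is read off. Uniformity
  over attainable arrangements is smoke-tested with a chi-square test
  over the 2520 arrangements of ACGUACGU.
- `external` — fixed-length segments drawn uniformly over all (record,
  start) positions of a user-supplied FASTA, the "genome background" mode.

Background sets default to 100 members. Each source sequence gets its own
random stream derived from (seed, SHA-256 of its identifier), so results
are reproducible and independent of processing order. The Z-score uses
the sample (n−1) standard deviation — conventional at 100 draws, and the
population/sample difference is immaterial at that size. Zero background
variance (e.g. a homopolymer, whose shuffles are all identical) makes Z
undefined; such sequences are flagged and excluded from threshold tables
rather than aborting the run, and sequences containing non-ACGU symbols
are dropped at parse time with the offending symbol logged. The KS
normality check compares background entropies to a normal with the
sample's own mean and standard deviation; with estimated parameters the
p-value is approximate (anti-conservative), which is adequate for its
role as a sanity check on using Z-scores at all. Threshold tables count
Z ≥ t inclusively, defaults t ∈ {2, 1.5, 1, 0.5}, percentages to two
decimals.

## Synthetic data

Two generators make the package testable without external datasets.

The **forward sampler** draws (sequence, structure) pairs from the
grammar's own joint distribution — used to verify the stem constraint and
rule-frequency statistics. Under the maximum-entropy scoring parameters
base pairs are rare (p3 ≈ 0.001) and expected sequence length is a few
nucleotides, so samples are short and mostly unpaired; this is correct
for the model but useless as "structured RNA" input. Structure-rich
fixtures are therefore sampled with a separate parameter set
(p1 = 0.10, p2 = 0.80, p3 = p4 = 0.05, p5 = 0.80, p6 = 0.20), chosen to
give a mean sample length of a few dozen nucleotides and mean stem length
of about eight pairs — helix densities of the order seen in structural
RNAs. Scoring always uses the default maximum-entropy parameters;
the sampling set only shapes the fixtures. Fixture panels mix
uniform-random sequences, structured samples (concatenated to exact
target lengths, padding sub-helix remainders with random bases), and
degenerate cases (poly-A, alternating GC, alternating GU).

What these fixtures do not emulate: real ncRNA families' length and GC
composition profiles, non-canonical/tertiary interactions, and the
evolutionary conservation that real genome backgrounds carry. Passing the
discrimination test (structured samples scoring mean Z > 0 against 50
dinucleotide shuffles while composition-matched random sequences sit at
Z ≈ 0, sign tests at 5%) shows the entropy machinery separates designed
structure from matched noise at desk scale — sequences of 80–120 nt,
20 per arm, 50 shuffles each — not that it attains any particular
sensitivity on biological datasets.

The **brute-force enumerator** lists every derivation with its exact
probability for n ≤ 14 (a hard limit; the count grows exponentially) and
is the oracle for the central equivalence test: on 200 random sequences
with n ∈ [7, 12], inside–outside pair probabilities match enumeration to
1e-9 relative (observed agreement is at machine precision) and total
inside probability to 1e-12. The enumerator is itself cross-checked
against a second, memoisation-free recursion.

## Known limitations

- Stems interrupted by internal loops into runs of one or two pairs are
  invisible to the model; RNAs whose native folds rely on such short
  helix segments (e.g. some SRP RNAs) will score poorly.
- Pseudoknots are outside the grammar's expressive power.
- The dinucleotide shuffle fixes sequence endpoints (a property of the
  Euler-path construction); for sequences whose dinucleotide multiset
  admits only one arrangement (e.g. block sequences like GGGAAACCCUUU)
  the "shuffle" is the identity and Z is undefined.
- Runtime is O(n³) with a small constant; ~3 s at n = 500 on one core.
  Sequences beyond ~10³ nucleotides are impractical without banding.
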