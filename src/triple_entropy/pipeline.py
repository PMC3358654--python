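"""Entropy Z-scores against shuffled backgrounds, and threshold summaries.

For a sequence x with entropy Q(x) and a background set S_x of shuffled
(or sampled) sequences, the Z-score is

    Z(x) = ( μ(Q(S_x)) − Q(x) ) / σ(Q(S_x))

with μ and σ the sample mean and sample standard deviation of the
background entropies.  A sequence that folds more certainly (lower
entropy) than its composition-matched background scores positive.
Summary tables report, for a list of thresholds t, the percentage of
sequences with Z ≥ t (inclusive).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .grammar import EmissionModel, GrammarParams, solve_rule_probabilities
from .inside_outside import DEFAULT_SCALE, entropy_of_sequence
from .sequences import RnaSequence
from .shuffles import (
    DEFAULT_SHUFFLE_COUNT,
    ShuffleSet,
    dinucleotide_shuffle,
    load_background,
    mono_shuffle,
)

__all__ = [
    "ZScoreResult",
    "ThresholdTable",
    "DEFAULT_THRESHOLDS",
    "zscore",
    "ks_normality",
    "threshold_table",
    "run_pipeline",
    "UndefinedZScoreError",
    "EmptyResultError",
]

logger = logging.getLogger("triple_entropy")

DEFAULT_THRESHOLDS: Tuple[float, ...] = (2.0, 1.5, 1.0, 0.5)


class UndefinedZScoreError(ValueError):
    """Background entropy variance is zero; Z is undefined."""


class EmptyResultError(RuntimeError):
    """No valid sequence produced a result."""


@dataclass(frozen=True)
class ZScoreResult:
    """Per-sequence entropy Z-score with its background statistics."""

    identifier: str
    n: int
    Q_x: float
    mu: float
    sigma: float
    Z: Optional[float]  # None when sigma = 0 (flagged, excluded from tables)
    ks_pvalue: Optional[float]
    background_size: int

    @property
    def defined(self) -> bool:
        return self.Z is not None


@dataclass(frozen=True)
class ThresholdTable:
    """Percentages of sequences with Z ≥ t for each threshold t."""

    label: str
    thresholds: Tuple[float, ...]
    percentages: Tuple[float, ...]
    n_sequences: int

    def as_dict(self) -> Dict[float, float]:
        return dict(zip(self.thresholds, self.percentages))


def zscore(
    Q_x: float,
    background: Sequence[float],
    *,
    identifier: str = "",
    n: int = 0,
    ks_pvalue: Optional[float] = None,
) -> ZScoreResult:
    """Z = (mean(background) − Q_x) / sd(background), sample (n−1) sd.

    Raises :class:`UndefinedZScoreError` when the background variance is
    zero; callers that prefer flag-and-exclude catch it.
    """
    vals = np.asarray(background, dtype=float)
    if vals.size < 2:
        raise ValueError("background needs at least 2 values for a Z-score")
    mu = float(vals.mean())
    sigma = float(vals.std(ddof=1))
    if sigma == 0.0:
        raise UndefinedZScoreError(
            f"zero background entropy variance for {identifier or 'sequence'}"
        )
    z = (mu - Q_x) / sigma
    return ZScoreResult(
        identifier=identifier,
        n=n,
        Q_x=Q_x,
        mu=mu,
        sigma=sigma,
        Z=z,
        ks_pvalue=ks_pvalue,
        background_size=int(vals.size),
    )


def ks_normality(background: Sequence[float]) -> float:
    """p-value of a KS test of the values against N(mean, sd).

    The reference normal uses the sample's own mean and standard
    deviation, so the p-value is approximate (no Lilliefors correction);
    p ≥ 0.05 means normality is not rejected at 95% confidence.
    """
    vals = np.asarray(background, dtype=float)
    if vals.size < 5:
        raise ValueError("KS normality test needs at least 5 values")
    sd = vals.std(ddof=1)
    if sd == 0.0:
        raise ValueError("KS normality test undefined for constant values")
    return float(stats.kstest(vals, "norm", args=(vals.mean(), sd)).pvalue)


def threshold_table(
    results: Sequence[ZScoreResult],
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    label: str = "dataset",
) -> ThresholdTable:
    """Percentage of sequences with Z ≥ t (inclusive) for each threshold.

    Sequences with undefined Z are excluded from both numerator and
    denominator.
    """
    if not results:
        raise ValueError("no results to tabulate")
    if not thresholds:
        raise ValueError("no thresholds given")
    zs = [r.Z for r in results if r.defined]
    if not zs:
        raise ValueError("no sequence has a defined Z-score")
    zs_arr = np.array(zs)
    percentages = tuple(
        round(100.0 * float(np.sum(zs_arr >= t)) / zs_arr.size, 2) for t in thresholds
    )
    return ThresholdTable(
        label=label,
        thresholds=tuple(float(t) for t in thresholds),
        percentages=percentages,
        n_sequences=zs_arr.size,
    )


def _background_for(
    x: RnaSequence,
    mode: str,
    count: int,
    seed: Optional[int],
    background_path,
) -> ShuffleSet:
    if mode == "mono":
        return mono_shuffle(x, count=count, seed=seed)
    if mode == "dinuc":
        return dinucleotide_shuffle(x, count=count, seed=seed)
    if mode == "external":
        if background_path is None:
            raise ValueError("external mode requires a background FASTA")
        return load_background(background_path, x, count=count, seed=seed)
    raise ValueError(f"unknown background mode {mode!r}")


def score_sequence(
    x: RnaSequence,
    params: GrammarParams,
    em: Optional[EmissionModel] = None,
    *,
    mode: str = "dinuc",
    count: int = DEFAULT_SHUFFLE_COUNT,
    seed: Optional[int] = None,
    background_path=None,
    scale: float = DEFAULT_SCALE,
) -> ZScoreResult:
    """Entropy Z-score of one sequence against its background set."""
    background = _background_for(x, mode, count, seed, background_path)
    q_x = entropy_of_sequence(x, params, em, scale=scale).Q
    q_bg = [entropy_of_sequence(m, params, em, scale=scale).Q for m in background.members]
    try:
        ks_p: Optional[float] = ks_normality(q_bg) if len(q_bg) >= 5 else None
    except ValueError:
        ks_p = None
    try:
        return zscore(q_x, q_bg, identifier=x.identifier, n=x.n, ks_pvalue=ks_p)
    except UndefinedZScoreError:
        vals = np.asarray(q_bg)
        return ZScoreResult(
            identifier=x.identifier,
            n=x.n,
            Q_x=q_x,
            mu=float(vals.mean()),
            sigma=0.0,
            Z=None,
            ks_pvalue=ks_p,
            background_size=len(q_bg),
        )


def run_pipeline(
    fasta,
    mode: str = "dinuc",
    count: int = DEFAULT_SHUFFLE_COUNT,
    seed: Optional[int] = None,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    *,
    background_path=None,
    params: Optional[GrammarParams] = None,
    em: Optional[EmissionModel] = None,
    scale: float = DEFAULT_SCALE,
    label: str = "dataset",
) -> Tuple[List[ZScoreResult], ThresholdTable]:
    """End-to-end run: read FASTA, score every valid sequence, tabulate.

    Invalid sequences (non-ACGU symbols) are logged and skipped.  Raises
    :class:`EmptyResultError` when no sequence yields a result.
    """
    from .io import read_fasta

    if em is None:
        em = EmissionModel.default()
    if params is None:
        params = solve_rule_probabilities(em)
    records = read_fasta(fasta)
    rows: List[ZScoreResult] = []
    for rec in records:
        if rec.sequence is None:
            logger.warning(
                "skipping %s: non-ACGU symbol %r", rec.identifier, rec.invalid_symbol
            )
            continue
        logger.info("scoring %s (n=%d)", rec.identifier, rec.sequence.n)
        rows.append(
            score_sequence(
                rec.sequence,
                params,
                em,
                mode=mode,
                count=count,
                seed=seed,
                background_path=background_path,
                scale=scale,
            )
        )
    if not rows:
        raise EmptyResultError("no valid sequences in input")
    table = threshold_table(rows, thresholds, label=label)
    return rows, table
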