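"""FASTA input, TSV output, and run configuration."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

from Bio import SeqIO

from .inside_outside import EntropyResult, PairProbabilityMatrix
from .pipeline import DEFAULT_THRESHOLDS, ThresholdTable, ZScoreResult
from .sequences import InvalidSequenceError, RnaSequence
from .shuffles import DEFAULT_SHUFFLE_COUNT

__all__ = [
    "SequenceRecord",
    "RunConfig",
    "FastaParseError",
    "read_fasta",
    "write_fasta",
    "write_results",
    "write_entropies",
    "write_pair_matrix",
]

logger = logging.getLogger("triple_entropy")


class FastaParseError(ValueError):
    """Malformed FASTA; carries the offending line number."""

    def __init__(self, path, line_number: int, message: str):
        self.line_number = line_number
        super().__init__(f"{path}:{line_number}: {message}")


@dataclass(frozen=True)
class SequenceRecord:
    """A FASTA record: either a valid RNA sequence or a flagged reject."""

    identifier: str
    sequence: Optional[RnaSequence]
    invalid_symbol: Optional[str] = None

    @property
    def is_valid(self) -> bool:
        return self.sequence is not None


@dataclass
class RunConfig:
    """Parameters of one scoring run; defaults follow the standard protocol
    (100 shuffles, dinucleotide mode, Z thresholds 2, 1.5, 1, 0.5)."""

    mode: str = "dinuc"
    count: int = DEFAULT_SHUFFLE_COUNT
    seed: Optional[int] = None
    thresholds: Tuple[float, ...] = DEFAULT_THRESHOLDS
    background: Optional[str] = None
    solver_tol: float = 1e-12
    outdir: Optional[str] = None
    unpaired: Optional[Dict[str, float]] = None
    paired: Optional[Dict[Tuple[str, str], float]] = None

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Parse a plain ``key = value`` configuration file.

        Recognised keys mirror the CLI flags: mode, count, seed,
        thresholds (comma-separated), background, solver_tol, outdir.
        """
        cfg = cls()
        for ln, raw in enumerate(Path(path).read_text().splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{ln}: expected 'key = value'")
            key, value = (s.strip() for s in line.split("=", 1))
            if key == "mode":
                cfg.mode = value
            elif key == "count":
                cfg.count = int(value)
            elif key == "seed":
                cfg.seed = int(value)
            elif key == "thresholds":
                cfg.thresholds = tuple(float(v) for v in value.split(","))
            elif key == "background":
                cfg.background = value
            elif key == "solver_tol":
                cfg.solver_tol = float(value)
            elif key == "outdir":
                cfg.outdir = value
            else:
                raise ValueError(f"{path}:{ln}: unknown key {key!r}")
        return cfg


def read_fasta(path) -> List[SequenceRecord]:
    """Parse FASTA into records, flagging sequences with non-ACGU symbols.

    Case-insensitive; T is mapped to U.  A record containing any other
    symbol is returned with ``sequence=None`` and the offending symbol, so
    callers can log and skip it.  An empty file yields an empty list.
    """
    path = Path(path)
    with open(path) as handle:
        line_number = 0
        for raw in handle:
            line_number += 1
            if raw.strip():
                if not raw.startswith(">"):
                    raise FastaParseError(
                        path, line_number, "expected '>' header before sequence data"
                    )
                break
    records: List[SequenceRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        try:
            seq = RnaSequence.from_string(rec.id, str(rec.seq))
            records.append(SequenceRecord(rec.id, seq))
        except InvalidSequenceError as err:
            records.append(SequenceRecord(rec.id, None, invalid_symbol=err.symbol))
    if not records:
        logger.warning("no records found in %s", path)
    return records


def write_fasta(sequences: Sequence[RnaSequence], path) -> None:
    with open(path, "w") as fh:
        for seq in sequences:
            fh.write(f">{seq.identifier}\n{seq.residues}\n")


def _fmt_z(z: Optional[float]) -> str:
    return "NA" if z is None else f"{z:.4f}"


def write_entropies(results: Sequence[EntropyResult], path) -> None:
    """Per-sequence entropy TSV: id, n, Q, expected pair count."""
    with open(path, "w") as fh:
        fh.write("id\tn\tQ\texpected_pairs\n")
        for r in results:
            fh.write(f"{r.identifier}\t{r.n}\t{r.Q:.6f}\t{r.expected_pairs:.6f}\n")


def write_results(
    rows: Sequence[ZScoreResult],
    table: Optional[ThresholdTable],
    outdir,
) -> List[Path]:
    """Write per-sequence Z-scores and the threshold summary table.

    Deterministic column order and fixed float formats (entropies 6 dp,
    Z 4 dp, percentages 2 dp); rerunning with identical inputs produces
    byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    zpath = outdir / "zscores.tsv"
    with open(zpath, "w") as fh:
        fh.write("id\tn\tQ\tmu\tsigma\tZ\tks_pvalue\tbackground_size\n")
        for r in rows:
            ks = "NA" if r.ks_pvalue is None else f"{r.ks_pvalue:.4f}"
            fh.write(
                f"{r.identifier}\t{r.n}\t{r.Q_x:.6f}\t{r.mu:.6f}\t{r.sigma:.6f}"
                f"\t{_fmt_z(r.Z)}\t{ks}\t{r.background_size}\n"
            )
    written.append(zpath)
    if table is not None:
        spath = outdir / "summary.tsv"
        with open(spath, "w") as fh:
            fh.write("label\t" + "\t".join(f"Z>={t:g}" for t in table.thresholds))
            fh.write("\tn_sequences\n")
            fh.write(
                table.label
                + "\t"
                + "\t".join(f"{p:.2f}" for p in table.percentages)
                + f"\t{table.n_sequences}\n"
            )
        written.append(spath)
    return written


def write_pair_matrix(P: PairProbabilityMatrix, path, square: bool = False) -> None:
    """Sparse (i, j, P_ij) TSV of positive entries, or a full square matrix."""
    with open(path, "w") as fh:
        if square:
            for row in P.matrix:
                fh.write("\t".join(f"{v:.6g}" for v in row) + "\n")
        else:
            fh.write("i\tj\tP_ij\n")
            for i, j, v in P.nonzero_entries():
                fh.write(f"{i}\t{j}\t{v:.6g}\n")
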