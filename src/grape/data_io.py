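"""Interaction-table I/O, dataset summary statistics, and StrictTCR folds.

Input rows are (CDR3β, epitope, label) triples.  Cross-validation uses the
StrictTCR discipline: records are grouped by unique TCR sequence and whole
groups are assigned to folds, so no TCR ever appears in both a training and a
validation fold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The 20 proteinogenic amino acids (one-letter codes).
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)

DEFAULT_COLUMNS = {"tcr": "cdr3b", "epitope": "epitope", "label": "label"}


@dataclass(frozen=True)
class InteractionRecord:
    """One labeled (CDR3β, epitope) pair — the atomic input row."""

    tcr: str
    epitope: str
    label: int
    source: str | None = None

    def __post_init__(self):
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")
        for name in ("tcr", "epitope"):
            seq = getattr(self, name)
            if not is_valid_sequence(seq):
                raise ValueError(f"invalid {name} sequence: {seq!r}")


def is_valid_sequence(seq: str) -> bool:
    """Non-empty, uppercase, strictly over the 20-letter amino-acid alphabet."""
    return isinstance(seq, str) and len(seq) > 0 and set(seq) <= _AA_SET


@dataclass(frozen=True)
class DatasetStats:
    """Summary of a labeled interaction table.

    ``density`` is the interaction density n_pairs / (n_tcr × n_epitope),
    computed over positive pairs only; with per-epitope TCR repertoires this
    is typically in the 1e-3 range for public TCR-epitope databases.
    """

    n_tcr: int
    n_epitope: int
    n_pairs: int
    density: float

    def density_rounded(self, ndigits: int = 4) -> float:
        return round(self.density, ndigits)


def read_interaction_table(
    path,
    fmt: str | None = None,
    columns: dict | None = None,
) -> list[InteractionRecord]:
    """Read a CSV/TSV of (tcr, epitope, label) rows.

    Rows whose sequences fail alphabet validation or whose label is not 0/1
    are dropped and counted in the log.  Raises on a missing file, a missing
    required column, or an empty result after filtering.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    cols = dict(DEFAULT_COLUMNS)
    if columns:
        cols.update(columns)
    if fmt is None:
        fmt = "tsv" if path.suffix.lower() in {".tsv", ".tab"} else "csv"
    if fmt not in {"csv", "tsv"}:
        raise ValueError(f"format must be 'csv' or 'tsv', got {fmt!r}")
    df = pd.read_csv(path, sep="\t" if fmt == "tsv" else ",", dtype=str)
    for key in ("tcr", "epitope", "label"):
        if cols[key] not in df.columns:
            raise ValueError(f"missing required column {cols[key]!r} in {path}")
    has_source = "source" in df.columns
    records, dropped = [], 0
    for row in df.itertuples(index=False):
        tcr = str(getattr(row, cols["tcr"]))
        epi = str(getattr(row, cols["epitope"]))
        lab = str(getattr(row, cols["label"])).strip()
        if not (is_valid_sequence(tcr) and is_valid_sequence(epi) and lab in {"0", "1"}):
            dropped += 1
            continue
        src = str(getattr(row, "source")) if has_source else None
        records.append(InteractionRecord(tcr, epi, int(lab), src))
    if dropped:
        logger.warning("dropped %d invalid rows from %s", dropped, path)
    if not records:
        raise ValueError(f"no valid interaction records in {path}")
    return records


def read_fasta_sequences(path) -> list[str]:
    """Plain sequence list from a FASTA file (via Biopython)."""
    from Bio import SeqIO

    return [str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")]


def deduplicate_records(records) -> tuple[list[InteractionRecord], int]:
    """Collapse duplicate (tcr, epitope) rows.

    Conflicting labels on the same pair resolve to the positive; conflicts
    are counted in the log and returned.
    """
    best: dict[tuple[str, str], InteractionRecord] = {}
    order: list[tuple[str, str]] = []
    conflicts = 0
    for rec in records:
        key = (rec.tcr, rec.epitope)
        if key not in best:
            best[key] = rec
            order.append(key)
        elif best[key].label != rec.label:
            conflicts += 1
            if rec.label == 1:
                best[key] = rec
    if conflicts:
        logger.warning("resolved %d conflicting duplicate pairs (kept positive)", conflicts)
    return [best[k] for k in order], conflicts


def dataset_statistics(records) -> DatasetStats:
    """Unique-sequence counts and interaction density over positive pairs."""
    records = list(records)
    if not records:
        raise ValueError("empty record list")
    tcrs = {r.tcr for r in records}
    epitopes = {r.epitope for r in records}
    pos_pairs = {(r.tcr, r.epitope) for r in records if r.label == 1}
    density = len(pos_pairs) / (len(tcrs) * len(epitopes))
    return DatasetStats(len(tcrs), len(epitopes), len(pos_pairs), density)


@dataclass(frozen=True)
class FoldAssignment:
    """StrictTCR fold map: every unique TCR lives in exactly one fold."""

    assignment: dict = field(repr=False)
    k: int = 5
    seed: int = 0

    def fold_of(self, tcr: str) -> int:
        return self.assignment[tcr]

    def fold_tcrs(self, fold: int) -> set[str]:
        return {t for t, f in self.assignment.items() if f == fold}


def strict_tcr_split(records, k: int = 5, seed: int = 0,
                     extra_tcrs=()) -> FoldAssignment:
    """Group records by unique TCR and deal TCRs round-robin into k folds.

    Unique TCRs are sorted before the seeded permutation, so the assignment
    is invariant to input row order.  Fold sizes (in unique TCRs) differ by
    at most one.  ``extra_tcrs`` (e.g. repertoire TCRs without observed
    interactions that will serve as negative-sampling candidates) join the
    deal so negative edges can never overlap between folds either.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    tcrs = sorted({r.tcr for r in records} | set(extra_tcrs))
    if len(tcrs) < k:
        raise ValueError(f"fewer unique TCRs ({len(tcrs)}) than folds ({k})")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(tcrs))
    assignment = {tcrs[idx]: i % k for i, idx in enumerate(perm)}
    return FoldAssignment(assignment, k=k, seed=seed)


def split_records(records, folds: FoldAssignment, fold: int):
    """Partition records into (train, validation) for one validation fold."""
    train = [r for r in records if folds.fold_of(r.tcr) != fold]
    val = [r for r in records if folds.fold_of(r.tcr) == fold]
    return train, val


def write_fold_assignment(path, folds: FoldAssignment) -> None:
    df = pd.DataFrame(
        sorted(folds.assignment.items()), columns=["cdr3b", "fold"]
    )
    df.to_csv(path, sep="\t", index=False)


def read_fold_assignment(path) -> FoldAssignment:
    df = pd.read_csv(path, sep="\t", dtype={"cdr3b": str, "fold": int})
    assignment = dict(zip(df["cdr3b"], df["fold"]))
    return FoldAssignment(assignment, k=int(df["fold"].max()) + 1, seed=-1)
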