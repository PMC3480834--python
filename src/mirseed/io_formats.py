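"""Readers and writers for the formats the pipeline touches, plus run configuration.

All tabular I/O is TSV with a header row, '.' decimal separator and
deterministic row/column order, so that re-running a stage is byte-reproducible.
Fold-change thresholds are supplied on the linear scale (e.g. 1.1) and
converted to |logFC| >= log2(cutoff) wherever they are applied: the pipeline
works on base-2 log fold changes throughout.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence, Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("mirseed")

_VALID_UTR_CHARS = frozenset("ACGTN")


@dataclass(frozen=True)
class UTRRecord:
    """One 3'UTR sequence, sense strand of the mRNA, 5'->3'.

    The sequence is DNA-normalized (uppercase, U->T) and restricted to
    {A, C, G, T, N}.
    """

    gene_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        if not self.sequence:
            raise ValueError(f"empty sequence for {self.gene_id}")
        bad = set(self.sequence) - _VALID_UTR_CHARS
        if bad:
            pos = next(i for i, c in enumerate(self.sequence) if c in bad)
            raise ValueError(
                f"illegal character {self.sequence[pos]!r} at position {pos} in {self.gene_id}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


def normalize_sequence(seq: str) -> str:
    """Uppercase and convert RNA U to DNA T."""
    return seq.upper().replace("U", "T")


def read_fasta(path: Union[str, Path]) -> list[UTRRecord]:
    """Read a UTR FASTA into records keyed by the first header token.

    Sequences are uppercased with U normalized to T; characters outside
    {A, C, G, T, N} are a hard error, as are duplicate identifiers and
    empty sequences.
    """
    records: list[UTRRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        gene_id = rec.id
        if gene_id in seen:
            raise ValueError(f"duplicate identifier {gene_id}")
        seen.add(gene_id)
        records.append(UTRRecord(gene_id, normalize_sequence(str(rec.seq))))
    return records


def write_fasta(records: Iterable[UTRRecord], path: Union[str, Path]) -> None:
    seqrecs = [
        SeqRecord(Seq(r.sequence), id=r.gene_id, description="") for r in records
    ]
    SeqIO.write(seqrecs, str(path), "fasta")


def read_foldchange_table(path: Union[str, Path]) -> pd.DataFrame:
    """Read a gene-level fold-change TSV with `gene_id` and `logFC` columns.

    Rows whose logFC is missing or non-numeric are dropped with a logged
    count. Duplicate gene identifiers are a hard error.
    """
    df = pd.read_csv(path, sep="\t")
    missing = {"gene_id", "logFC"} - set(df.columns)
    if missing:
        raise ValueError(
            f"missing column(s) {sorted(missing)}; found columns {list(df.columns)}"
        )
    if df.empty:
        logger.warning("fold-change table %s has no data rows", path)
        return pd.DataFrame({"gene_id": pd.Series(dtype=str), "logFC": pd.Series(dtype=float)})
    df = df[["gene_id", "logFC"]].copy()
    df["logFC"] = pd.to_numeric(df["logFC"], errors="coerce")
    keep = df["logFC"].notna() & df["logFC"].apply(math.isfinite)
    n_bad = int((~keep).sum())
    df = df[keep]
    if n_bad:
        logger.warning("dropped %d rows with missing/non-numeric logFC", n_bad)
    df["gene_id"] = df["gene_id"].astype(str)
    dup = df["gene_id"].duplicated()
    if dup.any():
        raise ValueError(f"duplicate gene_id {df['gene_id'][dup].iloc[0]}")
    return df.reset_index(drop=True)


def read_expression_matrix(path: Union[str, Path]) -> pd.DataFrame:
    """Read a gene x array matrix of log2 intensities, indexed by gene_id."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] < 2:
        raise ValueError("expression matrix needs at least 2 array columns")
    if df.index.duplicated().any():
        raise ValueError("duplicate gene_id in expression matrix")
    return df


def write_table(rows: pd.DataFrame, path: Union[str, Path], sort_by: Union[str, Sequence[str], None] = None) -> None:
    """Write a result table as TSV with deterministic row and column order."""
    df = rows.copy()
    if sort_by is not None:
        df = df.sort_values(list(sort_by) if not isinstance(sort_by, str) else [sort_by], kind="mergesort")
    df.to_csv(path, sep="\t", index=False)


@dataclass
class AnalysisConfig:
    """Run configuration shared across pipeline stages.

    fc_cutoff is a linear fold change (> 1); gene-set thresholds use
    |logFC| >= log2(fc_cutoff). variance_cutoff applies to the per-gene
    sample variance of log2 expression across arrays. nochange_size is an
    integer or "match-down" (no-change set sized to the down set).
    """

    fc_cutoff: float = 1.1
    variance_cutoff: float = 0.25
    k: int = 7
    n_permutations: int = 100
    rng_seed: int = 17
    nochange_size: Union[int, str] = "match-down"
    mutual_exclusivity: bool = True

    def __post_init__(self) -> None:
        if self.fc_cutoff <= 1:
            raise ValueError("fc_cutoff must be > 1 (linear fold change)")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if isinstance(self.nochange_size, str) and self.nochange_size != "match-down":
            raise ValueError('nochange_size must be an integer or "match-down"')

    @property
    def logfc_threshold(self) -> float:
        return math.log2(self.fc_cutoff)

    def to_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "AnalysisConfig":
        return cls(**json.loads(Path(path).read_text()))
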