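"""Variance-based non-specific filtering and up / down / no-change partitioning.

Fold changes are base-2 logs; the partition threshold is a linear fold
change converted to |logFC| >= log2(fc_cutoff) (inclusive on both sides).
The no-change set emulates "genes with logFC centered on 0": the genes
nearest zero in |logFC| among those assigned to neither tail, with ties
broken lexicographically by gene identifier so the partition is
deterministic. Its size defaults to the size of the down set, making the
down-vs-no-change comparison size-balanced.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .io_formats import AnalysisConfig, logger


@dataclass(frozen=True)
class GeneSets:
    up: frozenset[str]
    down: frozenset[str]
    nochange: frozenset[str]
    mean_logfc: dict[str, float]

    def membership_table(self, fc: pd.DataFrame) -> pd.DataFrame:
        """gene_id, logFC, set label (up/down/nochange/unassigned), sorted by gene_id."""
        def label(g: str) -> str:
            if g in self.up:
                return "up"
            if g in self.down:
                return "down"
            if g in self.nochange:
                return "nochange"
            return "unassigned"

        out = fc.copy()
        out["set"] = out["gene_id"].map(label)
        return out.sort_values("gene_id", kind="mergesort").reset_index(drop=True)


def variance_filter(expr: pd.DataFrame, variance_cutoff: float, quantile: bool = False) -> set[str]:
    """Genes whose log2-expression sample variance across arrays passes the cutoff.

    Default reading: retain variance >= variance_cutoff (absolute threshold,
    denominator n-1). With ``quantile=True`` the cutoff is instead the
    quantile of the variance distribution below which genes are removed
    (e.g. 0.25 removes the least-variable quarter).
    """
    if expr.shape[1] < 2:
        raise ValueError("variance filter needs at least 2 arrays")
    var = expr.var(axis=1, ddof=1)
    if quantile:
        threshold = float(var.quantile(variance_cutoff))
        return set(var.index[var >= threshold].astype(str))
    return set(var.index[var >= variance_cutoff].astype(str))


def define_gene_sets(fc: pd.DataFrame, config: AnalysisConfig) -> GeneSets:
    """Partition a fold-change table into disjoint up / down / no-change sets."""
    if fc.empty:
        raise ValueError("empty fold-change table")
    t = config.logfc_threshold
    logfc = fc.set_index("gene_id")["logFC"]
    down = set(logfc.index[logfc <= -t])
    up = set(logfc.index[logfc >= t])
    if not down or not up:
        logger.warning("empty %s set at fc_cutoff %.3g", "down" if not down else "up", config.fc_cutoff)

    rest = logfc.drop(index=list(down | up))
    n_nc = len(down) if config.nochange_size == "match-down" else int(config.nochange_size)
    order = sorted(rest.index, key=lambda g: (abs(rest[g]), g))
    nochange = set(order[:n_nc])

    def mean_of(members: set[str]) -> float:
        return float(logfc.loc[sorted(members)].mean()) if members else float("nan")

    return GeneSets(
        up=frozenset(up),
        down=frozenset(down),
        nochange=frozenset(nochange),
        mean_logfc={"up": mean_of(up), "down": mean_of(down), "nochange": mean_of(nochange)},
    )
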