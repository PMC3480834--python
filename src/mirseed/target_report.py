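"""Candidate-target reporting and miRNA-mRNA expression anti-correlation.

A candidate target is a gene in the down-regulated set carrying at least
one 7mer-m8, 7mer-1A or 8mer seed site in its 3'UTR. The correlation
operation tests whether a miRNA's expression is negatively associated with
a putative target's expression across tumor samples (Pearson r with the
exact t-transform p-value).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .gene_sets import GeneSets
from .seed_model import COMBINED_7_8, SiteCounts


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_value: float
    n: int


def candidate_targets(
    sets: GeneSets,
    site_counts: Mapping[str, SiteCounts],
    fc: pd.DataFrame,
) -> pd.DataFrame:
    """Down-regulated genes with >= 1 site of class 7mer-m8, 7mer-1A or 8mer.

    Returns a table sorted ascending by logFC (strongest down-regulation
    first) with per-class site counts and the strongest class present.
    """
    logfc = fc.set_index("gene_id")["logFC"]
    rows = []
    for g in sorted(sets.down):
        sc = site_counts.get(g)
        if sc is None:
            raise KeyError(f"no site counts for gene {g}")
        if not any(sc.count(cls) >= 1 for cls in COMBINED_7_8):
            continue
        rows.append(
            {
                "gene_id": g,
                "logFC": float(logfc[g]),
                "n_8mer": sc.n_8mer,
                "n_7mer_m8": sc.n_7mer_m8,
                "n_7mer_1a": sc.n_7mer_1a,
                "n_6mer": sc.n_6mer,
                "best_class": sc.best_class,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["gene_id", "logFC", "n_8mer", "n_7mer_m8", "n_7mer_1a", "n_6mer", "best_class"],
    )
    return df.sort_values(["logFC", "gene_id"], kind="mergesort").reset_index(drop=True)


def pearson_correlation(
    x: Sequence[float],
    y: Sequence[float],
    permutation: bool = False,
    n_permutations: int = 10000,
    rng_seed: int = 17,
) -> CorrelationResult:
    """Sample Pearson r with a two-sided p-value.

    The default p comes from the exact transform t = r*sqrt(n-2)/sqrt(1-r^2)
    on n-2 degrees of freedom; ``permutation=True`` instead estimates p by
    shuffling one vector.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {len(x)} vs {len(y)}")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 samples")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("zero variance in an input vector")
    res = stats.pearsonr(x, y)
    r = float(res.statistic)
    if permutation:
        rng = np.random.default_rng(rng_seed)
        null = np.array(
            [stats.pearsonr(x, rng.permutation(y)).statistic for _ in range(n_permutations)]
        )
        p = float((1 + (np.abs(null) >= abs(r)).sum()) / (n_permutations + 1))
    else:
        p = float(res.pvalue)
    return CorrelationResult(r=r, p_value=p, n=n)
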