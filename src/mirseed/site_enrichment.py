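"""Seed-site enrichment statistics between gene sets.

Three counting modes are provided for comparing site content between the
down-regulated set and the up / no-change sets:

* gene-fraction — fraction of genes in each set carrying >= 1 site of a
  class, compared by Fisher's exact test (two-sided, minimum-likelihood
  rule); this is the primary mode.
* size-corrected-occurrence — mean total occurrences per set after
  repeatedly subsampling every set to the smallest set's size, with
  percentile resampling intervals (descriptive; no p-value).
* per-kb — total occurrences per kilobase of UTR sequence in each set
  (descriptive; no p-value).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency, hypergeom

from .gene_sets import GeneSets
from .io_formats import UTRRecord
from .seed_model import COMBINED_7_8, SITE_CLASSES, SiteCounts

#: pooled category label: a gene counts as a carrier if it has any
#: 7mer-m8, 7mer-1A or 8mer site
COMBINED_LABEL = "combined-7/7A/8"

ENRICHMENT_CLASSES = SITE_CLASSES + (COMBINED_LABEL,)

# relative slack on the "point probability <= observed" comparison in the
# two-sided sum, guarding against floating-point ties
_REL_TOL = 1e-7


@dataclass(frozen=True)
class EnrichmentResult:
    site_class: str
    comparison: str  # "down-vs-up" or "down-vs-nochange"
    method: str
    a_with: int
    a_without: int
    b_with: int
    b_without: int
    statistic: float  # fraction difference (set A minus set B)
    p_value: float


@lru_cache(maxsize=65536)
def _hypergeom_pmf(n: int, r1: int, c1: int, lo: int, hi: int) -> tuple:
    return tuple(hypergeom.pmf(np.arange(lo, hi + 1), n, r1, c1))


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]].

    Sums hypergeometric point probabilities (margins fixed) over all tables
    whose probability is <= that of the observed table, with relative slack
    1e-7 on the comparison.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        raise ValueError("Fisher test undefined with an empty margin")
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    pmf = np.array(_hypergeom_pmf(n, r1, c1, lo, hi))
    p_obs = pmf[a - lo]
    mask = pmf <= p_obs * (1 + _REL_TOL)
    if mask.all():  # the observed table is the mode: the sum is exactly 1
        return 1.0
    return min(float(pmf[mask].sum()), 1.0)


def chi2_with_continuity(a: int, b: int, c: int, d: int) -> float:
    """Chi-squared test with Yates continuity correction (alternative to Fisher)."""
    _, p, _, _ = chi2_contingency(np.array([[a, b], [c, d]]), correction=True)
    return float(p)


def _has_site(sc: SiteCounts, site_class: str) -> bool:
    if site_class == COMBINED_LABEL:
        return any(sc.count(cls) >= 1 for cls in COMBINED_7_8)
    return sc.count(site_class) >= 1


def _occurrences(sc: SiteCounts, site_class: str) -> int:
    if site_class == COMBINED_LABEL:
        return sum(sc.count(cls) for cls in COMBINED_7_8)
    return sc.count(site_class)


def _carriers(members: Iterable[str], site_counts: Mapping[str, SiteCounts], site_class: str) -> tuple[int, int]:
    with_ = without = 0
    for g in members:
        if g not in site_counts:
            raise KeyError(f"no site counts for gene {g}")
        if _has_site(site_counts[g], site_class):
            with_ += 1
        else:
            without += 1
    return with_, without


def gene_fraction_enrichment(
    sets: GeneSets,
    site_counts: Mapping[str, SiteCounts],
    site_class: str,
    use_chi2: bool = False,
) -> list[EnrichmentResult]:
    """Fraction-of-genes-with-site comparison, down vs up and down vs no-change."""
    test = chi2_with_continuity if use_chi2 else fisher_exact_two_sided
    results = []
    a_with, a_without = _carriers(sorted(sets.down), site_counts, site_class)
    for comparison, other in (("down-vs-up", sets.up), ("down-vs-nochange", sets.nochange)):
        b_with, b_without = _carriers(sorted(other), site_counts, site_class)
        frac_a = a_with / (a_with + a_without) if (a_with + a_without) else float("nan")
        frac_b = b_with / (b_with + b_without) if (b_with + b_without) else float("nan")
        p = test(a_with, a_without, b_with, b_without)
        results.append(
            EnrichmentResult(
                site_class=site_class,
                comparison=comparison,
                method="gene-fraction",
                a_with=a_with,
                a_without=a_without,
                b_with=b_with,
                b_without=b_without,
                statistic=frac_a - frac_b,
                p_value=p,
            )
        )
    return results


def size_corrected_occurrences(
    sets: GeneSets,
    site_counts: Mapping[str, SiteCounts],
    site_class: str,
    n_resamples: int = 1000,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Mean total occurrences per set after subsampling all sets to equal size.

    Each of the three sets is repeatedly subsampled without replacement to
    the smallest set's size; the table reports the mean and percentile
    2.5/97.5 bounds of the per-subsample total occurrence count.
    """
    groups = {"up": sorted(sets.up), "down": sorted(sets.down), "nochange": sorted(sets.nochange)}
    if any(len(g) == 0 for g in groups.values()):
        raise ValueError("all three sets must be non-empty for size correction")
    m = min(len(g) for g in groups.values())
    rng = np.random.default_rng(rng_seed)
    rows = []
    for name, members in groups.items():
        occ = np.array([_occurrences(site_counts[g], site_class) for g in members], dtype=float)
        if len(members) == m:
            totals = np.full(n_resamples, occ.sum())
        else:
            totals = np.array(
                [occ[rng.choice(len(occ), size=m, replace=False)].sum() for _ in range(n_resamples)]
            )
        rows.append(
            {
                "set": name,
                "site_class": site_class,
                "subsample_size": m,
                "mean_occurrences": float(totals.mean()),
                "ci_low": float(np.percentile(totals, 2.5)),
                "ci_high": float(np.percentile(totals, 97.5)),
            }
        )
    return pd.DataFrame(rows)


def per_kb_density(
    members: Iterable[str],
    utrs: Sequence[UTRRecord],
    site_counts: Mapping[str, SiteCounts],
    site_class: str,
) -> float:
    """Site occurrences per kb of total UTR sequence in a gene set."""
    members = sorted(members)
    if not members:
        raise ValueError("empty gene set")
    lengths = {u.gene_id: u.length for u in utrs}
    total_nt = sum(lengths[g] for g in members)
    if total_nt == 0:
        raise ValueError("zero total UTR length")
    total_occ = sum(_occurrences(site_counts[g], site_class) for g in members)
    return 1000.0 * total_occ / total_nt


def enrichment_table(results: Iterable[EnrichmentResult]) -> pd.DataFrame:
    df = pd.DataFrame([r.__dict__ for r in results])
    return df.sort_values(["site_class", "comparison"], kind="mergesort").reset_index(drop=True)
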