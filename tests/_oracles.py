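"""Independent brute-force oracles used only by the tests.

These deliberately avoid the package's own code paths: naive sliding-window
matching, exact-fraction hypergeometric enumeration, and plain cumulative
sums, so that agreement with the implementation is evidence rather than
tautology.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np

STRENGTH_ORDER = ("8mer", "7mer-m8", "7mer-1A", "6mer")

# same slack the implementation contract states for the two-sided sum
_TOL = Fraction(10**7 + 1, 10**7)


def naive_site_scan(seq: str, sites, exclusive: bool) -> dict[str, int]:
    """Window-by-window site scan with explicit hierarchy resolution."""
    counts = {cls: 0 for cls in STRENGTH_ORDER}
    if not exclusive:
        for cls in STRENGTH_ORDER:
            site = sites.site(cls)
            counts[cls] = sum(
                1 for i in range(len(seq) - len(site) + 1) if seq[i : i + len(site)] == site
            )
        return counts
    core = sites.site("6mer")
    for i in range(len(seq) - 5):
        if seq[i : i + 6] != core:
            continue
        assigned = None
        for cls in STRENGTH_ORDER:
            site = sites.site(cls)
            # site start offset relative to the core occurrence
            start = i - (1 if cls in ("8mer", "7mer-m8") else 0)
            if start < 0 or start + len(site) > len(seq):
                continue
            if seq[start : start + len(site)] == site:
                assigned = cls
                break
        counts[assigned or "6mer"] += 1
    return counts


def fisher_two_sided_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Exact-fraction two-sided Fisher p by full enumeration of the support."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = comb(n, c1)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    masses = {k: Fraction(comb(r1, k) * comb(r2, c1 - k), denom) for k in range(lo, hi + 1)}
    p_obs = masses[a]
    return float(sum(m for m in masses.values() if m <= p_obs * _TOL))


def naive_kmer_counts(seq: str, k: int) -> dict[str, int]:
    """Overlapping k-mer counts; windows with non-ACGT characters skipped."""
    out: dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        w = seq[i : i + k]
        if set(w) <= set("ACGT"):
            out[w] = out.get(w, 0) + 1
    return out


def brute_running_sum(counts, lengths):
    """Cumulative sum of mean-centered rates, computed with plain Python floats."""
    rates = [x / l for x, l in zip(counts, lengths)]
    mean = sum(rates) / len(rates)
    profile, acc = [], 0.0
    for r in rates:
        acc += r - mean
        profile.append(acc)
    d = max(max(profile), 0.0)
    return np.array(profile), d
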