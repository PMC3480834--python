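"""Canonical miRNA seed-site construction and 3'UTR scanning.

The seed region is nucleotides 2-8 of the mature miRNA (5'->3'); a seed
site is the reverse complement of (a part of) the seed, found on the
sense strand of an mRNA 3'UTR. The four canonical site classes are

    6mer      reverse complement of miRNA positions 2-7
    7mer-m8   reverse complement of positions 2-8
    7mer-1A   the 6mer followed by a literal A on the mRNA
    8mer      the 7mer-m8 followed by that A

so every site contains the 6mer "core", optionally extended by one
matching base on either side. Under mutually exclusive counting each
genomic occurrence of the core is attributed to the single strongest class
whose full context matches at that locus (8mer > 7mer-m8 > 7mer-1A > 6mer).
"""

from __future__ import annotations

from dataclasses import dataclass

from .io_formats import UTRRecord, normalize_sequence

SITE_CLASSES = ("8mer", "7mer-m8", "7mer-1A", "6mer")
"""Site classes in decreasing strength order."""

COMBINED_7_8 = ("7mer-m8", "7mer-1A", "8mer")
"""The classes pooled in the combined 7/7A/8 category."""

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string over {A, C, G, T, N}."""
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"cannot reverse-complement characters {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MatureMiRNA:
    """A named mature miRNA sequence, 5'->3', DNA-normalized on construction."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", normalize_sequence(self.sequence))
        bad = set(self.sequence) - set("ACGT")
        if bad:
            raise ValueError(f"miRNA {self.name}: invalid characters {sorted(bad)}")
        if len(self.sequence) < 9:
            raise ValueError(f"miRNA {self.name}: sequence shorter than 9 nt")


@dataclass(frozen=True)
class SeedSiteSet:
    """The four canonical site strings for one miRNA."""

    site_6mer: str
    site_7mer_m8: str
    site_7mer_1a: str
    site_8mer: str

    def site(self, site_class: str) -> str:
        return {
            "6mer": self.site_6mer,
            "7mer-m8": self.site_7mer_m8,
            "7mer-1A": self.site_7mer_1a,
            "8mer": self.site_8mer,
        }[site_class]

    @property
    def core(self) -> str:
        """The 6mer core shared by all four site classes."""
        return self.site_6mer

    @property
    def m8_base(self) -> str:
        """The mRNA base pairing miRNA position 8 (prefix of 7mer-m8/8mer)."""
        return self.site_7mer_m8[0]


def derive_seed_sites(mirna: MatureMiRNA) -> SeedSiteSet:
    """Construct the canonical site strings from a mature miRNA sequence.

    The appended A of the 7mer-1A and 8mer classes is a literal adenosine
    on the mRNA opposite miRNA position 1, regardless of what position 1 is.
    """
    if len(mirna.sequence) < 8:
        raise ValueError("need at least 8 nt to derive seed sites")
    core = reverse_complement(mirna.sequence[1:7])  # positions 2-7
    m8 = reverse_complement(mirna.sequence[1:8])  # positions 2-8
    return SeedSiteSet(
        site_6mer=core,
        site_7mer_m8=m8,
        site_7mer_1a=core + "A",
        site_8mer=m8 + "A",
    )


@dataclass(frozen=True)
class SiteCounts:
    """Per-gene occurrence counts by site class plus the strongest class present."""

    gene_id: str
    n_8mer: int
    n_7mer_m8: int
    n_7mer_1a: int
    n_6mer: int

    def count(self, site_class: str) -> int:
        return {
            "8mer": self.n_8mer,
            "7mer-m8": self.n_7mer_m8,
            "7mer-1A": self.n_7mer_1a,
            "6mer": self.n_6mer,
        }[site_class]

    @property
    def best_class(self) -> str:
        for cls in SITE_CLASSES:
            if self.count(cls) > 0:
                return cls
        return "none"

    @property
    def total(self) -> int:
        return self.n_8mer + self.n_7mer_m8 + self.n_7mer_1a + self.n_6mer


def _find_all(haystack: str, needle: str) -> list[int]:
    """Start offsets of every (overlapping) occurrence of needle."""
    hits = []
    i = haystack.find(needle)
    while i != -1:
        hits.append(i)
        i = haystack.find(needle, i + 1)
    return hits


def scan_utr(utr: UTRRecord, sites: SeedSiteSet, mutual_exclusivity: bool = True) -> SiteCounts:
    """Count seed-site occurrences in one UTR.

    With ``mutual_exclusivity`` (the default), every occurrence of the 6mer
    core is assigned to exactly one class: the strongest whose full context
    matches at that locus. Overlapping core occurrences each count. With
    exclusivity off, each class is counted as an independent substring.
    Windows containing N never match (the core cannot contain N, and an N
    in a flanking position simply fails the flank comparison).
    """
    seq = utr.sequence
    if not mutual_exclusivity:
        return SiteCounts(
            gene_id=utr.gene_id,
            n_8mer=len(_find_all(seq, sites.site_8mer)),
            n_7mer_m8=len(_find_all(seq, sites.site_7mer_m8)),
            n_7mer_1a=len(_find_all(seq, sites.site_7mer_1a)),
            n_6mer=len(_find_all(seq, sites.site_6mer)),
        )
    counts = {cls: 0 for cls in SITE_CLASSES}
    m8 = sites.m8_base
    for i in _find_all(seq, sites.core):
        has_m8 = i > 0 and seq[i - 1] == m8
        has_a1 = i + 6 < len(seq) and seq[i + 6] == "A"
        if has_m8 and has_a1:
            counts["8mer"] += 1
        elif has_m8:
            counts["7mer-m8"] += 1
        elif has_a1:
            counts["7mer-1A"] += 1
        else:
            counts["6mer"] += 1
    return SiteCounts(
        gene_id=utr.gene_id,
        n_8mer=counts["8mer"],
        n_7mer_m8=counts["7mer-m8"],
        n_7mer_1a=counts["7mer-1A"],
        n_6mer=counts["6mer"],
    )


def scan_utrs(utrs, sites: SeedSiteSet, mutual_exclusivity: bool = True) -> dict[str, SiteCounts]:
    """Scan a UTR collection; returns gene_id -> SiteCounts."""
    return {u.gene_id: scan_utr(u, sites, mutual_exclusivity) for u in utrs}
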