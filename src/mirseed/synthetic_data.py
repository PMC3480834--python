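"""Synthetic fixtures emulating the statistical structure of the assay.

The generator reproduces, stage by stage, what the analysis assumes about
real data: a collection of 3'UTRs in which a fraction of genes carry a
planted seed-site word; a fold-change table in which carriers are shifted
down by a mean effect ``delta`` on top of Gaussian noise; a replicate
expression matrix with a two-component variance mixture (substrate for the
non-specific variance filter); and bivariate sample-level expression with a
target Pearson correlation.

Each stage draws from its own deterministic child of the scenario seed, so
any stage can be regenerated independently and the whole scenario is
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd

from .io_formats import UTRRecord

_STAGES = ("utrs", "plant", "logfc", "expr", "pairs")

# miR-143 8mer seed site: the default planted word
DEFAULT_PLANTED_WORD = "TCATCTCA"


@dataclass(frozen=True)
class ScenarioConfig:
    """Scenario parameters; defaults emulate the study conditions.

    delta is the mean extra down-shift (in logFC units) of seed-carrying
    genes; sigma the logFC noise sd; rho the target miRNA-mRNA sample
    correlation; n_arrays is per condition (treated and mock each get
    n_arrays replicate arrays).
    """

    n_genes: int = 1000
    utr_length_mean: float = 800.0
    utr_length_sd: float = 400.0
    gc_content: float = 0.45
    carrier_fraction: float = 0.3
    planted_word: str = DEFAULT_PLANTED_WORD
    delta: float = 0.25
    sigma: float = 0.3
    n_arrays: int = 4
    var_low: float = 0.05
    var_high: float = 0.6
    high_var_fraction: float = 0.3
    rho: float = -0.22
    n_samples: int = 184
    rng_seed: int = 17

    def __post_init__(self) -> None:
        if not 0 <= self.carrier_fraction <= 1:
            raise ValueError("carrier_fraction must be in [0, 1]")
        if not 0 <= self.gc_content <= 1:
            raise ValueError("gc_content must be in [0, 1]")
        if self.sigma <= 0 or self.utr_length_sd <= 0:
            raise ValueError("sd parameters must be positive")
        if not abs(self.rho) < 1:
            raise ValueError("|rho| must be < 1")
        if set(self.planted_word) - set("ACGT"):
            raise ValueError("planted_word must be over {A,C,G,T}")


def _stage_rng(config: ScenarioConfig, stage: str) -> np.random.Generator:
    children = np.random.SeedSequence(config.rng_seed).spawn(len(_STAGES))
    return np.random.default_rng(children[_STAGES.index(stage)])


def simulate_utrs(config: ScenarioConfig) -> list[UTRRecord]:
    """I.i.d.-base UTRs at the configured GC, log-normal lengths.

    Lengths are drawn from the log-normal with the configured mean and sd
    (moment-matched), clamped to at least the planted word's length.
    Background occurrences of the planted word are left in place.
    """
    rng = _stage_rng(config, "utrs")
    m, s = config.utr_length_mean, config.utr_length_sd
    sigma2 = np.log1p(s**2 / m**2)
    mu = np.log(m) - sigma2 / 2
    lengths = np.maximum(
        np.round(rng.lognormal(mu, np.sqrt(sigma2), config.n_genes)).astype(np.int64),
        len(config.planted_word),
    )
    gc = config.gc_content
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    draws = rng.choice(4, size=int(lengths.sum()), p=p)
    chars = np.frombuffer(b"ACGT", dtype=np.uint8)[draws]
    width = len(str(config.n_genes))
    records = []
    pos = 0
    for i, length in enumerate(lengths):
        seq = chars[pos : pos + length].tobytes().decode("ascii")
        records.append(UTRRecord(f"g{i + 1:0{width}d}", seq))
        pos += length
    return records


def plant_word(
    utrs: list[UTRRecord], config: ScenarioConfig
) -> tuple[list[UTRRecord], np.ndarray]:
    """Write one copy of the planted word into a random carrier subset.

    Carriers are a uniformly chosen subset of size
    round(carrier_fraction * n); the word overwrites existing bases at a
    uniform valid offset. Returns the modified collection and the boolean
    carrier flags aligned with the input order.
    """
    rng = _stage_rng(config, "plant")
    n = len(utrs)
    word = config.planted_word
    n_carriers = int(round(config.carrier_fraction * n))
    flags = np.zeros(n, dtype=bool)
    if n_carriers:
        carriers = rng.choice(n, size=n_carriers, replace=False)
        flags[carriers] = True
    out = []
    for i, rec in enumerate(utrs):
        if not flags[i]:
            out.append(rec)
            continue
        if len(rec.sequence) < len(word):
            raise ValueError(f"sequence {rec.gene_id} shorter than planted word")
        offset = int(rng.integers(0, len(rec.sequence) - len(word) + 1))
        seq = rec.sequence[:offset] + word + rec.sequence[offset + len(word) :]
        out.append(UTRRecord(rec.gene_id, seq))
    return out, flags


def simulate_logfc(carrier_flags: np.ndarray, config: ScenarioConfig) -> pd.DataFrame:
    """logFC_i = -delta * carrier_i + Normal(0, sigma^2) noise."""
    rng = _stage_rng(config, "logfc")
    n = len(carrier_flags)
    logfc = -config.delta * carrier_flags.astype(float) + rng.normal(0, config.sigma, n)
    width = len(str(config.n_genes))
    return pd.DataFrame(
        {"gene_id": [f"g{i + 1:0{width}d}" for i in range(n)], "logFC": logfc}
    )


def simulate_expression_matrix(
    config: ScenarioConfig,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Replicate-array log2 intensities with a two-component variance mixture.

    A ``high_var_fraction`` of genes gets per-array noise variance
    ``var_high`` (above the filter cutoff), the rest ``var_low``. Columns
    are treated_1..n / mock_1..n. Returns (matrix, high-variance flags).
    """
    rng = _stage_rng(config, "expr")
    n = config.n_genes
    n_cols = 2 * config.n_arrays
    high = rng.random(n) < config.high_var_fraction
    sd = np.where(high, np.sqrt(config.var_high), np.sqrt(config.var_low))
    baseline = rng.normal(7.0, 1.5, n)
    values = baseline[:, None] + rng.normal(0, 1, (n, n_cols)) * sd[:, None]
    width = len(str(config.n_genes))
    cols = [f"treated_{j + 1}" for j in range(config.n_arrays)] + [
        f"mock_{j + 1}" for j in range(config.n_arrays)
    ]
    df = pd.DataFrame(values, columns=cols)
    df.index = [f"g{i + 1:0{width}d}" for i in range(n)]
    df.index.name = "gene_id"
    return df, high


def simulate_paired_samples(config: ScenarioConfig) -> tuple[np.ndarray, np.ndarray]:
    """Bivariate-normal (miRNA, mRNA) sample vectors with correlation rho."""
    rng = _stage_rng(config, "pairs")
    z = rng.normal(size=(config.n_samples, 2))
    x = z[:, 0]
    y = config.rho * z[:, 0] + np.sqrt(1 - config.rho**2) * z[:, 1]
    return x, y


@dataclass(frozen=True)
class Scenario:
    """All stage outputs of one simulated study."""

    config: ScenarioConfig
    utrs: list[UTRRecord]
    carrier_flags: np.ndarray
    fc: pd.DataFrame
    expr: pd.DataFrame
    high_var_flags: np.ndarray
    mirna_expression: np.ndarray
    mrna_expression: np.ndarray

    @property
    def truth(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": [u.gene_id for u in self.utrs],
                "carrier": self.carrier_flags.astype(int),
            }
        )


def simulate_scenario(config: Optional[ScenarioConfig] = None, **overrides) -> Scenario:
    """Generate a full scenario (UTRs with planted sites, logFC, arrays, pairs)."""
    if config is None:
        config = ScenarioConfig(**overrides)
    elif overrides:
        config = replace(config, **overrides)
    utrs, flags = plant_word(simulate_utrs(config), config)
    fc = simulate_logfc(flags, config)
    expr, high = simulate_expression_matrix(config)
    x, y = simulate_paired_samples(config)
    return Scenario(
        config=config,
        utrs=utrs,
        carrier_flags=flags,
        fc=fc,
        expr=expr,
        high_var_flags=high,
        mirna_expression=x,
        mrna_expression=y,
    )
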