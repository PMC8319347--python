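"""Parallel-evolution G-scores with a randomization null.

For each gene *i* with observed nonsynonymous mutation count ``O_i`` and a
length-proportional expectation ``E_i = N * L_i / sum_j L_j`` the
goodness-of-fit score is

    G_i = 2 * O_i * ln(O_i / E_i)        (G_i = 0 when O_i = 0)

and the genome-wide parallelism statistic is the total ``G = sum_i G_i``.
The null distribution of the total is obtained by re-placing the observed
number of mutations uniformly along the genome (gene hit probability
proportional to gene length; hits landing in intergenic sequence score 0)
and the departure from the null is summarized as a Z-score
``(G_obs - mu_G) / sigma_G``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .variant_filtering import MutationCall

__all__ = [
    "GeneCatalog",
    "GScoreReport",
    "gene_gscore",
    "observed_gscores",
    "expected_gscore_null",
    "parallelism_zscore",
    "gscore_analysis",
]

#: Annotation terms counted as nonsynonymous (function-affecting).
NONSYNONYMOUS_TERMS = frozenset(
    {
        "frameshift",
        "stop_gained",
        "stop_lost",
        "start_gained",
        "start_lost",
        "codon_deletion",
        "codon_insertion_or_change",
        "nonsynonymous_coding",
        "nonsynonymous_start",
    }
)


@dataclass(frozen=True)
class GeneCatalog:
    """Gene lengths plus the total genome length.

    ``genome_length`` may exceed the summed gene length; the difference is
    treated as intergenic sequence by the randomization null.
    """

    gene_ids: tuple[str, ...]
    lengths: np.ndarray  # bp, same order as gene_ids
    genome_length: int

    def __post_init__(self) -> None:
        lengths = np.asarray(self.lengths, dtype=float)
        object.__setattr__(self, "lengths", lengths)
        if len(self.gene_ids) != len(lengths):
            raise ValueError("gene_ids and lengths must have equal length")
        if len(lengths) == 0:
            raise ValueError("empty gene catalog")
        if np.any(lengths <= 0):
            raise ValueError("gene lengths must be positive")
        if lengths.sum() > self.genome_length:
            raise ValueError("sum of gene lengths exceeds genome length")

    @property
    def total_gene_length(self) -> float:
        return float(self.lengths.sum())

    @property
    def intergenic_fraction(self) -> float:
        return 1.0 - self.total_gene_length / self.genome_length

    def index_of(self, gene_id: str) -> int:
        try:
            return self.gene_ids.index(gene_id)
        except ValueError:
            raise KeyError(gene_id) from None

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame({"gene": self.gene_ids, "length": self.lengths.astype(int)})
        df["genome_length"] = int(self.genome_length)
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GeneCatalog":
        df = pd.read_csv(path, sep="\t")
        return cls(
            gene_ids=tuple(df["gene"].astype(str)),
            lengths=df["length"].to_numpy(dtype=float),
            genome_length=int(df["genome_length"].iloc[0]),
        )


@dataclass
class GScoreReport:
    """Observed and null G-score summary for one organism."""

    gene_ids: tuple[str, ...]
    observed: np.ndarray          # O_i
    expected: np.ndarray          # E_i
    gscores: np.ndarray           # G_i
    total: float                  # G_obs = sum_i G_i
    n_mutations: int              # N used for E_i
    n_intergenic_excluded: int = 0
    null_mean: float | None = None
    null_sd: float | None = None
    n_sims: int = 0
    zscore: float | None = None

    def per_gene_table(self) -> pd.DataFrame:
        """Per-gene table sorted by descending G_i."""
        df = pd.DataFrame(
            {
                "gene": self.gene_ids,
                "observed": self.observed,
                "expected": self.expected,
                "gscore": self.gscores,
            }
        )
        return df.sort_values("gscore", ascending=False, ignore_index=True)


def gene_gscore(O: float, E: float) -> float:
    """G = 2 * O * ln(O / E), with the limit convention G = 0 at O = 0."""
    if E <= 0:
        raise ValueError("expected count must be positive")
    if O < 0:
        raise ValueError("observed count must be nonnegative")
    if O == 0:
        return 0.0
    return float(2.0 * O * np.log(O / E))


def _gscore_totals(observed: np.ndarray, expected: np.ndarray) -> np.ndarray:
    """Vectorized total G over the last axis; rows of ``observed`` are datasets."""
    O = np.asarray(observed, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(O > 0, 2.0 * O * np.log(np.where(O > 0, O, 1.0) / expected), 0.0)
    return terms.sum(axis=-1)


def observed_gscores(
    mutations: Iterable[MutationCall],
    catalog: GeneCatalog,
    count_mode: str = "pooled",
    nonsynonymous_only: bool = True,
) -> GScoreReport:
    """Per-gene observed counts, expectations and G-scores.

    ``count_mode='pooled'`` counts every mutation event; ``'per_line_unique'``
    counts each gene at most once per evolution line (a gene "mutated in k
    lines" contributes k).  Intergenic calls (loci absent from the catalog)
    are excluded and their count is reported.
    """
    if count_mode not in ("pooled", "per_line_unique"):
        raise ValueError(f"unknown count_mode {count_mode!r}")
    gene_index = {g: i for i, g in enumerate(catalog.gene_ids)}
    observed = np.zeros(len(catalog.gene_ids))
    seen: set[tuple[str, str]] = set()
    n_intergenic = 0
    for call in mutations:
        if nonsynonymous_only and call.annotation not in NONSYNONYMOUS_TERMS:
            continue
        idx = gene_index.get(call.locus)
        if idx is None:
            n_intergenic += 1
            continue
        if count_mode == "per_line_unique":
            key = (call.line, call.locus)
            if key in seen:
                continue
            seen.add(key)
        observed[idx] += 1

    n_total = int(observed.sum())
    if n_total == 0:
        raise ValueError("no genic mutations to score")
    expected = n_total * catalog.lengths / catalog.total_gene_length
    gscores = np.array([gene_gscore(o, e) for o, e in zip(observed, expected)])
    return GScoreReport(
        gene_ids=catalog.gene_ids,
        observed=observed,
        expected=expected,
        gscores=gscores,
        total=float(gscores.sum()),
        n_mutations=n_total,
        n_intergenic_excluded=n_intergenic,
    )


def expected_gscore_null(
    catalog: GeneCatalog,
    n_total: int,
    n_sims: int = 1000,
    seed: int | None = None,
) -> tuple[float, float, np.ndarray]:
    """Null distribution of the total G under random mutation placement.

    Each simulation drops ``n_total`` mutations independently and uniformly
    along the genome: a gene is hit with probability L_i / genome_length and
    the remaining mass falls in intergenic sequence, which contributes 0 to
    the total.  Expected counts are the same length-proportional E_i used
    for the observed data.  Returns ``(mean, sd, totals)``.
    """
    if n_total < 1:
        raise ValueError("n_total must be >= 1 (nothing to randomize)")
    if n_sims < 2:
        raise ValueError("n_sims must be >= 2")
    rng = np.random.default_rng(seed)
    p = np.append(catalog.lengths / catalog.genome_length,
                  max(catalog.intergenic_fraction, 0.0))
    p = p / p.sum()
    counts = rng.multinomial(n_total, p, size=n_sims)[:, :-1]
    expected = n_total * catalog.lengths / catalog.total_gene_length
    totals = _gscore_totals(counts, expected)
    mu = float(totals.mean())
    sd = float(totals.std(ddof=1))
    if sd == 0.0:
        raise ValueError("null sd is zero; Z-score undefined for this catalog")
    return mu, sd, totals


def parallelism_zscore(g_obs: float, mu_g: float, sigma_g: float) -> float:
    """Z = (G_obs - mu_G) / sigma_G."""
    if sigma_g <= 0:
        raise ValueError("sigma_g must be positive")
    return float((g_obs - mu_g) / sigma_g)


def gscore_analysis(
    mutations: Iterable[MutationCall],
    catalog: GeneCatalog,
    n_sims: int = 1000,
    seed: int | None = None,
    count_mode: str = "pooled",
    nonsynonymous_only: bool = True,
) -> GScoreReport:
    """Observed G-scores plus the randomization null and Z-score."""
    report = observed_gscores(mutations, catalog, count_mode, nonsynonymous_only)
    mu, sd, _ = expected_gscore_null(catalog, report.n_mutations, n_sims, seed)
    report.null_mean = mu
    report.null_sd = sd
    report.n_sims = n_sims
    report.zscore = parallelism_zscore(report.total, mu, sd)
    return report
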