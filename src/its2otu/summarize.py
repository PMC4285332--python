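"""Diversity summaries: rank abundance, dominance ratios, rarefaction.

The signature of multicopy rDNA is a steeply uneven rank-abundance
profile — one or two dominant copies and a long tail of rare
intragenomic variants — quantified here by the dominance fold ratio
(top/second count), top-N read fractions, and analytic rarefaction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import gammaln

from .seqio import CountTable

__all__ = [
    "RankAbundance",
    "rank_abundance",
    "dominance_fold",
    "top_n_fraction",
    "rarefaction_curve",
    "rarefaction_monte_carlo",
]


@dataclass
class RankAbundance:
    """Descending (variant id, count, fraction) rows for one sample."""

    sample_id: str
    variant_ids: list[str]
    counts: list[int]

    def __post_init__(self) -> None:
        if any(c2 > c1 for c1, c2 in zip(self.counts, self.counts[1:])):
            raise ValueError("counts must be non-increasing")

    @property
    def total(self) -> int:
        return sum(self.counts)

    @property
    def fractions(self) -> list[float]:
        t = self.total
        return [c / t for c in self.counts]

    def __len__(self) -> int:
        return len(self.counts)


def rank_abundance(table: CountTable, sample_id: str) -> RankAbundance:
    """Rank variants of one sample by read count (ties: lexicographic seq)."""
    if sample_id not in table.samples:
        raise KeyError(sample_id)
    pairs = [
        (v, v.counts.get(sample_id, 0)) for v in table if v.counts.get(sample_id, 0)
    ]
    if not pairs:
        raise ValueError(f"sample {sample_id!r} has no reads")
    pairs.sort(key=lambda p: (-p[1], p[0].seq))
    return RankAbundance(
        sample_id,
        [v.id for v, _ in pairs],
        [c for _, c in pairs],
    )


def dominance_fold(ra: RankAbundance) -> float:
    """Fold ratio of the most abundant variant over the second (≥ 1)."""
    if len(ra) < 2:
        raise ValueError("dominance fold needs at least two variants")
    return ra.counts[0] / ra.counts[1]


def top_n_fraction(ra: RankAbundance, n: int) -> float:
    """Read fraction captured by the n most abundant variants."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return sum(ra.counts[:n]) / ra.total


def rarefaction_curve(
    counts: Sequence[int], depths: Sequence[int]
) -> list[float]:
    """Expected number of distinct variants in subsamples of given depths.

    Uses the exact hypergeometric expectation
    ``E[S_n] = sum_i (1 - C(N - N_i, n) / C(N, n))`` evaluated in
    log-gamma space, where N is the sample total and N_i the variant
    counts.  ``depths`` must not exceed N.
    """
    counts = [int(c) for c in counts if c > 0]
    if not counts:
        raise ValueError("empty sample")
    N = sum(counts)
    out = []
    for n in depths:
        if n < 0 or n > N:
            raise ValueError(f"depth {n} exceeds sample total {N}")
        if n == 0:
            out.append(0.0)
            continue
        expected = 0.0
        for Ni in counts:
            if N - Ni < n:
                expected += 1.0
            else:
                log_p = (
                    gammaln(N - Ni + 1)
                    - gammaln(n + 1)
                    - gammaln(N - Ni - n + 1)
                    - (gammaln(N + 1) - gammaln(n + 1) - gammaln(N - n + 1))
                )
                expected += 1.0 - float(np.exp(log_p))
        out.append(expected)
    return out


def rarefaction_monte_carlo(
    counts: Sequence[int],
    depth: int,
    n_reps: int = 10_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Resampling estimate of rarefied richness: (mean, standard error)."""
    counts = [int(c) for c in counts if c > 0]
    N = sum(counts)
    if depth > N:
        raise ValueError(f"depth {depth} exceeds sample total {N}")
    rng = np.random.default_rng(seed)
    pool = np.repeat(np.arange(len(counts)), counts)
    richness = np.empty(n_reps)
    for r in range(n_reps):
        sub = rng.choice(pool, size=depth, replace=False)
        richness[r] = np.unique(sub).size
    return float(richness.mean()), float(richness.std(ddof=1) / np.sqrt(n_reps))
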