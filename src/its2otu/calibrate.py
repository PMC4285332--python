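"""Cut-off calibration from isoclonal-culture controls.

An isoclonal culture is founded from a single cell, so every sequence
variant it yields is intragenomic.  The spread of pairwise uncorrected
distances among its abundant variants therefore bounds the within-
species divergence that an OTU cut-off must absorb: the species-level
cut-off is the smallest candidate at which every control culture
collapses into a single OTU.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .distance import AlignmentParams, GapPolicy, distance_matrix, pairwise_distance
from .otu import average_linkage_clusters
from .seqio import CountTable

__all__ = [
    "IntragenomicStats",
    "CalibrationResult",
    "intragenomic_stats",
    "derive_species_cutoff",
    "clade_cutoff_check",
    "DEFAULT_GRID",
]

#: Candidate cut-offs bracketing typical species-level values.
DEFAULT_GRID: tuple[float, ...] = tuple(round(0.01 * k, 2) for k in range(1, 11))


@dataclass(frozen=True)
class IntragenomicStats:
    """Summary of pairwise distances among one culture's abundant variants.

    ``sufficient`` is False when fewer than two variants pass the read
    floor, in which case the distance fields are NaN (never silent
    zeros).
    """

    sample_id: str
    n_variants_used: int
    mean: float
    median: float
    minimum: float
    maximum: float

    @property
    def range(self) -> float:
        return self.maximum - self.minimum

    @property
    def sufficient(self) -> bool:
        return self.n_variants_used >= 2


def _insufficient(sample_id: str, n: int) -> IntragenomicStats:
    nan = float("nan")
    return IntragenomicStats(sample_id, n, nan, nan, nan, nan)


def _qualifying(table: CountTable, sample_id: str, min_count: int):
    return [v for v in table if v.counts.get(sample_id, 0) >= min_count]


def intragenomic_stats(
    table: CountTable,
    sample_id: str,
    min_count: int = 100,
    params: AlignmentParams | None = None,
    policy: GapPolicy | None = None,
) -> IntragenomicStats:
    """Mean/median/min/max pairwise distance among a culture's variants.

    Only variants with at least ``min_count`` reads *in that sample* are
    considered — a per-sample read floor that guards the statistics
    against contamination and ultralow-abundance artefacts.
    """
    if sample_id not in table.samples:
        raise KeyError(sample_id)
    variants = _qualifying(table, sample_id, min_count)
    if len(variants) < 2:
        return _insufficient(sample_id, len(variants))
    dists = [
        pairwise_distance(a.seq, b.seq, params, policy)
        for a, b in combinations(variants, 2)
    ]
    arr = np.array(dists)
    return IntragenomicStats(
        sample_id=sample_id,
        n_variants_used=len(variants),
        mean=float(arr.mean()),
        median=float(np.median(arr)),
        minimum=float(arr.min()),
        maximum=float(arr.max()),
    )


def stats_table(
    table: CountTable,
    sample_ids: Sequence[str],
    min_count: int = 100,
    params: AlignmentParams | None = None,
    policy: GapPolicy | None = None,
) -> pd.DataFrame:
    """Per-culture intragenomic distance summary as a DataFrame."""
    rows = []
    for s in sample_ids:
        st = intragenomic_stats(table, s, min_count, params, policy)
        rows.append(
            {
                "sample": st.sample_id,
                "n_variants": st.n_variants_used,
                "mean": st.mean,
                "median": st.median,
                "min": st.minimum,
                "max": st.maximum,
                "range": st.range,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class CalibrationResult:
    """Per-culture OTU counts along a cut-off grid, and the derived cut-off.

    ``derived_cutoff`` is the smallest grid value at which every control
    collapses into one OTU, or None when no grid value achieves that.
    ``degenerate`` flags runs in which no control had two qualifying
    variants (the derived value then defaults to the smallest grid
    entry, trivially).
    """

    grid: tuple[float, ...]
    otu_counts: pd.DataFrame  # index: sample, columns: grid values
    derived_cutoff: float | None
    degenerate: bool = False


def derive_species_cutoff(
    table: CountTable,
    control_samples: Sequence[str],
    grid: Sequence[float] = DEFAULT_GRID,
    min_count: int = 100,
    params: AlignmentParams | None = None,
    policy: GapPolicy | None = None,
) -> CalibrationResult:
    """Smallest cut-off collapsing every control culture into one OTU.

    For each grid value, each control's qualifying variants (per-sample
    read floor ``min_count``) are clustered by average linkage; the
    derived cut-off is the smallest value yielding exactly one cluster
    for all controls.  Controls with fewer than two qualifying variants
    are trivially one OTU at any cut-off.
    """
    grid = tuple(sorted(grid))
    if not grid:
        raise ValueError("empty cut-off grid")
    if not control_samples:
        raise ValueError("no control samples given")

    per_control: dict[str, list] = {
        s: _qualifying(table, s, min_count) for s in control_samples
    }
    degenerate = all(len(v) < 2 for v in per_control.values())

    counts = pd.DataFrame(index=list(control_samples), columns=list(grid), dtype=int)
    for s, variants in per_control.items():
        if len(variants) < 2:
            counts.loc[s] = 1
            continue
        dm = distance_matrix(
            [v.seq for v in variants], [v.id for v in variants], params, policy
        )
        for g in grid:
            counts.loc[s, g] = len(average_linkage_clusters(dm, g))

    derived = None
    for g in grid:
        if (counts[g] == 1).all():
            derived = g
            break
    return CalibrationResult(grid, counts, derived, degenerate)


def clade_cutoff_check(
    table: CountTable,
    expected_clades: dict[str, str],
    candidates: Sequence[float],
    params: AlignmentParams | None = None,
    policy: GapPolicy | None = None,
) -> pd.DataFrame:
    """Test candidate clade cut-offs against known clade labels.

    ``expected_clades`` maps variant id → expected clade.  For each
    candidate, all listed variants are clustered by average linkage and
    the resulting partition is compared to the expectation with the
    adjusted Rand index; the check passes when ARI == 1.
    """
    ids = sorted(expected_clades)
    lookup = {v.id: v for v in table}
    missing = [i for i in ids if i not in lookup]
    if missing:
        raise KeyError(f"variants not in table: {missing[:3]}")
    dm = distance_matrix([lookup[i].seq for i in ids], ids, params, policy)
    truth = [expected_clades[i] for i in ids]

    rows = []
    for cand in candidates:
        clusters = average_linkage_clusters(dm, cand)
        labels = {m: k for k, c in enumerate(clusters) for m in c}
        pred = [labels[i] for i in ids]
        ari = adjusted_rand_score(truth, pred)
        rows.append(
            {
                "candidate": cand,
                "n_clusters": len(clusters),
                "adjusted_rand": ari,
                "recovered": bool(np.isclose(ari, 1.0)),
            }
        )
    return pd.DataFrame(rows)
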