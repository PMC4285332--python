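"""Two-tier taxon-based framework.

Tier one bins unique variants into deeply divergent clades by
average-neighbour (average-linkage) clustering at a coarse cut-off
(default 0.15).  Within each clade, variants much shorter than the rest
are screened out, and tier two clusters the remainder into species/
type-level OTUs at a fine cut-off (default 0.03, i.e. 97% similarity).
Each OTU is represented by its most abundant member, annotated against
a reference database of named ITS2 types by exhaustive nearest-
reference search.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .distance import (
    AlignmentParams,
    DistanceMatrix,
    GapPolicy,
    distance_matrix,
    global_align,
    uncorrected_distance,
)
from .preprocess import FilterPolicy, preprocess_reads
from .seqio import CountTable, MappingTable, ReferenceDB, SequenceRecord, UniqueSequence

__all__ = [
    "PipelineThresholds",
    "CladeAssignment",
    "Otu",
    "OtuPartition",
    "ReferenceHit",
    "average_linkage_clusters",
    "average_neighbor_cluster",
    "assign_clades",
    "length_screen",
    "pick_representative",
    "nearest_reference",
    "run_pipeline",
    "PipelineResult",
    "PipelineError",
]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass(frozen=True)
class PipelineThresholds:
    """Distance cut-offs of the two clustering tiers plus the length screen."""

    clade_cutoff: float = 0.15
    otu_cutoff: float = 0.03
    length_screen_quantile: float = 0.90

    def __post_init__(self) -> None:
        if not 0 < self.otu_cutoff < self.clade_cutoff <= 1:
            raise ValueError("need 0 < otu_cutoff < clade_cutoff <= 1")
        if not 0 < self.length_screen_quantile <= 1:
            raise ValueError("length_screen_quantile must lie in (0, 1]")


def average_linkage_clusters(
    dm: DistanceMatrix, cutoff: float
) -> list[list[str]]:
    """Agglomerative average-linkage clustering with a closed threshold.

    Repeatedly merges the pair of clusters with the smallest average
    inter-cluster distance while that distance is ≤ ``cutoff``.  Ties
    are broken on the lowest (i, j) index pair, so output is
    deterministic.  Returns clusters of variant labels, each sorted,
    ordered by their smallest member label.
    """
    n = len(dm)
    if n == 0:
        raise ValueError("empty distance matrix")
    d = dm.values.astype(float).copy()
    sizes = np.ones(n)
    active = list(range(n))
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    np.fill_diagonal(d, np.inf)

    while len(active) > 1:
        sub = d[np.ix_(active, active)]
        k = int(np.argmin(sub))  # first minimum → lowest index pair
        i_loc, j_loc = divmod(k, len(active))
        if i_loc > j_loc:
            i_loc, j_loc = j_loc, i_loc
        best = sub[i_loc, j_loc]
        if best > cutoff:
            break
        i, j = active[i_loc], active[j_loc]
        # Lance–Williams update for average linkage (UPGMA)
        ni, nj = sizes[i], sizes[j]
        new_row = (ni * d[i] + nj * d[j]) / (ni + nj)
        d[i] = new_row
        d[:, i] = new_row
        d[i, i] = np.inf
        sizes[i] = ni + nj
        members[i] = members[i] + members.pop(j)
        active.remove(j)
        d[j] = np.inf
        d[:, j] = np.inf

    clusters = [sorted(dm.labels[idx] for idx in members[i]) for i in active]
    clusters.sort(key=lambda c: c[0])
    return clusters


class ReferenceHit(NamedTuple):
    type_name: str
    percent_identity: float
    tie: bool


@dataclass
class Otu:
    otu_id: str
    members: list[str]
    representative: str
    annotation: ReferenceHit | None = None


@dataclass
class OtuPartition:
    """Assignment of variants to OTUs at a stated distance cut-off."""

    cutoff: float
    clusters: list[Otu]

    def __post_init__(self) -> None:
        all_members = [m for c in self.clusters for m in c.members]
        if len(all_members) != len(set(all_members)):
            raise ValueError("OTU clusters overlap")
        for c in self.clusters:
            if c.representative not in c.members:
                raise ValueError(f"representative of {c.otu_id} is not a member")

    def __len__(self) -> int:
        return len(self.clusters)

    @property
    def member_ids(self) -> list[str]:
        return [m for c in self.clusters for m in c.members]


def pick_representative(members: Sequence[UniqueSequence]) -> str:
    """Most abundant member; ties go to the lexicographically smallest sequence."""
    if not members:
        raise ValueError("empty cluster")
    best = min(members, key=lambda v: (-v.total, v.seq))
    return best.id


def average_neighbor_cluster(
    dm: DistanceMatrix,
    cutoff: float,
    table: CountTable | None = None,
    id_prefix: str = "OTU",
) -> OtuPartition:
    """Average-neighbour OTU clustering with representative picking.

    Clusters are numbered by descending total read count (then by
    smallest member label) when a CountTable is supplied, otherwise by
    smallest member label.
    """
    clusters = average_linkage_clusters(dm, cutoff)
    if table is not None:
        lookup = {v.id: v for v in table}
        def cluster_key(c: list[str]):
            return (-sum(lookup[m].total for m in c), c[0])
        clusters.sort(key=cluster_key)
    otus = []
    for rank, c in enumerate(clusters, start=1):
        if table is not None:
            rep = pick_representative([lookup[m] for m in c])
        else:
            rep = c[0]
        otus.append(Otu(f"{id_prefix}{rank}", list(c), rep))
    return OtuPartition(cutoff, otus)


@dataclass
class CladeAssignment:
    """Variant id → clade label; clades ordered by descending read count."""

    assignment: dict[str, str]

    @property
    def clades(self) -> list[str]:
        seen: list[str] = []
        for label in self.assignment.values():
            if label not in seen:
                seen.append(label)
        return sorted(seen)

    def members(self, clade: str) -> list[str]:
        return sorted(v for v, c in self.assignment.items() if c == clade)


def assign_clades(
    table: CountTable, dm: DistanceMatrix, clade_cutoff: float = 0.15
) -> CladeAssignment:
    """Bin variants into clades by average-neighbour clustering.

    Clade labels are structural ("clade1", "clade2", ...), numbered by
    descending total read count; human-readable clade letters come only
    from downstream reference annotation.
    """
    clusters = average_linkage_clusters(dm, clade_cutoff)
    lookup = {v.id: v for v in table}
    clusters.sort(key=lambda c: (-sum(lookup[m].total for m in c), c[0]))
    assignment: dict[str, str] = {}
    for rank, c in enumerate(clusters, start=1):
        for m in c:
            assignment[m] = f"clade{rank}"
    return CladeAssignment(assignment)


def length_screen(
    variants: Sequence[UniqueSequence], quantile: float = 0.90
) -> tuple[list[UniqueSequence], list[UniqueSequence]]:
    """Drop variants shorter than ``quantile`` of a clade's variants.

    A variant is discarded when the fraction of variants strictly longer
    than it is ≥ ``quantile`` — e.g. at the default 0.90, a variant
    shorter than 90% of its clade is removed.
    """
    if not variants:
        raise ValueError("empty clade")
    if not 0 < quantile <= 1:
        raise ValueError("quantile must lie in (0, 1]")
    lengths = np.array([len(v.seq) for v in variants])
    n = len(variants)
    retained, discarded = [], []
    for v in variants:
        frac_longer = np.sum(lengths > len(v.seq)) / n
        (discarded if frac_longer >= quantile else retained).append(v)
    return retained, discarded


def nearest_reference(
    query: str,
    db: ReferenceDB,
    params: AlignmentParams | None = None,
    policy: GapPolicy | None = None,
) -> ReferenceHit:
    """Best-identity reference type for a query sequence.

    Every database entry is globally aligned to the query; percent
    identity is ``100 * (1 - uncorrected distance)`` under the same gap
    policy as the clustering distances.  Ties go to the first entry in
    database order and are reported via the ``tie`` flag.
    """
    if len(db) == 0:
        raise ValueError("empty reference database")
    best: ReferenceHit | None = None
    best_pid = -1.0
    tie = False
    for entry in db:
        if query == entry.seq:
            pid = 100.0
        else:
            aa, ab = global_align(query, entry.seq, params)
            pid = 100.0 * (1.0 - uncorrected_distance(aa, ab, policy))
        if pid > best_pid + 1e-12:
            best = ReferenceHit(entry.type_name, pid, False)
            best_pid = pid
            tie = False
        elif abs(pid - best_pid) <= 1e-12:
            tie = True
    assert best is not None
    return ReferenceHit(best.type_name, best.percent_identity, tie)


@dataclass
class PipelineResult:
    """End-to-end pipeline output: per-clade OTU partitions and a flat table."""

    table: CountTable
    clades: CladeAssignment
    partitions: dict[str, OtuPartition]
    otu_table: pd.DataFrame
    filter_report: pd.DataFrame
    chimera_ids: list[str]
    thresholds: PipelineThresholds


def _annotate(
    hit: ReferenceHit, clade: str, min_identity: float = 90.0
) -> ReferenceHit:
    if hit.tie or hit.percent_identity < min_identity:
        return ReferenceHit(f"unclassified_{clade}", hit.percent_identity, hit.tie)
    return hit


def run_pipeline(
    reads: Iterable[SequenceRecord],
    mapping: MappingTable,
    refdb: ReferenceDB | None = None,
    policy: FilterPolicy | None = None,
    thresholds: PipelineThresholds | None = None,
    params: AlignmentParams | None = None,
    gap_policy: GapPolicy | None = None,
) -> PipelineResult:
    """Full pipeline: reads → filtered variants → clades → OTUs → annotation.

    Stages: demultiplex, reverse-primer trim, quality filter,
    dereplicate, chimera flagging, singleton removal, clade binning at
    the coarse cut-off, per-clade length screen, per-clade
    average-neighbour OTU clustering at the fine cut-off,
    representative picking and nearest-reference annotation.
    """
    thresholds = thresholds or PipelineThresholds()
    table, report, chimeras = preprocess_reads(reads, mapping, policy)
    if len(table) == 0:
        raise PipelineError("preprocess: no variants retained after filtering")

    seqs = [v.seq for v in table]
    dm = distance_matrix(seqs, table.ids, params, gap_policy)
    clades = assign_clades(table, dm, thresholds.clade_cutoff)

    lookup = {v.id: v for v in table}
    partitions: dict[str, OtuPartition] = {}
    rows = []
    kept_ids: list[str] = []
    for clade in clades.clades:
        clade_members = [lookup[m] for m in clades.members(clade)]
        retained, _ = length_screen(clade_members, thresholds.length_screen_quantile)
        if not retained:
            continue
        ids = sorted(v.id for v in retained)
        kept_ids.extend(ids)
        sub_dm = dm.subset(ids)
        sub_table = table.subset(ids)
        part = average_neighbor_cluster(
            sub_dm, thresholds.otu_cutoff, sub_table, id_prefix=f"{clade}_OTU"
        )
        if refdb is not None:
            for otu in part.clusters:
                hit = nearest_reference(
                    lookup[otu.representative].seq, refdb, params, gap_policy
                )
                otu.annotation = _annotate(hit, clade)
        partitions[clade] = part
        for otu in part.clusters:
            row: dict[str, object] = {
                "otu_id": otu.otu_id,
                "clade": clade,
                "representative_id": otu.representative,
                "type_name": otu.annotation.type_name if otu.annotation else "",
                "pct_identity": (
                    round(otu.annotation.percent_identity, 2)
                    if otu.annotation
                    else np.nan
                ),
                "n_variants": len(otu.members),
            }
            for s in table.samples:
                row[s] = sum(lookup[m].counts.get(s, 0) for m in otu.members)
            rows.append(row)

    if not rows:
        raise PipelineError("otu: no variants survived the per-clade length screen")
    otu_table = pd.DataFrame(rows)
    return PipelineResult(
        table=table.subset(kept_ids),
        clades=clades,
        partitions=partitions,
        otu_table=otu_table,
        filter_report=report.to_frame(),
        chimera_ids=chimeras,
        thresholds=thresholds,
    )
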