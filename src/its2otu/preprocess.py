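"""Read-level stages: demultiplexing, primer trimming, quality filtering,
dereplication, singleton removal and a simplified chimera flagger.

The filter criteria follow common 454 amplicon practice: reads are
discarded on any barcode mismatch, more than two forward-primer
mismatches, any ambiguous base, a homopolymer run longer than four, or
a post-trim length below 250 nt.  The reverse primer is removed
cutadapt-style at an overall error rate of 0.15.  Qualities, when
present, are ignored: every criterion is sequence-based.
"""

from __future__ import annotations

import re
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import edlib
import numpy as np
import pandas as pd

from .seqio import (
    IUPAC,
    CountTable,
    MappingTable,
    SequenceRecord,
    UniqueSequence,
)

__all__ = [
    "FilterPolicy",
    "FilterReport",
    "demultiplex",
    "trim_reverse_primer",
    "quality_filter",
    "dereplicate",
    "remove_singletons",
    "flag_chimeras",
    "preprocess_reads",
]

UNASSIGNED = "_unassigned"

#: Discard reasons, in the order the filters run.
REASONS = (
    "barcode",
    "fwd_primer",
    "rev_primer_missing",
    "ambiguity",
    "homopolymer",
    "length",
    "chimera",
)


@dataclass(frozen=True)
class FilterPolicy:
    """Thresholds of the read filter.

    Defaults discard reads with any barcode mismatch, >2 forward-primer
    mismatches, >0 ambiguous bases, homopolymer runs >4 nt, or length
    <250 nt after trimming; the reverse primer is trimmed at an overall
    error rate of 0.15.  ``require_rev_primer`` additionally discards
    reads in which the reverse primer was not found (off by default: the
    usual adapter-trimming convention keeps such reads).
    """

    max_barcode_mismatch: int = 0
    max_fwd_primer_mismatch: int = 2
    max_ambiguous: int = 0
    max_homopolymer: int = 4
    min_length: int = 250
    rev_primer_error_rate: float = 0.15
    require_rev_primer: bool = False

    def __post_init__(self) -> None:
        for name in (
            "max_barcode_mismatch",
            "max_fwd_primer_mismatch",
            "max_ambiguous",
            "max_homopolymer",
            "min_length",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.rev_primer_error_rate <= 1.0:
            raise ValueError("rev_primer_error_rate must lie in [0, 1]")


@dataclass
class FilterReport:
    """Per-sample accounting of kept and discarded reads.

    Reads that fail barcode assignment have no sample and are booked
    under the pseudo-sample ``_unassigned``.  The invariant
    ``input == kept + sum(discarded)`` holds at all times.
    """

    n_input: int = 0
    kept: Counter = field(default_factory=Counter)
    discarded: dict = field(default_factory=lambda: defaultdict(Counter))

    def record_kept(self, sample: str) -> None:
        self.kept[sample] += 1

    def record_discard(self, sample: str | None, reason: str) -> None:
        if reason not in REASONS:
            raise ValueError(f"unknown discard reason {reason!r}")
        self.discarded[sample or UNASSIGNED][reason] += 1

    def unkeep(self, sample: str, reason: str) -> None:
        """Move a previously kept read into a discard bucket."""
        if self.kept[sample] < 1:
            raise ValueError(f"no kept reads to discard for {sample!r}")
        self.kept[sample] -= 1
        self.record_discard(sample, reason)

    @property
    def n_kept(self) -> int:
        return sum(self.kept.values())

    @property
    def n_discarded(self) -> int:
        return sum(sum(c.values()) for c in self.discarded.values())

    def check_conservation(self) -> bool:
        return self.n_input == self.n_kept + self.n_discarded

    def to_frame(self) -> pd.DataFrame:
        samples = sorted(set(self.kept) | set(self.discarded))
        rows = []
        for s in samples:
            row = {"sample": s, "kept": self.kept.get(s, 0)}
            for r in REASONS:
                row[r] = self.discarded.get(s, {}).get(r, 0)
            rows.append(row)
        return pd.DataFrame(rows, columns=["sample", "kept", *REASONS])


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance needs equal lengths")
    return sum(x != y for x, y in zip(a, b))


def primer_mismatches(primer: str, window: str) -> int:
    """Substitution count of a read window against an IUPAC primer.

    The primer side is expanded (e.g. W matches A or T); an N in the
    read matches only a primer N.
    """
    if len(primer) != len(window):
        raise ValueError("primer/window length mismatch")
    mm = 0
    for p, c in zip(primer, window):
        allowed = IUPAC.get(p)
        if allowed is None or (c not in allowed and not (c == "N" and p == "N")):
            mm += 1
    return mm


def demultiplex(
    reads: Iterable[SequenceRecord],
    mapping: MappingTable,
    policy: FilterPolicy | None = None,
) -> tuple[dict[str, list[SequenceRecord]], FilterReport]:
    """Assign reads to samples and strip barcode + forward primer.

    Barcode matching is 5'-anchored Hamming distance (no indels, as
    barcodes are fixed-length); the forward primer is matched directly
    after the barcode with IUPAC-aware substitution counting.
    """
    if len(mapping) == 0:
        raise ValueError("empty mapping table")
    policy = policy or FilterPolicy()
    bl = mapping.barcode_length
    report = FilterReport()
    out: dict[str, list[SequenceRecord]] = {r.sample_id: [] for r in mapping}
    exact = {r.barcode: r for r in mapping}

    for read in reads:
        report.n_input += 1
        if len(read.seq) < bl:
            report.record_discard(None, "barcode")
            continue
        prefix = read.seq[:bl]
        row = exact.get(prefix)
        if row is None and policy.max_barcode_mismatch > 0:
            best, best_mm = None, bl + 1
            for r in mapping:
                mm = hamming(prefix, r.barcode)
                if mm < best_mm:
                    best, best_mm = r, mm
            if best is not None and best_mm <= policy.max_barcode_mismatch:
                row = best
        if row is None:
            report.record_discard(None, "barcode")
            continue
        fp = row.forward_primer
        if len(read.seq) < bl + len(fp):
            report.record_discard(row.sample_id, "fwd_primer")
            continue
        mm = primer_mismatches(fp, read.seq[bl : bl + len(fp)])
        if mm > policy.max_fwd_primer_mismatch:
            report.record_discard(row.sample_id, "fwd_primer")
            continue
        rest = read.seq[bl + len(fp) :]
        if not rest:
            report.record_discard(row.sample_id, "length")
            continue
        qual = read.qual[bl + len(fp) :] if read.qual is not None else None
        out[row.sample_id].append(SequenceRecord(read.id, rest, qual))
        report.record_kept(row.sample_id)
    return out, report


def trim_reverse_primer(
    read: SequenceRecord, rev_primer: str, error_rate: float = 0.15
) -> tuple[SequenceRecord, bool]:
    """Remove the reverse primer from the 3' end, cutadapt-style.

    An interior occurrence is located with an infix edit-distance search
    (substitutions and indels both count as errors); if the best hit has
    an error rate ≤ ``error_rate`` the read is cut at the hit start.
    Otherwise primer prefixes of ≥8 nt overlapping the read's 3' end are
    tried by substitution counting.  Unmatched reads return unchanged.
    """
    if not 0.0 <= error_rate <= 1.0:
        raise ValueError("error_rate must lie in [0, 1]")
    seq = read.seq
    if len(rev_primer) == 0 or len(seq) == 0:
        return read, False

    cut: int | None = None
    if len(seq) >= len(rev_primer):
        max_ed = int(error_rate * len(rev_primer))
        res = edlib.align(rev_primer, seq, mode="HW", task="locations", k=max_ed)
        if res["editDistance"] != -1 and res["locations"]:
            cut = min(loc[0] for loc in res["locations"])
    if cut is None:
        for k in range(min(len(rev_primer), len(seq)) - 1, 7, -1):
            if hamming(rev_primer[:k], seq[-k:]) <= error_rate * k:
                cut = len(seq) - k
                break
    if cut is None:
        return read, False
    if cut == 0:
        # primer spans the whole read; nothing sequence-like remains
        return read, False
    qual = read.qual[:cut] if read.qual is not None else None
    return SequenceRecord(read.id, seq[:cut], qual), True


def quality_filter(
    read: SequenceRecord, policy: FilterPolicy | None = None
) -> str | None:
    """Return a discard reason, or None when the read passes.

    Rules are applied in order: ambiguity count, homopolymer run length
    (a run strictly longer than the threshold fails), minimum length.
    """
    policy = policy or FilterPolicy()
    if read.seq.count("N") > policy.max_ambiguous:
        return "ambiguity"
    run_re = re.compile(r"(.)\1{%d,}" % policy.max_homopolymer)
    if run_re.search(read.seq):
        return "homopolymer"
    if len(read.seq) < policy.min_length:
        return "length"
    return None


def dereplicate(
    per_sample_reads: Mapping[str, Sequence[SequenceRecord]],
) -> CountTable:
    """Collapse identical sequences into unique variants with per-sample counts."""
    tallies: dict[str, Counter] = defaultdict(Counter)
    for sample, reads in per_sample_reads.items():
        for r in reads:
            tallies[r.seq][sample] += 1
    samples = list(per_sample_reads.keys())
    variants = [UniqueSequence(seq, dict(c)) for seq, c in tallies.items()]
    return CountTable(variants, samples)


def remove_singletons(table: CountTable) -> CountTable:
    """Drop variants seen exactly once across the entire data set."""
    return CountTable([v for v in table if v.total > 1], table.samples)


def flag_chimeras(
    table: CountTable, skew: float = 2.0
) -> tuple[CountTable, list[str]]:
    """Flag and remove two-parent single-crossover chimeras.

    A deliberate simplification of abundance-aware chimera detection: a
    variant is flagged when some split point leaves its 5' segment
    within one mismatch of one parent and its 3' segment within one
    mismatch of a different parent, both parents being at least ``skew``
    times more abundant, while no single parent explains the variant to
    within two mismatches.  Comparisons are positional, so only
    equal-length parents are considered.  Returns the cleaned table and
    the flagged variant ids.
    """
    variants = table.variants  # already sorted by descending abundance
    flagged: list[str] = []
    by_len: dict[int, list[UniqueSequence]] = defaultdict(list)
    for v in variants:
        by_len[len(v.seq)].append(v)

    arrs = {
        v.id: np.frombuffer(v.seq.encode("ascii"), dtype=np.uint8) for v in variants
    }
    for v in variants:
        parents = [
            p
            for p in by_len[len(v.seq)]
            if p.total >= skew * v.total and p.seq != v.seq
        ]
        if len(parents) < 2:
            continue
        q = arrs[v.id]
        mm = np.stack([arrs[p.id] != q for p in parents])  # parents × L booleans
        prefix = np.cumsum(mm, axis=1)  # mismatches in v[:s] vs each parent
        totals = prefix[:, -1]
        if totals.min() < 3:
            continue  # a single parent explains the variant
        L = len(v.seq)
        # split at s = 1..L-1: column t of `left` is mismatches in v[:t+1]
        left = prefix[:, :-1]
        right = totals[:, None] - left
        left_ok = left <= 1
        right_ok = right <= 1
        # need two *different* parents: best-left parent ok and best-right
        # parent ok with distinct indices at the same split
        for s in range(L - 1):
            li = np.flatnonzero(left_ok[:, s])
            ri = np.flatnonzero(right_ok[:, s])
            if li.size and ri.size and (li.size > 1 or ri.size > 1 or li[0] != ri[0]):
                flagged.append(v.id)
                break
    kept = CountTable([v for v in variants if v.id not in set(flagged)], table.samples)
    return kept, flagged


def preprocess_reads(
    reads: Iterable[SequenceRecord],
    mapping: MappingTable,
    policy: FilterPolicy | None = None,
    check_chimeras: bool = True,
) -> tuple[CountTable, FilterReport, list[str]]:
    """Full read-level stage: demux → trim → filter → derep → chimera → singletons.

    Returns the cleaned CountTable, the filter report, and the flagged
    chimera ids.  Chimera checking runs on the pooled table by default.
    """
    policy = policy or FilterPolicy()
    per_sample, report = demultiplex(reads, mapping, policy)
    rev = {r.sample_id: r.reverse_primer for r in mapping}
    filtered: dict[str, list[SequenceRecord]] = {s: [] for s in per_sample}
    for sample, rs in per_sample.items():
        for read in rs:
            trimmed_read, found = trim_reverse_primer(
                read, rev[sample], policy.rev_primer_error_rate
            )
            if policy.require_rev_primer and not found:
                report.unkeep(sample, "rev_primer_missing")
                continue
            reason = quality_filter(trimmed_read, policy)
            if reason is not None:
                report.unkeep(sample, reason)
                continue
            filtered[sample].append(trimmed_read)
    table = dereplicate(filtered)
    flagged: list[str] = []
    if check_chimeras and len(table):
        table, flagged = flag_chimeras(table)
    table = remove_singletons(table)
    return table, report, flagged
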