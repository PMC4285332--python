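"""Synthetic amplicon generator with known ground truth.

Emulates the genomic and technical structure of multicopy ITS2
pyrosequencing data: per-genome variant pools with one or two dominant
copies and a geometric long tail of rare intragenomic variants within a
few percent divergence; multiple clades separated by >15% divergence;
per-lineage rDNA copy-number bias; and barcoded 454-style reads with
substitution errors, homopolymer ±1 indels and two-parent chimeras.
Every stage of the pipeline can thus be tested against simulator truth
without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .distance import pairwise_distance
from .seqio import (
    MappingRow,
    MappingTable,
    ReferenceDB,
    ReferenceEntry,
    SequenceRecord,
    sequence_id,
)

__all__ = [
    "GenomeModel",
    "ReadModel",
    "SimulatedSample",
    "simulate_rdna_library",
    "simulate_sample",
    "make_reference_db",
    "make_clade_genomes",
    "make_mapping",
    "random_sequence",
    "max_homopolymer_run",
    "mutate",
    "DEFAULT_FWD_PRIMER",
    "DEFAULT_REV_PRIMER",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# 454-style ITS2 primer pair (amplicon-facing parts, without adapters).
DEFAULT_FWD_PRIMER = "GAATTGCAGAACTCCGTG"
DEFAULT_REV_PRIMER = "GGGATCCATATGCTTAAGTTCAGCGGGT"


def max_homopolymer_run(seq: str) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def random_sequence(
    rng: np.random.Generator, length: int, max_run: int = 4
) -> str:
    """Random ACGT string with homopolymer runs capped at ``max_run``.

    Amplifiable templates must survive the homopolymer filter, so
    generated genomes avoid runs longer than the filter threshold.
    """
    out = bytearray()
    run = 0
    for _ in range(length):
        while True:
            b = int(rng.choice(_BASES))
            if not (out and b == out[-1] and run >= max_run):
                break
        run = run + 1 if out and b == out[-1] else 1
        out.append(b)
    return out.decode("ascii")


def mutate(rng: np.random.Generator, seq: str, n_subs: int) -> str:
    """Apply ``n_subs`` substitutions at distinct positions."""
    arr = bytearray(seq, "ascii")
    positions = rng.choice(len(arr), size=n_subs, replace=False)
    for p in positions:
        alternatives = [b for b in _BASES if b != arr[p]]
        arr[p] = int(rng.choice(alternatives))
    return arr.decode("ascii")


@dataclass(frozen=True)
class GenomeModel:
    """Intragenomic ITS2 variant structure of one lineage.

    ``dominant_seqs`` carry ``dominance`` of the copy mass; the
    remaining mass is spread over ``n_rare_variants`` substitution
    mutants of the dominants, each within ``max_intra_divergence``
    uncorrected distance, with geometrically decaying frequencies.
    ``rdna_copy_weight`` models lineage-specific rDNA copy number and
    multiplies the cell proportion when reads are drawn from mixtures.
    """

    species_name: str
    clade_label: str
    dominant_seqs: tuple[str, ...]
    n_rare_variants: int = 30
    max_intra_divergence: float = 0.02
    dominance: float = 0.8
    rdna_copy_weight: float = 1.0

    def __post_init__(self) -> None:
        if not 1 <= len(self.dominant_seqs) <= 2:
            raise ValueError("need one or two dominant sequences")
        if not 0 < self.dominance <= 1:
            raise ValueError("dominance must lie in (0, 1]")
        if self.rdna_copy_weight <= 0:
            raise ValueError("rdna_copy_weight must be positive")
        if not 0 <= self.max_intra_divergence <= 1:
            raise ValueError("max_intra_divergence must lie in [0, 1]")


@dataclass(frozen=True)
class ReadModel:
    """Technical read structure and error rates.

    Default rates emulate flowgram-denoised 454 reads — the input the
    base-called pipeline expects — where residual substitution error is
    roughly 2 per 10 kb and homopolymer-length errors survive at about
    1 per 1000 eligible runs.
    """

    barcode: str = "ACGTACGT"
    fwd_primer: str = DEFAULT_FWD_PRIMER
    rev_primer: str = DEFAULT_REV_PRIMER
    substitution_rate: float = 0.0002
    homopolymer_indel_rate: float = 0.001
    chimera_rate: float = 0.0

    def __post_init__(self) -> None:
        for name in ("substitution_rate", "homopolymer_indel_rate", "chimera_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


def simulate_rdna_library(
    model: GenomeModel, seed: int | np.random.Generator
) -> list[tuple[str, float]]:
    """Draw a genome's variant pool: (sequence, frequency) rows summing to 1.

    Rare variants are substitution mutants of a randomly chosen
    dominant, with 1..floor(d*L) substitutions so each stays within
    ``max_intra_divergence`` d; their frequencies follow a geometric
    tail (ratio 0.7).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    doms = list(model.dominant_seqs)
    if len(doms) == 2:
        dom_freqs = [0.7 * model.dominance, 0.3 * model.dominance]
    else:
        dom_freqs = [model.dominance]
    pool = list(zip(doms, dom_freqs))
    if model.n_rare_variants == 0 or model.dominance == 1.0:
        total = sum(f for _, f in pool)
        return [(s, f / total) for s, f in pool]

    seen = set(doms)
    rare: list[str] = []
    while len(rare) < model.n_rare_variants:
        parent = doms[int(rng.integers(len(doms)))]
        max_k = max(1, int(model.max_intra_divergence * len(parent)))
        k = int(rng.integers(1, max_k + 1))
        variant = mutate(rng, parent, k)
        # keep the genome pool amplifiable: no filter-failing runs
        if variant not in seen and max_homopolymer_run(variant) <= 4:
            seen.add(variant)
            rare.append(variant)
    ratio = 0.7
    weights = ratio ** np.arange(len(rare))
    weights *= (1.0 - model.dominance) / weights.sum()
    pool.extend(zip(rare, weights.tolist()))
    return pool


def _homopolymer_runs(seq: str, min_len: int = 3) -> list[tuple[int, int]]:
    runs = []
    i = 0
    while i < len(seq):
        j = i
        while j < len(seq) and seq[j] == seq[i]:
            j += 1
        if j - i >= min_len:
            runs.append((i, j))
        i = j
    return runs


def _apply_read_errors(
    rng: np.random.Generator, seq: str, model: ReadModel
) -> tuple[str, int, int]:
    """Substitutions everywhere; ±1 indels inside homopolymer runs ≥ 3."""
    n_subs = int(rng.binomial(len(seq), model.substitution_rate))
    if n_subs:
        seq = mutate(rng, seq, min(n_subs, len(seq)))
    n_indels = 0
    if model.homopolymer_indel_rate > 0:
        runs = _homopolymer_runs(seq)
        edits: list[tuple[int, int]] = []  # (position, +1/-1)
        for start, end in runs:
            if rng.random() < model.homopolymer_indel_rate:
                edits.append((start, 1 if rng.random() < 0.5 else -1))
        for pos, delta in sorted(edits, reverse=True):
            if delta > 0:
                seq = seq[:pos] + seq[pos] + seq[pos:]
            else:
                seq = seq[:pos] + seq[pos + 1 :]
            n_indels += 1
    return seq, n_subs, n_indels


@dataclass
class SimulatedSample:
    """Reads plus the truth table mapping each read to its origin."""

    sample_id: str
    reads: list[SequenceRecord]
    truth: pd.DataFrame  # read_id, species, template_id, is_chimera, n_subs, n_indels
    libraries: dict[str, list[tuple[str, float]]]
    read_model: ReadModel


def simulate_sample(
    genomes: Sequence[GenomeModel],
    proportions: Sequence[float],
    n_reads: int,
    read_model: ReadModel,
    seed: int | np.random.Generator,
    sample_id: str = "sample1",
) -> SimulatedSample:
    """Simulate one barcoded amplicon sample from a (possibly mixed) pool.

    Read sampling weights are cell proportion × rDNA copy weight, so a
    lineage with more rDNA copies contributes disproportionately many
    reads — the copy-number bias seen in pooled-culture experiments.
    Chimeric reads splice two templates at a single crossover.
    """
    if len(genomes) != len(proportions):
        raise ValueError("genomes/proportions length mismatch")
    if abs(sum(proportions) - 1.0) > 1e-9:
        raise ValueError("proportions must sum to 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    weights = np.array(
        [p * g.rdna_copy_weight for p, g in zip(proportions, genomes)], dtype=float
    )
    weights /= weights.sum()

    libraries = {g.species_name: simulate_rdna_library(g, rng) for g in genomes}
    lib_seqs = {k: [s for s, _ in v] for k, v in libraries.items()}
    lib_freqs = {k: np.array([f for _, f in v]) for k, v in libraries.items()}

    def draw_template() -> tuple[str, str]:
        gi = int(rng.choice(len(genomes), p=weights))
        g = genomes[gi]
        vi = int(rng.choice(len(lib_seqs[g.species_name]), p=lib_freqs[g.species_name]))
        return g.species_name, lib_seqs[g.species_name][vi]

    reads: list[SequenceRecord] = []
    truth_rows = []
    for k in range(n_reads):
        is_chimera = rng.random() < read_model.chimera_rate
        if is_chimera:
            sp1, t1 = draw_template()
            sp2, t2 = draw_template()
            lo = min(len(t1), len(t2))
            margin = max(1, lo // 6)
            cross = int(rng.integers(margin, lo - margin))
            template = t1[:cross] + t2[cross:]
            species = f"{sp1}|{sp2}"
        else:
            species, template = draw_template()
        seq, n_subs, n_indels = _apply_read_errors(rng, template, read_model)
        full = read_model.barcode + read_model.fwd_primer + seq + read_model.rev_primer
        rid = f"{sample_id}_r{k:06d}"
        reads.append(
            SequenceRecord(rid, full, tuple([40] * len(full)))
        )
        truth_rows.append(
            {
                "read_id": rid,
                "species": species,
                "template_id": sequence_id(template),
                "is_chimera": is_chimera,
                "n_subs": n_subs,
                "n_indels": n_indels,
            }
        )
    truth = pd.DataFrame(truth_rows)
    return SimulatedSample(sample_id, reads, truth, libraries, read_model)


def make_reference_db(genomes: Sequence[GenomeModel]) -> ReferenceDB:
    """Reference database with one entry per dominant sequence."""
    if not genomes:
        raise ValueError("need at least one genome")
    entries = []
    for g in genomes:
        for i, seq in enumerate(g.dominant_seqs):
            suffix = "" if len(g.dominant_seqs) == 1 else f".{i + 1}"
            entries.append(
                ReferenceEntry(f"{g.species_name}{suffix}", seq, "synthetic")
            )
    return ReferenceDB(entries)


def make_clade_genomes(
    n_clades: int,
    seed: int | np.random.Generator,
    length: int = 320,
    min_interclade: float = 0.15,
    **genome_kwargs,
) -> list[GenomeModel]:
    """One genome per clade, dominants forced > ``min_interclade`` apart.

    Dominant sequences are random templates per clade; rejection
    sampling guarantees every inter-clade uncorrected distance exceeds
    the threshold (random sequences of this length are far more
    divergent than 15%, so rejections are rare).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    doms: list[str] = []
    attempts = 0
    while len(doms) < n_clades:
        cand = random_sequence(rng, length)
        if all(pairwise_distance(cand, d) > min_interclade for d in doms):
            doms.append(cand)
        attempts += 1
        if attempts > 100 * n_clades:
            raise RuntimeError("rejection sampling failed to separate clades")
    letters = "ABCDEFGHI"
    return [
        GenomeModel(
            species_name=f"{letters[i]}1",
            clade_label=letters[i],
            dominant_seqs=(doms[i],),
            **genome_kwargs,
        )
        for i in range(n_clades)
    ]


def make_mapping(
    samples: Sequence[str],
    seed: int | np.random.Generator,
    barcode_length: int = 8,
    fwd_primer: str = DEFAULT_FWD_PRIMER,
    rev_primer: str = DEFAULT_REV_PRIMER,
) -> MappingTable:
    """Random unique equal-length barcodes for a list of sample ids."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    barcodes: list[str] = []
    while len(barcodes) < len(samples):
        b = random_sequence(rng, barcode_length)
        if b not in barcodes:
            barcodes.append(b)
    return MappingTable(
        [
            MappingRow(s, b, fwd_primer, rev_primer)
            for s, b in zip(samples, barcodes)
        ]
    )
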