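"""Clustering-tier tests: naive-agglomeration and scipy UPGMA oracles."""

import numpy as np
import pytest
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from its2otu.distance import DistanceMatrix, distance_matrix
from its2otu.otu import (
    PipelineError,
    PipelineThresholds,
    assign_clades,
    average_linkage_clusters,
    average_neighbor_cluster,
    length_screen,
    nearest_reference,
    pick_representative,
    run_pipeline,
)
from its2otu.seqio import ReferenceDB, ReferenceEntry, UniqueSequence
from conftest import make_count_table


def naive_average_linkage(d: np.ndarray, cutoff: float) -> list[frozenset]:
    """O(n^3) reference agglomeration, recomputing every average from raw d."""
    clusters = [frozenset([i]) for i in range(len(d))]
    while len(clusters) > 1:
        best = None
        best_pair = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                avg = np.mean(
                    [d[i, j] for i in clusters[a] for j in clusters[b]]
                )
                if best is None or avg < best - 1e-12:
                    best, best_pair = avg, (a, b)
        if best > cutoff:
            break
        a, b = best_pair
        merged = clusters[a] | clusters[b]
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)] + [merged]
    return sorted(clusters, key=min)


def random_distance_matrix(rng, n):
    m = rng.uniform(0, 0.3, size=(n, n))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0)
    return m


class TestAverageLinkage:
    def test_single_point(self):
        dm = DistanceMatrix(["a"], np.zeros((1, 1)))
        assert average_linkage_clusters(dm, 0.03) == [["a"]]

    def test_post_merge_average_blocks_chaining(self):
        # d(1,2)=0.01 merges; average of {1,2} to 3 is 0.05 > 0.03 -> stays apart
        d = np.array([[0, 0.01, 0.05], [0.01, 0, 0.05], [0.05, 0.05, 0]])
        dm = DistanceMatrix(["1", "2", "3"], d)
        assert average_linkage_clusters(dm, 0.03) == [["1", "2"], ["3"]]

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            average_linkage_clusters(DistanceMatrix([], np.zeros((0, 0))), 0.1)

    def test_matches_naive_agglomeration(self, rng):
        """200 random matrices, n <= 12, against the O(n^3) oracle."""
        for _ in range(200):
            n = int(rng.integers(2, 13))
            d = random_distance_matrix(rng, n)
            cutoff = float(rng.uniform(0.02, 0.25))
            dm = DistanceMatrix([str(i) for i in range(n)], d)
            got = {frozenset(int(x) for x in c)
                   for c in average_linkage_clusters(dm, cutoff)}
            want = set(naive_average_linkage(d, cutoff))
            assert got == want

    def test_matches_scipy_upgma_tree_cut(self, rng):
        """Cutting scipy's UPGMA dendrogram at t reproduces the partition."""
        for _ in range(25):
            n = int(rng.integers(3, 30))
            d = random_distance_matrix(rng, n)
            cutoff = float(rng.uniform(0.02, 0.25))
            dm = DistanceMatrix([str(i) for i in range(n)], d)
            ours = {frozenset(int(x) for x in c)
                    for c in average_linkage_clusters(dm, cutoff)}
            Z = linkage(squareform(d), method="average")
            flat = fcluster(Z, t=cutoff, criterion="distance")
            theirs = {
                frozenset(np.flatnonzero(flat == k).tolist())
                for k in np.unique(flat)
            }
            assert ours == theirs

    def test_monotone_in_cutoff(self, rng):
        d = random_distance_matrix(rng, 15)
        dm = DistanceMatrix([str(i) for i in range(15)], d)
        counts = [
            len(average_linkage_clusters(dm, c))
            for c in (0.0, 0.05, 0.1, 0.2, 0.3)
        ]
        assert counts == sorted(counts, reverse=True)
        assert counts[0] == 15  # cutoff 0 -> singletons (distinct distances)


class TestAverageNeighborCluster:
    def test_partition_covers_all_and_reps_are_members(self, rng):
        seqs = ["ACGTACGTAC", "ACCTACGTAC", "TTTTGGGGCC"]
        t = make_count_table({s: 10 * (i + 1) for i, s in enumerate(seqs)})
        dm = distance_matrix([v.seq for v in t], t.ids)
        part = average_neighbor_cluster(dm, 0.2, t)
        assert sorted(part.member_ids) == sorted(t.ids)
        for otu in part.clusters:
            assert otu.representative in otu.members


class TestAssignClades:
    def test_all_close_one_clade(self):
        seqs = ["ACGTACGTAC" * 5, "ACCTACGTAC" + "ACGTACGTAC" * 4]
        t = make_count_table({s: 5 for s in seqs})
        dm = distance_matrix([v.seq for v in t], t.ids)
        clades = assign_clades(t, dm, 0.15)
        assert len(clades.clades) == 1

    def test_three_simulated_clades_recovered(self, three_clade_genomes):
        from its2otu.simulate import simulate_rdna_library

        seqs, truth = [], {}
        for g in three_clade_genomes:
            pool = simulate_rdna_library(
                g.__class__(**{**g.__dict__, "n_rare_variants": 5}), seed=31
            )
            for s, _ in pool:
                seqs.append(s)
                truth[s] = g.clade_label
        t = make_count_table({s: 10 for s in seqs})
        dm = distance_matrix([v.seq for v in t], t.ids)
        clades = assign_clades(t, dm, 0.15)
        assert len(clades.clades) == 3
        # co-clustered iff same simulated clade
        lookup = {v.id: truth[v.seq] for v in t}
        for clade in clades.clades:
            labels = {lookup[m] for m in clades.members(clade)}
            assert len(labels) == 1


class TestLengthScreen:
    def test_equal_lengths_none_discarded(self):
        vs = [UniqueSequence("A" * 30 + "C" * i, {"s": 1}) for i in range(1)]
        vs = [UniqueSequence("ACGT" * 10, {"s": 2}), UniqueSequence("TTTT" * 10, {"s": 1})]
        retained, discarded = length_screen(vs)
        assert discarded == [] and len(retained) == 2

    def test_single_short_variant_discarded(self):
        long = [UniqueSequence("ACGT" * 75 + "C" * i, {"s": 1}) for i in range(9)]
        short = UniqueSequence("ACGT" * 50, {"s": 1})
        retained, discarded = length_screen(long + [short])
        assert discarded == [short]
        assert len(retained) == 9

    def test_uniform_lengths_match_brute_force(self):
        vs = [UniqueSequence("A" * L + "CGT", {"s": 1}) for L in range(250, 340, 9)]
        n = len(vs)
        retained, discarded = length_screen(vs, 0.90)
        lengths = [len(v.seq) for v in vs]
        for v in vs:
            frac_longer = sum(l > len(v.seq) for l in lengths) / n
            assert (v in discarded) == (frac_longer >= 0.90)


class TestPickRepresentative:
    def test_most_abundant_wins(self):
        x = UniqueSequence("AAAA", {"s": 100})
        y = UniqueSequence("CCCC", {"s": 5})
        assert pick_representative([x, y]) == x.id

    def test_single_member(self):
        x = UniqueSequence("AAAA", {"s": 1})
        assert pick_representative([x]) == x.id

    def test_tie_broken_lexicographically(self):
        x = UniqueSequence("AAC", {"s": 7})
        y = UniqueSequence("AAA", {"s": 7})
        assert pick_representative([x, y]) == y.id


class TestNearestReference:
    DB = ReferenceDB(
        [
            ReferenceEntry("A1", "ACGTACGTCA" * 32),
            ReferenceEntry("B1", "TTGGCCAATG" * 32),
        ]
    )

    def test_exact_match(self):
        hit = nearest_reference("ACGTACGTCA" * 32, self.DB)
        assert hit.type_name == "A1"
        assert hit.percent_identity == 100.0
        assert not hit.tie

    def test_one_substitution_identity(self):
        q = "C" + ("ACGTACGTCA" * 32)[1:]
        hit = nearest_reference(q, self.DB)
        assert hit.type_name == "A1"
        assert hit.percent_identity == pytest.approx(100 * 319 / 320)

    def test_empty_db_rejected(self):
        with pytest.raises(ValueError):
            nearest_reference("ACGT", ReferenceDB([]))

    def test_tie_reported(self):
        db = ReferenceDB(
            [ReferenceEntry("X", "ACGTACGTCA"), ReferenceEntry("Y", "ACGTACGTCA", "dup")]
        )
        hit = nearest_reference("ACGTACGTCA", db)
        assert hit.type_name == "X" and hit.tie


class TestRunPipeline:
    def test_isoclonal_culture_single_dominant_otu(self, small_isoclonal_sample, two_clade_genomes):
        from its2otu.simulate import make_reference_db

        sim, mapping = small_isoclonal_sample
        refdb = make_reference_db(two_clade_genomes[:1])
        result = run_pipeline(sim.reads, mapping, refdb)
        counts = result.otu_table["iso"]
        assert counts.max() / counts.sum() >= 0.99
        top = result.otu_table.loc[counts.idxmax()]
        assert top["type_name"] == two_clade_genomes[0].species_name

    def test_zero_retained_reads_raise_stage_error(self):
        from its2otu.seqio import MappingRow, MappingTable, SequenceRecord

        mapping = MappingTable([MappingRow("s1", "AAAA", "GGGG", "CCCC")])
        reads = [SequenceRecord("r1", "TTTTTTTT")]
        with pytest.raises(PipelineError):
            run_pipeline(reads, mapping)

    def test_read_conservation_into_otu_table(self, small_isoclonal_sample):
        sim, mapping = small_isoclonal_sample
        result = run_pipeline(sim.reads, mapping)
        assert result.otu_table["iso"].sum() == result.table.total_reads
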