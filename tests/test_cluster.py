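"""Greedy two-pass flowgram clustering and the miss histogram."""

import random

import pytest

import ampliflow as af
from ampliflow.cluster import (
    Cluster,
    MissMatrix,
    denoise_reads,
    match_cluster,
    pass1,
    pass2,
)
from ampliflow.distances import DistanceModel

J05 = DistanceModel.constant(0.50)


def _cluster(flows):
    c = Cluster()
    c.add("seed", flows)
    return c


class TestMatchCluster:
    def test_identical_read_matches(self):
        assert match_cluster([1.0, 2.0], _cluster([1.0, 2.0]), J05)

    def test_boundary_value_matches_and_beyond_records_a_miss(self):
        cl = _cluster([1.09, 2.00])
        assert match_cluster([1.59, 2.00], cl, J05)
        misses = MissMatrix()
        assert not match_cluster([1.60, 2.00], cl, J05, misses)
        assert misses.total == 1
        assert misses.counts[109, 160] == 1  # (center 1.09, read 1.60) bin

    def test_length_difference_alone_never_rejects(self):
        cl = _cluster([1.0, 2.0, 3.0, 1.0])
        assert match_cluster([1.0, 2.0], cl, J05)
        assert match_cluster([1.0] , cl, J05)


class TestPass1:
    def test_identical_flowgrams_one_cluster(self):
        reads = [(f"r{i}", [1.0, 2.0]) for i in range(7)]
        clusters = pass1(reads, J05)
        assert len(clusters) == 1
        assert clusters[0].size == 7
        assert clusters[0].center == [1.0, 2.0]

    def test_weighted_average_center(self):
        clusters = pass1([("a", [1.00]), ("b", [1.40])], J05)
        assert len(clusters) == 1
        assert clusters[0].center == [pytest.approx(1.20)]

    def test_far_apart_reads_found_separate_clusters(self):
        clusters = pass1([("a", [1.00]), ("b", [3.00])], J05)
        assert len(clusters) == 2

    def test_longer_read_extends_center_with_count_one(self):
        clusters = pass1([("a", [1.0]), ("b", [1.0, 2.0])], J05)
        (cl,) = clusters
        assert cl.center == [1.0, 2.0]
        assert cl.counts == [2, 1]

    def test_centers_equal_brute_force_means(self):
        rng = random.Random(7)
        reads = []
        for i in range(60):
            base = rng.choice([1.0, 3.0, 6.0])
            ln = rng.randint(3, 8)
            reads.append((f"r{i}", [round(base + rng.uniform(-0.3, 0.3), 2)
                                    for _ in range(ln)]))
        flows_of = dict(reads)
        for cl in pass1(reads, J05):
            for p, center_val in enumerate(cl.center):
                vals = [flows_of[rid][p] for rid, ln in cl.members if ln > p]
                assert center_val == pytest.approx(sum(vals) / len(vals), abs=1e-9)
                assert cl.counts[p] == len(vals)


class TestPass2:
    def test_stable_input_keeps_assignment(self):
        reads = [("a", [1.0]), ("b", [1.0]), ("c", [5.0])]
        clusters = pass1(reads, J05)
        finals, assignment = pass2(reads, clusters, J05)
        assert assignment == {"a": 0, "b": 0, "c": 1}
        assert [c.size for c in finals] == [2, 1]

    def test_drift_case_read_moves_to_more_populous_cluster(self):
        """r2 founded its own cluster in pass 1, but cluster A's center
        drifted toward it; sorted-by-size pass 2 reclaims it."""
        reads = [("r1", [1.00]), ("r2", [1.60]), ("r3", [1.40]), ("r4", [1.40])]
        clusters = pass1(reads, J05)
        assert [c.size for c in clusters] == [3, 1]
        assert clusters[0].center == [pytest.approx(1.2667, abs=1e-3)]
        finals, assignment = pass2(reads, clusters, J05)
        assert assignment["r2"] == 0          # joined the populous cluster
        assert len(finals) == 1               # the emptied cluster is dropped
        assert finals[0].size == 4

    def test_orphan_founds_singleton_after_sorted_list(self):
        reads = [("a", [1.0]), ("b", [1.0])]
        clusters = pass1(reads, J05)
        finals, assignment = pass2(reads + [("z", [9.0])], clusters, J05)
        assert assignment == {"a": 0, "b": 0, "z": 1}
        assert finals[1].center == [9.0]

    def test_conservation(self):
        rng = random.Random(3)
        reads = [(f"r{i}", [round(rng.uniform(0, 4), 2) for _ in range(5)])
                 for i in range(40)]
        result = denoise_reads(reads, J05)
        assert sum(c.size for c in result.clusters) == 40
        assert set(result.assignment) == {rid for rid, _ in reads}


class TestDenoise:
    def test_threshold_infinity_collapses_to_one_cluster(self):
        rng = random.Random(1)
        reads = [(f"r{i}", [round(rng.uniform(0, 6), 2) for _ in range(6)])
                 for i in range(25)]
        result = denoise_reads(reads, DistanceModel.constant(1e9))
        assert len(result.clusters) == 1

    def test_deterministic_given_order_and_model(self):
        rng = random.Random(5)
        reads = [(f"r{i}", [round(rng.uniform(0, 4), 2) for _ in range(4)])
                 for i in range(30)]
        r1 = denoise_reads(reads, J05)
        r2 = denoise_reads(reads, J05)
        assert r1.assignment == r2.assignment
        assert [c.center for c in r1.clusters] == [c.center for c in r2.clusters]

    def test_identical_reads_produce_zero_misses(self):
        reads = [(f"r{i}", [1.0, 2.0]) for i in range(5)]
        result = denoise_reads(reads, J05)
        assert result.misses.total == 0

    def test_miss_total_counts_failed_comparisons(self):
        # two separated groups: each cross-group attempt fails at position 0,
        # in pass 1 and again in pass 2
        reads = [("a", [1.0]), ("b", [1.0]), ("c", [9.0])]
        result = denoise_reads(reads, J05)
        # pass1: c vs center(a,b) -> 1 miss; pass2: c tried against the
        # sorted big cluster -> 1 more
        assert result.misses.total == 2

    def test_empty_bin_is_success(self, tmp_path):
        p = tmp_path / "empty.flows.tsv"
        af.write_flowgrams("empty", [], p, flow_chars="TACG", phase=0)
        result = af.denoise_bin(p, J05)
        assert result.clusters == []
        assert result.assignment == {}


class TestMissMatrix:
    def test_values_clamped_into_range(self):
        m = MissMatrix()
        m.record(12.3, -0.5)
        assert m.counts[m.nbins - 1, 0] == 1

    def test_sparse_tsv_roundtrip(self, tmp_path):
        m = MissMatrix()
        m.record(1.09, 1.60)
        m.record(1.09, 1.60)
        m.record(0.0, 2.0)
        p = tmp_path / "misses.tsv"
        m.to_tsv(p)
        rows = [l.split("\t") for l in p.read_text().splitlines() if not l.startswith("#")]
        assert ["1.09", "1.60", "2"] in rows
        assert ["0.00", "2.00", "1"] in rows
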