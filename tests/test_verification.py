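"""Integration calling: anchor filter, clustering, coordinates, copy number."""

import numpy as np
import pytest

from knockin.mapper import map_pairs
from knockin.simulate import plant_insertion, simulate_locus, simulate_read_pairs
from knockin.verification import (AnchorPair, VerificationError,
                                  assess_copy_number, augment_reference,
                                  call_integrations, cluster_anchors,
                                  collect_anchor_pairs,
                                  collect_split_boundaries, contig_depths)


def make_library(seed, host_len=30_000, cassette_len=700, pos=15_000,
                 zygosity="het", copies=1, depth=20, with_insertion=True):
    host = simulate_locus(host_len, 0.4, seed=seed).seq
    cas = simulate_locus(cassette_len, 0.45, seed=seed + 1000).seq
    if with_insertion:
        alleles, _ = plant_insertion(host, cas, pos, zygosity, copies)
    else:
        alleles = {"wt": host}
    pairs, _ = simulate_read_pairs(alleles, depth, seed=seed + 2000)
    ref = augment_reference({"chr1": host}, {"tag": cas})
    alns = map_pairs(pairs, ref.contigs)
    return ref, alns


class TestAugmentReference:
    def test_host_and_insert_lookup(self):
        ref = augment_reference({"chr1": "ACGT"}, {"eGFP": "TTTT"})
        assert not ref.is_insert("chr1")
        assert ref.is_insert("eGFP")
        with pytest.raises(VerificationError):
            ref.is_insert("chr9")

    def test_duplicate_name_rejected(self):
        with pytest.raises(VerificationError, match="duplicate"):
            augment_reference({"eGFP": "ACGT"}, {"eGFP": "TTTT"})

    def test_fasta_round_trip(self, tmp_path):
        from knockin.io import read_fasta, write_fasta
        seqs = {"chr1": "ACGTACGT", "eGFP": "TTGGCCAA"}
        write_fasta(seqs, tmp_path / "x.fa")
        assert read_fasta(tmp_path / "x.fa") == seqs


class TestAnchorPairs:
    def test_filter_is_exact_xor_of_insert_membership(self):
        ref, alns = make_library(seed=30)
        anchors = collect_anchor_pairs(alns, ref, min_mapq=20)
        anchored_ids = {a.read_id for a in anchors}
        for pa in alns:
            m1, m2 = pa.mate1, pa.mate2
            eligible = (m1.mapped and m2.mapped
                        and min(m1.mapq, m2.mapq) >= 20
                        and ref.is_insert(m1.contig) != ref.is_insert(m2.contig))
            assert eligible == (pa.read_id in anchored_ids)

    def test_anchor_count_tracks_junction_sampling(self):
        # pairs straddle a junction when the fragment covers it but neither
        # read does fully; expected rate ~ 2 sides x per-haplotype depth x
        # (insert_size - read_len)/insert_size junction-spanning fraction
        ref, alns = make_library(seed=31, depth=24)
        anchors = collect_anchor_pairs(alns, ref)
        per_hap = 24 / 2
        expect = 2 * per_hap * (400 - 150) / (2 * 150)
        assert abs(len(anchors) - expect) <= 4 * np.sqrt(expect)

    def test_side_assignment_from_host_orientation(self):
        ref, alns = make_library(seed=32)
        for a in collect_anchor_pairs(alns, ref):
            assert a.side == ("left" if a.host_strand == "+" else "right")


def brute_force_single_linkage(positions, window):
    """All-pairs transitive closure at gap <= window (independent oracle)."""
    n = len(positions)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if abs(positions[i] - positions[j]) <= window:
                pi, pj = find(i), find(j)
                if pi != pj:
                    parent[pi] = pj
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(positions[i])
    return sorted(sorted(g) for g in groups.values())


class TestClustering:
    def test_matches_brute_force_linkage(self):
        rng = np.random.default_rng(0)
        for trial in range(5):
            pos = sorted(int(p) for p in rng.integers(0, 50_000, size=150))
            anchors = [AnchorPair(f"r{i}", "tag", 0, "chr1", p, "+", "left")
                       for i, p in enumerate(pos)]
            clusters, low = cluster_anchors(anchors, cluster_window=500,
                                            min_support=1)
            expect = brute_force_single_linkage(pos, 500)
            got_members = sorted(
                [sorted(pos[i] for i, a in enumerate(anchors)
                        if a.read_id in c.member_ids) for c in clusters])
            assert got_members == expect

    def test_tight_cluster_kept_support_counted(self):
        anchors = [AnchorPair(f"r{i}", "tag", 0, "chr1", 1000 + 10 * i, "+", "left")
                   for i in range(5)]
        clusters, low = cluster_anchors(anchors, 500, min_support=3)
        assert len(clusters) == 1 and clusters[0].support == 5
        assert low == []

    def test_weak_signal_surfaces_in_diagnostics(self):
        # mirrors a weakly supported partial insertion: too few anchors to
        # call, but not silently dropped
        anchors = [AnchorPair("r0", "tag", 0, "chr1", 1000, "+", "left"),
                   AnchorPair("r1", "tag", 0, "chr1", 1100, "+", "left")]
        clusters, low = cluster_anchors(anchors, 500, min_support=3)
        assert clusters == []
        assert len(low) == 1 and low[0].support == 2


class TestIntegrationCalls:
    def test_planted_junction_recovered_exactly_with_split_reads(self):
        ref, alns = make_library(seed=33, pos=15_000)
        anchors = collect_anchor_pairs(alns, ref)
        clusters, _ = cluster_anchors(anchors)
        splits = collect_split_boundaries(alns, ref)
        calls = call_integrations(clusters, splits)
        assert len(calls) == 1
        assert calls[0].split_support >= 1
        assert calls[0].coordinate == 15_000

    def test_no_insertion_no_calls(self):
        ref, alns = make_library(seed=34, with_insertion=False)
        anchors = collect_anchor_pairs(alns, ref)
        clusters, low = cluster_anchors(anchors)
        calls = call_integrations(clusters, collect_split_boundaries(alns, ref))
        assert calls == [] and anchors == []

    def test_two_insertions_on_two_contigs(self):
        hostA = simulate_locus(20_000, 0.4, seed=35).seq
        hostB = simulate_locus(20_000, 0.4, seed=36).seq
        cas = simulate_locus(700, 0.45, seed=37).seq
        allelesA, _ = plant_insertion(hostA, cas, 8_000, "het")
        allelesB, _ = plant_insertion(hostB, cas, 12_000, "het")
        alleles = {"A_" + k: v for k, v in allelesA.items()}
        alleles.update({"B_" + k: v for k, v in allelesB.items()})
        pairs, _ = simulate_read_pairs(alleles, depth=40, seed=38)
        ref = augment_reference({"chrA": hostA, "chrB": hostB}, {"tag": cas})
        alns = map_pairs(pairs, ref.contigs)
        anchors = collect_anchor_pairs(alns, ref)
        clusters, _ = cluster_anchors(anchors)
        calls = call_integrations(clusters, collect_split_boundaries(alns, ref))
        coords = {(c.host_contig, c.coordinate) for c in calls}
        assert coords == {("chrA", 8_000), ("chrB", 12_000)}


class TestCopyNumber:
    def test_het_depth_ratio_converges_to_half(self):
        # expected ratio 0.5; tolerance 3 binomial SDs of the insert-read count
        for depth in (10, 20, 40):
            ref, alns = make_library(seed=40 + depth, depth=depth)
            depths = contig_depths(alns, ref)
            ratio = depths["tag"] / depths["chr1"]
            n_insert_reads = max(depths["tag"] * 700 / 150, 1)
            assert abs(ratio - 0.5) <= 3 * 0.5 / np.sqrt(n_insert_reads)

    def test_classes_across_regimes(self):
        ref, alns = make_library(seed=50)
        anchors = collect_anchor_pairs(alns, ref)
        clusters, _ = cluster_anchors(anchors)
        call = call_integrations(clusters, collect_split_boundaries(alns, ref))[0]
        call = assess_copy_number(alns, call, ref)
        assert call.copy_class == "single_copy_het"
        ref3, alns3 = make_library(seed=51, copies=3)
        anchors3 = collect_anchor_pairs(alns3, ref3)
        clusters3, _ = cluster_anchors(anchors3)
        call3 = call_integrations(clusters3, collect_split_boundaries(alns3, ref3))[0]
        call3 = assess_copy_number(alns3, call3, ref3)
        assert call3.copy_class == "multi_copy_or_concatemer"
        assert call3.depth_ratio > 1.0

    def test_zero_insert_reads_is_partial_class(self):
        ref, alns = make_library(seed=52, with_insertion=False)
        from knockin.verification import IntegrationCall
        call = IntegrationCall("tag", "chr1", 1000, 0, 0, 0)
        call = assess_copy_number(alns, call, ref)
        assert call.depth_ratio == 0.0
        assert call.copy_class == "partial_low_support"

    def test_zero_host_depth_is_error(self):
        ref = augment_reference({"chr1": "A" * 1000}, {"tag": "G" * 100})
        from knockin.verification import IntegrationCall
        with pytest.raises(VerificationError, match="zero host depth"):
            assess_copy_number([], IntegrationCall("tag", "chr1", 5, 0, 0, 0), ref)


class TestDeterminism:
    def test_identical_inputs_identical_calls(self):
        out = []
        for _ in range(2):
            ref, alns = make_library(seed=60)
            anchors = collect_anchor_pairs(alns, ref)
            clusters, _ = cluster_anchors(anchors)
            calls = call_integrations(clusters, collect_split_boundaries(alns, ref))
            out.append([(c.insert_name, c.host_contig, c.coordinate,
                         c.left_support, c.right_support, c.split_support)
                        for c in calls])
        assert out[0] == out[1]
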