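"""Binding-cluster calling, consensus pairing and boundary profiles."""

import numpy as np
import pytest

from clipsplice import (
    AlignedClipRead,
    BindingCluster,
    GenomicInterval,
    boundary_density_profile,
    call_clusters,
    cluster_score,
    consensus_clusters,
    preferred_crosslink_site,
)


def read(start, end, conversions=(), strand="+", chrom="chr1"):
    return AlignedClipRead(
        GenomicInterval(chrom, start, end, strand), tuple(conversions)
    )


class TestCallClusters:
    def test_overlapping_reads_merge(self):
        clusters = call_clusters([read(100, 130, [110]), read(120, 150, [125])])
        assert len(clusters) == 1
        c = clusters[0]
        assert (c.interval.start, c.interval.end) == (100, 150)
        assert c.n_reads == 2 and c.n_converted_reads == 2

    def test_abutting_reads_do_not_merge_under_half_open_coords(self):
        clusters = call_clusters(
            [read(100, 130, [110]), read(100, 130, [111]),
             read(131, 160, [140]), read(131, 160, [141])]
        )
        assert len(clusters) == 2

    def test_min_reads_and_conversion_filters(self):
        # singleton read dropped; unconverted pair dropped
        assert call_clusters([read(0, 30, [10])]) == []
        assert call_clusters([read(0, 30), read(10, 40)]) == []
        kept = call_clusters([read(0, 30), read(10, 40)], require_conversion=False)
        assert len(kept) == 1 and kept[0].preferred_crosslink is None

    def test_pcr_duplicates_collapse_by_default(self):
        dup = [read(0, 30, [5])] * 5 + [read(10, 40, [15])]
        assert call_clusters(dup)[0].n_reads == 2
        assert call_clusters(dup, collapse_duplicates=False)[0].n_reads == 6

    def test_conversion_outside_read_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            read(100, 130, [130])

    def test_opposite_strands_never_merge(self):
        clusters = call_clusters(
            [read(0, 30, [5]), read(0, 30, [5], strand="-"),
             read(10, 40, [15]), read(10, 40, [15], strand="-")]
        )
        assert len(clusters) == 2
        assert {c.interval.strand for c in clusters} == {"+", "-"}

    def test_matches_union_find_oracle_on_random_reads(self, rng):
        reads = []
        for _ in range(500):
            start = int(rng.integers(0, 5000))
            length = int(rng.integers(20, 40))
            chrom = f"chr{rng.integers(1, 3)}"
            strand = "+" if rng.random() < 0.5 else "-"
            conv = (start + int(rng.integers(0, length)),)
            reads.append(read(start, start + length, conv, strand, chrom))

        # oracle: union-find over the pairwise-overlap graph
        parent = list(range(len(reads)))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(len(reads)):
            for j in range(i + 1, len(reads)):
                a, b = reads[i].interval, reads[j].interval
                if a.chrom == b.chrom and a.strand == b.strand and \
                        a.start < b.end and b.start < a.end:
                    parent[find(i)] = find(j)
        groups = {}
        for i in range(len(reads)):
            groups.setdefault(find(i), []).append(i)
        expected = set()
        for members in groups.values():
            if len(members) < 2:
                continue
            ivs = [reads[m].interval for m in members]
            expected.add(
                (ivs[0].chrom, ivs[0].strand,
                 min(v.start for v in ivs), max(v.end for v in ivs), len(members))
            )

        called = call_clusters(reads, collapse_duplicates=False)
        got = {
            (c.interval.chrom, c.interval.strand, c.interval.start,
             c.interval.end, c.n_reads)
            for c in called
        }
        assert got == expected

    def test_idempotent_on_own_clusters(self, rng):
        reads = [
            read(int(s), int(s) + 30, [int(s) + 3])
            for s in rng.integers(0, 2000, size=200)
        ]
        first = call_clusters(reads, collapse_duplicates=False)
        for c in first:
            member_reads = [
                r for r in reads
                if c.interval.start <= r.interval.start and r.interval.end <= c.interval.end
            ]
            again = call_clusters(member_reads, collapse_duplicates=False)
            assert len(again) == 1
            assert again[0].interval == c.interval
            assert again[0].preferred_crosslink == c.preferred_crosslink


class TestPreferredCrosslink:
    @pytest.mark.parametrize(
        "conv, expected",
        [({110: 5, 112: 3}, 110), ({110: 4, 115: 4}, 110), ({200: 1}, 200)],
    )
    def test_argmax_with_leftmost_ties(self, conv, expected):
        assert preferred_crosslink_site(conv) == expected

    def test_empty_map_is_an_error(self):
        with pytest.raises(ValueError):
            preferred_crosslink_site({})


def make_cluster(start, end, crosslink, strand="+", n_conv=3):
    return BindingCluster(
        GenomicInterval("chr1", start, end, strand),
        n_reads=n_conv + 1,
        n_converted_reads=n_conv,
        conversions_per_position={crosslink: n_conv},
        preferred_crosslink=crosslink,
    )


class TestConsensus:
    def test_reciprocal_containment_pairs(self):
        pairs = consensus_clusters(
            [make_cluster(100, 120, 110)], [make_cluster(105, 125, 112)]
        )
        assert len(pairs) == 1
        assert pairs[0].crosslink == 110  # replicate 1's crosslink adopted

    def test_one_way_containment_is_not_enough(self):
        pairs = consensus_clusters(
            [make_cluster(100, 120, 110)], [make_cluster(105, 135, 130)]
        )
        assert pairs == []

    def test_set_symmetric_under_replicate_swap(self, rng):
        rep1, rep2 = _simulated_replicate_clusters(rng, n_sites=40)
        forward = consensus_clusters(rep1, rep2)
        backward = consensus_clusters(rep2, rep1)
        fw = {(id(p.rep1), id(p.rep2)) for p in forward}
        bw = {(id(p.rep2), id(p.rep1)) for p in backward}
        assert fw == bw
        assert len(forward) <= min(len(rep1), len(rep2))

    def test_matches_quadratic_oracle(self, rng):
        rep1, rep2 = _simulated_replicate_clusters(rng, n_sites=80, per_site=(3, 2))
        assert len(rep1) >= 200 and len(rep2) >= 150

        # oracle: all-pairs reciprocal-containment check + greedy distance resolution
        candidates = []
        for i, a in enumerate(rep1):
            for j, b in enumerate(rep2):
                if a.interval.chrom != b.interval.chrom or \
                        a.interval.strand != b.interval.strand:
                    continue
                if b.interval.contains(a.preferred_crosslink) and \
                        a.interval.contains(b.preferred_crosslink):
                    candidates.append(
                        (abs(a.preferred_crosslink - b.preferred_crosslink), i, j)
                    )
        candidates.sort()
        used1, used2, expected = set(), set(), set()
        for dist, i, j in candidates:
            if i in used1 or j in used2:
                continue
            used1.add(i)
            used2.add(j)
            expected.add((i, j))

        idx1 = {id(c): i for i, c in enumerate(rep1)}
        idx2 = {id(c): j for j, c in enumerate(rep2)}
        got = {
            (idx1[id(p.rep1)], idx2[id(p.rep2)])
            for p in consensus_clusters(rep1, rep2)
        }
        assert got == expected


def _simulated_replicate_clusters(rng, n_sites=80, per_site=(1, 1)):
    """Clusters drawn around shared true sites, several per site and replicate."""
    sites = np.sort(rng.choice(np.arange(500, 100000, 120), size=n_sites, replace=False))
    reps = []
    for k in (0, 1):
        clusters = []
        for s in sites:
            for _ in range(per_site[k]):
                start = int(s) - int(rng.integers(5, 25))
                end = int(s) + int(rng.integers(5, 25))
                xl = int(np.clip(s + rng.integers(-3, 4), start, end - 1))
                clusters.append(make_cluster(start, end, xl))
        reps.append(clusters)
    return reps


class TestScore:
    def test_values_and_monotonicity(self):
        assert cluster_score(make_cluster(0, 10, 5, n_conv=0)) == 0.0
        assert cluster_score(make_cluster(0, 10, 5, n_conv=7)) == 3.0
        counts = [0, 1, 5, 7, 20]
        scores = [cluster_score(make_cluster(0, 10, 5, n_conv=c)) for c in counts]
        assert scores == sorted(scores)


class TestBoundaryProfile:
    def test_crosslink_exactly_at_acceptor(self, plus_gene):
        # last intronic base of intron 0 is position 19; window small enough
        # that the second acceptor (39) is out of reach
        c = make_cluster(12, 25, 19)
        profile = boundary_density_profile([c], [plus_gene], window=15, which="intron-exon")
        n_boundaries = 2
        assert profile[15] == pytest.approx(1.0 / n_boundaries)
        assert profile.sum() == pytest.approx(1.0 / n_boundaries)

    def test_minus_strand_offsets_are_transcript_oriented(self, minus_gene):
        # upstream intron (transcript order) is (30,40); its acceptor base is 30;
        # a crosslink 5 nt into the intron (genomic 35) must land at offset -5
        c = make_cluster(31, 39, 35, strand="-")
        profile = boundary_density_profile([c], [minus_gene], window=50, which="intron-exon")
        assert profile[50 - 5] > 0

    def test_empty_items_give_zero_profile(self, plus_gene):
        profile = boundary_density_profile([], [plus_gene], window=20)
        assert profile.shape == (41,)
        assert not profile.any()

    def test_reads_use_full_coverage(self, plus_gene):
        r = read(5, 15, [9])  # covers the donor at offset 0 (first intronic base = 10)
        profile = boundary_density_profile([r], [plus_gene], window=10, which="exon-intron")
        # 10 covered positions fall in the +-10 window around position 10
        assert profile.sum() * 2 == pytest.approx(10)
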