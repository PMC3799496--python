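"""Binding-splicing integration: proximity, splicing map, CDFs, splice-site PWMs."""

import numpy as np
import pytest

from clipsplice import (
    GeneModel,
    GenomicInterval,
    SimulationConfig,
    binding_proximity,
    flanking_splice_sites,
    group_effect_cdf,
    intron_retention_association,
    proximity_table,
    simulate_genome,
    splice_site_strength,
    splicing_map,
    train_splice_site_model,
)
from clipsplice.clusters import BindingCluster, ConsensusCluster
from clipsplice.splicemap import score_window


def make_consensus(crosslink, strand="+", chrom="chr1", pad=10):
    cluster = BindingCluster(
        GenomicInterval(chrom, crosslink - pad, crosslink + pad, strand),
        n_reads=5, n_converted_reads=4,
        conversions_per_position={crosslink: 4},
        preferred_crosslink=crosslink,
    )
    return ConsensusCluster(cluster, cluster, crosslink=crosslink)


@pytest.fixture
def wide_gene():
    """Four exons with 200-nt introns: room for 150-nt proximity windows."""
    exons = [GenomicInterval("chr1", s, s + 100, "+") for s in (0, 300, 600, 900)]
    return GeneModel("wide", exons)


class TestBindingProximity:
    def test_crosslink_inside_downstream_intron_near_acceptor(self, wide_gene):
        ctx = flanking_splice_sites(1, wide_gene)  # downstream intron (400, 600)
        # 100 nt into the downstream intron from its acceptor (position 599)
        prof = binding_proximity([make_consensus(499)], ctx, max_dist=150)
        assert prof.flags == {
            "up5ss": False, "up3ss": False, "down5ss": True, "down3ss": True
        }
        assert prof.n_sites_bound == 2

    def test_distant_crosslink_sets_no_flags(self, wide_gene):
        ctx = flanking_splice_sites(1, wide_gene)
        prof = binding_proximity([make_consensus(2000)], ctx, max_dist=150)
        assert prof.n_sites_bound == 0

    def test_exonic_crosslink_needs_the_relaxed_rule(self, wide_gene):
        ctx = flanking_splice_sites(1, wide_gene)  # exon (300, 400)
        strict = binding_proximity([make_consensus(350)], ctx, max_dist=150)
        assert strict.n_sites_bound == 0
        relaxed = binding_proximity(
            [make_consensus(350)], ctx, max_dist=150, include_exonic_side=True
        )
        assert relaxed.flags["up3ss"] and relaxed.flags["down5ss"]

    def test_table_is_invariant_under_consensus_order(self, wide_gene):
        contexts = [flanking_splice_sites(i, wide_gene) for i in (1, 2)]
        consensus = [make_consensus(x) for x in (450, 550, 650)]
        a = proximity_table(consensus, contexts)
        b = proximity_table(consensus[::-1], contexts)
        assert a.equals(b)


class TestSplicingMap:
    def test_single_crosslink_lands_in_its_bin(self, wide_gene):
        ctx = flanking_splice_sites(1, wide_gene)
        # 70 nt upstream of the downstream-intron acceptor (599)
        consensus = [make_consensus(599 - 70)]
        (profile,) = splicing_map(
            consensus, {"g": {ctx.exon_id}}, {ctx.exon_id: ctx},
            window=300, bin_size=5,
        )
        dens = profile.densities["down3ss"]
        edges = profile.bin_edges
        hit_bin = np.digitize(-70, edges) - 1
        assert dens[hit_bin] == 1.0
        assert profile.integral("down3ss") == 1.0

    def test_density_conservation(self, wide_gene):
        contexts = {
            ctx.exon_id: ctx
            for ctx in (flanking_splice_sites(i, wide_gene) for i in (1, 2))
        }
        rng = np.random.default_rng(0)
        consensus = [make_consensus(int(x)) for x in rng.integers(100, 900, 60)]
        (profile,) = splicing_map(
            consensus, {"all": set(contexts)}, contexts, window=100, bin_size=5
        )
        for anchor in ("up5ss", "up3ss", "down5ss", "down3ss"):
            hits = 0
            for ctx in contexts.values():
                site = ctx.sites[anchor]
                hits += sum(
                    1 for c in consensus if site - 100 <= c.crosslink < site + 101
                )
            assert profile.integral(anchor) * profile.n_exons == pytest.approx(hits)

    def test_empty_group_warns_and_zeroes(self, wide_gene):
        ctx = flanking_splice_sites(1, wide_gene)
        with pytest.warns(UserWarning, match="empty"):
            (profile,) = splicing_map([], {"none": set()}, {ctx.exon_id: ctx})
        assert all(not profile.densities[a].any() for a in profile.densities)


class TestGroupCdf:
    def test_identical_group_matches_background(self, rng):
        values = {f"e{i}": float(v) for i, v in enumerate(rng.normal(0, 1, 200))}
        ids = list(values)
        cdfs = group_effect_cdf(values, {"bg": set(ids), "grp": set(ids)}, "bg")
        assert np.allclose(cdfs.cdfs["bg"], cdfs.cdfs["grp"])
        assert cdfs.comparisons.loc[0, "p"] > 0.001

    def test_location_shift_detected(self, rng):
        bg = {f"b{i}": float(v) for i, v in enumerate(rng.normal(0, 1, 100))}
        grp = {f"g{i}": float(v) for i, v in enumerate(rng.normal(-1, 1, 100))}
        values = {**bg, **grp}
        cdfs = group_effect_cdf(values, {"bg": set(bg), "grp": set(grp)}, "bg")
        assert cdfs.comparisons.loc[0, "p"] < 0.01
        assert np.all(cdfs.cdfs["grp"] >= cdfs.cdfs["bg"] - 1e-12)  # left shift

    def test_small_group_comparison_skipped(self, rng):
        values = {f"e{i}": float(i) for i in range(30)}
        with pytest.warns(UserWarning, match="too small"):
            cdfs = group_effect_cdf(
                values, {"bg": set(values), "tiny": {"e1", "e2"}}, "bg"
            )
        assert np.isnan(cdfs.comparisons.loc[0, "p"])

    def test_monotone_ordering_with_additive_effects(self, rng):
        groups, values = {}, {}
        for k in range(4):
            members = set()
            for i in range(120):
                fid = f"k{k}_{i}"
                values[fid] = float(rng.normal(-0.8 * k, 1.0))
                members.add(fid)
            groups[f"bound_{k}"] = members
        cdfs = group_effect_cdf(values, groups, "bound_0")
        medians = [np.median(cdfs.values[f"bound_{k}"]) for k in range(4)]
        assert medians == sorted(medians, reverse=True)
        # stochastic ordering: each CDF dominates the previous one
        for k in range(1, 4):
            diff = cdfs.cdfs[f"bound_{k}"] - cdfs.cdfs[f"bound_{k - 1}"]
            assert diff.mean() > 0


class TestIntronRetentionAssociation:
    def test_grouped_intron_z_values_are_routed_by_side(self, wide_gene):
        z_pir = {"wide:I0": 0.5, "wide:I1": 2.0, "wide:I2": -0.3}
        groups = {"bg": {"wide:E1", "wide:E2"}, "skipped": {"wide:E1"}}
        out = intron_retention_association(z_pir, groups, [wide_gene], "bg")
        assert set(out) == {"upstream", "downstream"}
        assert set(out["upstream"].values["skipped"]) == {0.5}
        assert set(out["downstream"].values["skipped"]) == {2.0}

    def test_missing_pir_counted_and_excluded(self, wide_gene):
        z_pir = {"wide:I0": 0.5}  # I1, I2 missing
        groups = {"bg": {"wide:E1", "wide:E2"}}
        with pytest.warns(UserWarning, match="lacked PIR"):
            out = intron_retention_association(z_pir, groups, [wide_gene], "bg")
        assert out["downstream"].values["bg"].size == 0


@pytest.fixture(scope="module")
def trained_model():
    config = SimulationConfig(seed=33, n_genes=500)
    genes, sequences, _ = simulate_genome(config)
    model = train_splice_site_model(genes, sequences)
    return genes, sequences, model


class TestSpliceSiteModel:
    def test_columns_sum_to_one(self, trained_model):
        _, _, model = trained_model
        for kind in ("5ss", "3ss"):
            probs = model.probabilities(kind)
            assert np.allclose(probs.sum(axis=1), 1.0)

    def test_recovers_planted_composition(self, trained_model):
        _, _, model = trained_model
        donor = model.probabilities("5ss")  # 3 exonic + 6 intronic positions
        # fixed GT at the first two intronic bases, random elsewhere
        assert donor[3, 2] > 0.97 and donor[4, 3] > 0.97  # G then T
        for pos in (0, 1, 2, 5, 6, 7, 8):
            assert np.all(np.abs(donor[pos] - 0.25) < 0.03)
        acceptor = model.probabilities("3ss")  # 20 intronic + 3 exonic
        assert acceptor[18, 0] > 0.97 and acceptor[19, 2] > 0.97  # A then G

    def test_score_equals_hand_summed_log_odds(self, trained_model):
        _, _, model = trained_model
        window = "ACGGTACGT"
        probs = model.probabilities("5ss")
        base_index = {b: i for i, b in enumerate("ACGT")}
        expected = sum(
            np.log2(probs[i, base_index[b]] / model.background[b])
            for i, b in enumerate(window)
        )
        assert score_window(window, "5ss", model) == pytest.approx(expected, rel=1e-6)

    def test_consensus_window_is_maximal(self, trained_model, rng):
        _, _, model = trained_model
        probs = model.probabilities("3ss")
        consensus = "".join("ACGT"[i] for i in probs.argmax(axis=1))
        best = score_window(consensus, "3ss", model)
        for _ in range(50):
            random_window = "".join(rng.choice(list("ACGT"), size=len(consensus)))
            assert score_window(random_window, "3ss", model) <= best

    def test_uniform_model_scores_zero(self):
        from Bio import motifs
        from Bio.Seq import Seq

        from clipsplice.splicemap import SpliceSiteModel

        flat = motifs.create([Seq(b * 9) for b in "ACGT"]).counts.normalize(
            pseudocounts=1.0
        )
        model = SpliceSiteModel(flat, flat, {b: 0.25 for b in "ACGT"})
        assert score_window("ACGTACGTA", "5ss", model) == pytest.approx(0.0)

    def test_annotated_sites_score_above_random_windows(self, trained_model, rng):
        genes, sequences, model = trained_model
        gene = genes[0]
        real = splice_site_strength(sequences, gene, 0, "5ss", model)
        assert real is not None
        random_scores = [
            score_window("".join(rng.choice(list("ACGT"), size=9)), "5ss", model)
            for _ in range(30)
        ]
        assert real.score > np.median(random_scores)

    def test_too_few_training_sites_is_an_error(self):
        config = SimulationConfig(seed=2, n_genes=3)
        genes, sequences, _ = simulate_genome(config)
        with pytest.raises(ValueError, match="supply a pre-trained"):
            train_splice_site_model(genes, sequences, min_sites=1000)
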