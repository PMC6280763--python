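"""Ground-truth generator: genomes, libraries, degradation, two conditions."""

import numpy as np
import pandas as pd
import pytest

from cageforge import clustering as cl
from cageforge import expression as ex
from cageforge import normalization as nm
from cageforge import seqfeatures as sf
from cageforge import synthetic as syn


class TestGenerateGenome:
    def test_truth_record_per_promoter(self, small_world):
        assert small_world["truth"].n_promoters == 120
        assert len(small_world["genome"]["chr1"]) == 300_000

    def test_sharp_promoters_carry_tata(self, small_world):
        """PWM scanning of truth dominant positions finds the implanted
        TATA element in >= 90% of sharp promoters."""
        truth = small_world["truth"].promoters
        genome = small_world["genome"]
        pwm = sf.tata_pwm()
        for klass, expected in (("sharp", True), ("broad", False)):
            sub = truth[truth["promoter_class"] == klass]
            hits = 0
            for row in sub.itertuples(index=False):
                seq = sf.oriented_window(genome, row.chrom, row.dominant_pos,
                                         row.strand, -35, -25 + pwm.length - 1)
                scores = pwm.scan(seq)
                hits += np.nanmax(scores) >= pwm.threshold
            rate = hits / len(sub)
            assert (rate >= 0.9) if expected else (rate < 0.2)

    def test_broad_islands_are_gc_elevated(self, small_world):
        genome = small_world["genome"]["chr1"]
        truth = small_world["truth"].promoters
        broad = truth[truth["promoter_class"] == "broad"]
        gcs = []
        for row in broad.itertuples(index=False):
            s = genome[int(row.island_start) - 1:int(row.island_end)]
            gcs.append((s.count("G") + s.count("C")) / len(s))
        background_gc = small_world["truth"].params["gc"]
        assert np.mean(gcs) > background_gc + 0.10

    def test_initiator_written_at_minus_one_plus_one(self, small_world):
        genome = small_world["genome"]
        for row in small_world["truth"].promoters.head(30).itertuples(index=False):
            seq = sf.oriented_window(genome, row.chrom, row.dominant_pos,
                                     row.strand, -1, 0)
            assert seq == row.initiator

    def test_overcrowded_genome_rejected(self):
        with pytest.raises(ValueError, match="overcrowded"):
            syn.generate_genome(n_promoters=100, chrom_length=50_000)


class TestSimulateLibrary:
    def test_total_tags_equal_depth(self, small_world):
        assert small_world["table"]["count"].sum() == 200_000

    def test_all_positions_on_emitted_chromosome(self, small_world):
        table = small_world["table"]
        L = small_world["truth"].chrom_length
        assert (table["chrom"] == "chr1").all()
        assert table["pos"].between(1, L).all()

    def test_dominant_ctss_recovered(self, small_world):
        """Clustering recovers each promoter's true dominant CTSS."""
        truth = small_world["truth"].promoters
        dom = {(r.chrom, r.strand, r.dominant_pos)
               for r in truth.itertuples(index=False)}
        hits = sum((c.chrom, c.strand, c.dominant_pos) in dom
                   for c in small_world["clusters"])
        assert hits / len(truth) >= 0.95

    def test_bit_reproducible_under_seed(self, small_world):
        again = syn.simulate_library(small_world["truth"],
                                     depth_tags=200_000, seed=0)
        pd.testing.assert_frame_equal(again, small_world["table"])

    def test_fitted_slope_matches_configured(self):
        """The dominant-CTSS count distribution inherits the configured
        power-law slope.  A sharp-only genome is used so that CTSS counts
        track promoter weights (broad promoters split their tags over many
        positions, which reshapes the CTSS-level tail), and the depth is
        chosen so the count-distribution body sits below the fit window."""
        genome, truth = syn.generate_genome(n_promoters=2000,
                                            sharp_fraction=1.0,
                                            chrom_length=2_100_000, seed=2)
        table = syn.simulate_library(truth, depth_tags=60_000, seed=2,
                                     slope=1.25)
        fit = nm.fit_power_law(table, fit_range=(10, 1000))
        assert fit.alpha == pytest.approx(1.25, abs=0.1)

    def test_depth_below_promoter_count_rejected(self, small_world):
        with pytest.raises(ValueError, match="depth"):
            syn.simulate_library(small_world["truth"], depth_tags=10)


class TestDegradation:
    def test_identity_case(self, small_world):
        out = syn.simulate_degradation(small_world["table"], 1.0,
                                       pcr_cycles=0, g_bias=0.0, seed=0)
        pd.testing.assert_frame_equal(out, small_world["table"])

    def test_subsampling_sharpens_broad_library(self, broad_world):
        deep_med = np.median([c.iq_width for c in broad_world["clusters"]])
        degraded = syn.simulate_degradation(broad_world["table"], 0.01, seed=0)
        shallow = cl.cluster_ctss(nm.normalize(degraded))
        assert np.median([c.iq_width for c in shallow]) < deep_med

    def test_pcr_resampling_restores_depth(self, small_world):
        out = syn.simulate_degradation(small_world["table"], 0.05,
                                       pcr_cycles=10, pcr_efficiency=0.8,
                                       seed=0)
        assert out["count"].sum() == small_world["table"]["count"].sum()
        # duplicate inflation: far fewer distinct CTSSs than the parent
        assert len(out) < 0.5 * len(small_world["table"])

    def test_g_bias_raises_g_share(self, small_world):
        genome = small_world["genome"]

        def g_share(table):
            comp = sf.ctss_composition(table, genome)
            return comp["base_freq"].get("G", 0.0)

        biased = syn.simulate_degradation(small_world["table"], 0.5,
                                          g_bias=0.8, genome=genome, seed=0)
        assert g_share(biased) > g_share(small_world["table"])

    def test_invalid_parameters(self, small_world):
        with pytest.raises(ValueError):
            syn.simulate_degradation(small_world["table"], 0.0)
        with pytest.raises(ValueError):
            syn.simulate_degradation(small_world["table"], 0.5, g_bias=1.0)


class TestSpikeCarrier:
    def test_zero_leftover_is_identity(self, small_world):
        from cageforge import carrier as ca
        design = ca.design_carrier()
        out = syn.spike_carrier(small_world["table"], design, 0.0, seed=0)
        assert (out["origin"] == "sample").all()
        pd.testing.assert_frame_equal(out.drop(columns="origin"),
                                      small_world["table"])

    def test_leftover_share_observed(self, small_world):
        from cageforge import carrier as ca
        design = ca.design_carrier()
        out = syn.spike_carrier(small_world["table"], design, 0.27, seed=0)
        share = out.loc[out["origin"] == "carrier", "count"].sum() \
            / out["count"].sum()
        assert share == pytest.approx(0.27, abs=0.01)

    def test_flags_partition_table(self, small_world):
        from cageforge import carrier as ca
        design = ca.design_carrier()
        out = syn.spike_carrier(small_world["table"], design, 0.1, seed=0)
        assert set(out["origin"]) == {"sample", "carrier"}
        assert (out.loc[out["origin"] == "carrier", "chrom"] == "carrier").all()
        assert (out.loc[out["origin"] == "sample", "chrom"] == "chr1").all()


@pytest.fixture(scope="module")
def experiment():
    genome, truth = syn.generate_genome(n_promoters=100, sharp_fraction=0.5,
                                        chrom_length=250_000, seed=4)
    ta, tb, truth2 = syn.generate_two_conditions(
        truth, n_specific_a=10, n_specific_b=10, n_switch=8,
        switch_distance=30, depth_tags=300_000, seed=4)
    ca_ = cl.cluster_ctss(nm.normalize(ta))
    cb = cl.cluster_ctss(nm.normalize(tb))
    cons = cl.merge_consensus({"a": ca_, "b": cb})
    return {"truth": truth2, "cons": cons, "ta": ta, "tb": tb}


class TestTwoConditions:

    def test_switches_recovered_at_implanted_distance(self, experiment):
        events, med = ex.detect_switching(experiment["cons"], "a", "b",
                                          min_tpm=5, min_distance=10)
        implanted = experiment["truth"].switching_events
        got = {(e.chrom, e.strand, e.dominant_a) for e in events}
        want = {(r.chrom, r.strand, r.dominant_a)
                for r in implanted.itertuples(index=False)}
        assert len(want & got) / len(want) >= 0.95
        assert med == pytest.approx(30, abs=2)

    def test_no_false_switches_between_identical_samples(self, experiment):
        ca_ = cl.cluster_ctss(nm.normalize(experiment["ta"]))
        cons = cl.merge_consensus({"a": ca_, "b": ca_})
        events, _ = ex.detect_switching(cons, "a", "b", min_tpm=5,
                                        min_distance=10)
        assert events == []

    def test_specific_promoters_separate_on_som(self, experiment):
        truth = experiment["truth"].promoters
        cons = experiment["cons"]
        matrix = ex.build_matrix(cons, ["a", "b"], min_tpm=1)
        labels = ex.som_cluster(matrix, grid=(4, 2), seed=0)["labels"]
        # map consensus rows back to truth roles via dominant positions
        kept = cons.iloc[matrix.row_index]
        roles = []
        dom_role = {(r.chrom, r.strand, r.dominant_pos): r.role
                    for r in truth.itertuples(index=False)}
        for row in kept.itertuples(index=False):
            roles.append(dom_role.get((row.chrom, row.strand,
                                       row.dominant_a), "other"))
        roles = np.array(roles)
        la = set(labels[roles == "A"])
        lb = set(labels[roles == "B"])
        assert la and lb and not (la & lb)

    def test_ubiquitous_promoters_correlate_across_conditions(self, experiment):
        """Promoters without implanted condition effects share their
        expression weight, so their consensus-level expression agrees."""
        truth = experiment["truth"].promoters
        cons = experiment["cons"]
        ubiq = {(r.chrom, r.strand, r.dominant_pos)
                for r in truth[truth["role"] == "ubiquitous"]
                .itertuples(index=False)}
        mask = [(row.chrom, row.strand, row.dominant_a) in ubiq
                for row in cons.itertuples(index=False)]
        sub = cons[np.array(mask)]
        r = np.corrcoef(sub["tpm_a"], sub["tpm_b"])[0, 1]
        assert len(sub) > 30 and r >= 0.95

    def test_role_counts_validated(self, small_world):
        with pytest.raises(ValueError, match="exceed"):
            syn.generate_two_conditions(small_world["truth"], 100, 100, 100)
        with pytest.raises(ValueError, match="switch_distance"):
            syn.generate_two_conditions(small_world["truth"], 1, 1, 1,
                                        switch_distance=0)
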