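"""Promoter-architecture sequence analysis."""

import numpy as np
import pandas as pd
import pytest

from cageforge import clustering as cl
from cageforge import seqfeatures as sf
from cageforge._util import revcomp


def ctss(entries):
    df = pd.DataFrame(entries, columns=["chrom", "pos", "strand"])
    df["count"] = 1
    df["tpm"] = 1.0
    return df


def toy_clusters(entries, **kw):
    df = pd.DataFrame(entries, columns=["chrom", "pos", "strand", "tpm"])
    df["count"] = 1
    return cl.cluster_ctss(df, min_tpm=0, **kw)


class TestComposition:
    def test_plus_strand_initiator(self):
        genome = {"c": "TTTTCATTTT"}  # CTSS at pos 6 reads ...C,A...
        res = sf.ctss_composition(ctss([("c", 6, "+")]), genome)
        assert res["dinuc_freq"].idxmax() == "CA"
        assert res["base_freq"].idxmax() == "A"

    def test_minus_strand_reverse_complemented(self):
        genome = {"c": "TTTTTGTTTT"}  # + strand reads TG at 5-6
        res = sf.ctss_composition(ctss([("c", 5, "-")]), genome)
        assert res["dinuc_freq"].idxmax() == "CA"

    def test_frequencies_sum_to_one(self, small_world):
        res = sf.ctss_composition(small_world["normalized"],
                                  small_world["genome"])
        assert res["base_freq"].sum() == pytest.approx(1.0, abs=1e-12)
        assert res["dinuc_freq"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_edge_ctss_excluded(self):
        genome = {"c": "ACGT"}
        res = sf.ctss_composition(ctss([("c", 1, "+"), ("c", 3, "+")]), genome)
        assert res["n_excluded"] == 1

    def test_strand_symmetry(self, small_world):
        """Reverse-complementing the genome and flipping all CTSSs leaves
        composition unchanged."""
        genome = small_world["genome"]
        table = small_world["normalized"]
        L = len(genome["chr1"])
        mirrored_genome = {"chr1": revcomp(genome["chr1"])}
        mirrored = table.copy()
        mirrored["pos"] = L - mirrored["pos"] + 1
        mirrored["strand"] = np.where(mirrored["strand"] == "+", "-", "+")
        a = sf.ctss_composition(table, genome)
        b = sf.ctss_composition(mirrored, mirrored_genome)
        pd.testing.assert_series_equal(a["dinuc_freq"], b["dinuc_freq"])


class TestDinucDensity:
    def test_poly_a_genome(self):
        genome = {"c": "A" * 2000}
        clusters = toy_clusters([("c", 1000, "+", 5.0)])
        ww = sf.dinuc_density_matrix(clusters, genome, "WW", flank=100,
                                     smooth=None)
        gc = sf.dinuc_density_matrix(clusters, genome, "GC", flank=100,
                                     smooth=None)
        assert (ww["matrix"] == 1).all() and (gc["matrix"] == 0).all()

    def test_unsmoothed_entries_are_binary(self, small_world):
        res = sf.dinuc_density_matrix(small_world["clusters"][:20],
                                      small_world["genome"], "TA",
                                      flank=100, smooth=None)
        assert set(np.unique(res["matrix"])) <= {0.0, 1.0}

    def test_rows_sorted_by_iq_width(self, small_world):
        res = sf.dinuc_density_matrix(small_world["clusters"],
                                      small_world["genome"], "TA", flank=50,
                                      smooth=None)
        assert (np.diff(res["iq_widths"]) >= 0).all()

    def test_ta_peak_recovered_at_minus_30_in_sharp_promoters(self, small_world):
        """The implanted TATA element shows as a TA-density peak upstream of
        sharp promoters but not in the broad block."""
        sharp = [c for c in small_world["clusters"] if c.shape_class == "sharp"]
        broad = [c for c in small_world["clusters"] if c.shape_class == "broad"]
        res_s = sf.dinuc_density_matrix(sharp, small_world["genome"], "TA",
                                        flank=100, smooth=None)
        res_b = sf.dinuc_density_matrix(broad, small_world["genome"], "TA",
                                        flank=100, smooth=None)
        win = (res_s["offsets"] >= -32) & (res_s["offsets"] <= -24)
        bg = (res_s["offsets"] >= 40) & (res_s["offsets"] <= 100)
        # the TATA element makes a TA column shared by ~all sharp rows
        assert res_s["matrix"][:, win].max(axis=0).max() > 0.9
        assert res_s["matrix"][:, win].mean(axis=0).max() > \
            5 * res_s["matrix"][:, bg].mean()
        assert res_s["matrix"][:, win].mean() > 3 * res_b["matrix"][:, win].mean()

    def test_bad_pattern_rejected(self, small_world):
        with pytest.raises(ValueError, match="IUPAC"):
            sf.dinuc_density_matrix(small_world["clusters"],
                                    small_world["genome"], "TAX")


class TestPWM:
    def test_consensus_scores_max_and_hits(self):
        pwm = sf.tata_pwm()
        assert pwm.score(pwm.consensus()) == pytest.approx(pwm.max_score)
        assert pwm.score(pwm.consensus()) >= pwm.threshold

    def test_toy_two_column_threshold_arithmetic(self):
        # per column: A scores 1, C scores 0 -> "AC" scores 1 = min + 0.5*range
        matrix = np.array([[1.0, 1.0], [0.0, 0.0],
                           [0.0, 0.0], [0.0, 0.0]])
        pwm = sf.PWM(matrix=matrix, threshold_fraction=0.8)
        assert pwm.score("AC") == 1.0
        assert pwm.score("AC") < pwm.threshold  # 1 < 0 + 0.8*2
        assert pwm.score("AA") >= pwm.threshold

    def test_gc_random_sequence_rarely_hits_tata(self, rng):
        genome = {"c": "".join(rng.choice(list("GC"), 120_000))}
        clusters = toy_clusters([("c", int(p), "+", 5.0)
                                 for p in range(500, 120_000 - 500, 119)])
        res = sf.scan_pwm(clusters, genome, sf.tata_pwm())
        assert res["percent_with_hit"] < 5.0

    def test_hits_equal_brute_force_scorer(self, small_world):
        """scan_pwm hit flags equal an independent exhaustive scorer."""
        pwm = sf.tata_pwm()
        clusters = small_world["clusters"][:40]
        res = sf.scan_pwm(clusters, small_world["genome"], pwm,
                          search_window=(-35, -25))
        thr = pwm.threshold
        for tc, flag in zip(clusters, res["hits"]):
            best = -np.inf
            for start in range(-35, -24):
                win = sf.oriented_window(small_world["genome"], tc.chrom,
                                         tc.dominant_pos, tc.strand,
                                         start, start + pwm.length - 1)
                if any(b not in "ACGT" for b in win):
                    continue
                s = sum(pwm.matrix["ACGT".index(b), j]
                        for j, b in enumerate(win))
                best = max(best, s)
            assert flag == (best >= thr)

    def test_ambiguous_window_skipped(self):
        genome = {"c": "N" * 200}
        clusters = toy_clusters([("c", 100, "+", 5.0)])
        res = sf.scan_pwm(clusters, genome, sf.tata_pwm())
        assert not res["hits"][0] and np.isnan(res["best_scores"][0])

    def test_empirical_threshold_mode(self, rng):
        pwm = sf.tata_pwm()
        bg = rng.normal(size=1000)
        emp = sf.PWM(matrix=pwm.matrix, threshold_fraction=0.8,
                     threshold_mode="empirical", background_scores=bg)
        assert emp.threshold == pytest.approx(np.quantile(bg, 0.8))


class TestWWPeriodicity:
    def test_phased_broad_promoters_recover_ten_and_a_half(self, broad_world):
        broad = [c for c in broad_world["clusters"]
                 if c.shape_class == "broad"]
        pe = sf.ww_periodicity(broad, broad_world["genome"])
        assert pe.period == pytest.approx(10.5, abs=0.5)
        assert pe.significant

    def test_random_sequence_has_no_significant_peak(self, rng):
        genome = {"c": "".join(rng.choice(list("ACGT"), 300_000))}
        clusters = toy_clusters([("c", int(p), "+", 5.0)
                                 for p in range(1000, 299_000, 596)])
        pe = sf.ww_periodicity(clusters, genome)
        assert not pe.significant

    def test_random_alignment_attenuates_amplitude(self, broad_world):
        """Aligning on a random member CTSS instead of the dominant blurs
        the phase and weakens the spectral peak."""
        broad = [c for c in broad_world["clusters"]
                 if c.shape_class == "broad"]
        dom = sf.ww_periodicity(broad, broad_world["genome"])
        ctl = sf.ww_periodicity(broad, broad_world["genome"], align="random",
                                seed=7)
        assert ctl.amplitude < dom.amplitude

    def test_region_too_short_errors(self, broad_world):
        with pytest.raises(ValueError, match="two periods"):
            sf.ww_periodicity(broad_world["clusters"], broad_world["genome"],
                              region=(1, 30))


class TestIntervalOverlay:
    def test_interval_spanning_everything(self, small_world):
        clusters = small_world["clusters"][:10]
        iv = pd.DataFrame({"chrom": ["chr1"], "start": [0],
                           "end": [400_000]})
        res = sf.interval_overlay(clusters, iv, flank=100)
        assert res["fraction"] == 1.0

    def test_no_intervals(self, small_world):
        iv = pd.DataFrame({"chrom": [], "start": [], "end": []})
        res = sf.interval_overlay(small_world["clusters"][:10], iv, flank=100)
        assert res["fraction"] == 0.0
        assert np.allclose(res["profile"], 0.0)

    def test_half_overlap_matches_hand_tally(self):
        clusters = toy_clusters([("c", p, "+", 5.0)
                                 for p in (1000, 3000, 5000, 7000)])
        iv = pd.DataFrame({"chrom": ["c", "c"], "start": [950, 2950],
                           "end": [1050, 3050]})
        res = sf.interval_overlay(clusters, iv, flank=20)
        assert res["fraction"] == 0.5
        assert res["flags"].tolist() == [True, True, False, False]

    def test_broad_promoters_carry_the_island_signal(self, small_world):
        """CpG-island truth intervals overlap broad but not sharp windows."""
        truth = small_world["truth"].promoters
        islands = truth.dropna(subset=["island_start"])
        iv = pd.DataFrame({"chrom": islands["chrom"],
                           "start": islands["island_start"].astype(int) - 1,
                           "end": islands["island_end"].astype(int)})
        res = sf.interval_overlay(small_world["clusters"], iv, flank=100)
        assert res["broad"]["fraction"] > 0.95
        assert res["sharp"]["fraction"] < 0.1
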