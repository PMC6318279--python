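"""Enrichment tracks, the depletion-domain caller against a brute-force
reference, peak allele specificity, methylation binning and metagenes."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from xikit import epigenome, simulate, statstests
from xikit.core import (AllelicTrack, ConfigurationError, DataError,
                        EnrichmentTrack, GenomicDomain)


def _track(values, bin_size=10_000, chrom="chrX"):
    return EnrichmentTrack(chrom, bin_size, np.asarray(values, dtype=float))


def _allelic(values, bin_size=500):
    v = np.asarray(values, dtype=float)
    return AllelicTrack("chrX", bin_size, np.zeros_like(v), v,
                        np.zeros_like(v))


class TestEnrichmentTrack:
    def test_equal_ip_and_input_gives_zeros(self):
        v = np.full(40, 5.0)
        track = epigenome.enrichment_track(_allelic(v), _allelic(v),
                                           coarse_bin=10_000)
        assert np.allclose(track.log2_ratio, 0.0)

    def test_pseudocounted_ratio_arithmetic(self):
        # one fine bin: IP 8, input 2, equal library sizes -> log2(9/3)
        track = epigenome.enrichment_track(_allelic([8.0]), _allelic([2.0]),
                                           coarse_bin=500, scale=1.0)
        assert track.log2_ratio[0] == pytest.approx(np.log2(3), abs=1e-12)

    def test_coarse_bin_is_mean_of_fine_values(self):
        # fine log-ratios {+1, -1} in one coarse bin average to 0
        ip = _allelic([2.0, 0.5] * 10)
        inp = _allelic([1.0, 1.0] * 10)
        track = epigenome.enrichment_track(ip, inp, coarse_bin=10_000,
                                           pseudocount=0.0, scale=1.0)
        assert track.log2_ratio[0] == pytest.approx(0.0, abs=1e-12)

    def test_mismatched_bins_rejected(self):
        with pytest.raises(ConfigurationError):
            epigenome.enrichment_track(_allelic([1, 2]), _allelic([1, 2]),
                                       coarse_bin=750)


# -- brute-force reference for the domain caller ----------------------------

def domains_by_gap_grouping(values, bin_size, threshold, max_gap):
    """Independent reference: group below-threshold bins directly by the
    bp gap between consecutive ones."""
    below = [i for i, v in enumerate(values)
             if not np.isnan(v) and v < threshold]
    groups = []
    for i in below:
        if groups and (i - groups[-1][-1] - 1) * bin_size <= max_gap:
            groups[-1].append(i)
        else:
            groups.append([i])
    return [(g[0] * bin_size, (g[-1] + 1) * bin_size) for g in groups]


class TestDepletionDomains:
    def test_no_negative_bins_gives_no_domains(self):
        domains, summary = epigenome.call_depletion_domains(
            _track(np.abs(np.arange(10)) + 0.1))
        assert domains == []
        assert summary.count == 0

    def test_twenty_kb_gap_is_merged_inclusively(self):
        # negative runs [0,100kb) and [120kb,200kb): gap exactly 20 kb
        values = np.full(20, 1.0)
        values[0:10] = -1
        values[12:20] = -1
        domains, _ = epigenome.call_depletion_domains(_track(values))
        assert [(d.start, d.end) for d in domains] == [(0, 200_000)]

    def test_thirty_kb_gap_stays_split(self):
        values = np.full(23, 1.0)
        values[0:10] = -1
        values[13:23] = -1
        domains, _ = epigenome.call_depletion_domains(_track(values))
        assert len(domains) == 2

    def test_missing_bins_count_toward_gap(self):
        values = np.array([-1.0, np.nan, np.nan, -1.0, 1.0])
        domains, _ = epigenome.call_depletion_domains(_track(values))
        assert [(d.start, d.end) for d in domains] == [(0, 40_000)]
        domains, _ = epigenome.call_depletion_domains(_track(values),
                                                      max_gap=10_000)
        assert len(domains) == 2

    def test_negative_max_gap_rejected(self):
        with pytest.raises(ConfigurationError):
            epigenome.call_depletion_domains(_track([1.0]), max_gap=-1)

    def test_matches_brute_force_on_random_tracks(self, rng):
        for _ in range(100):
            values = rng.normal(0, 1, size=1000)
            values[rng.random(1000) < 0.05] = np.nan
            track = _track(values)
            domains, _ = epigenome.call_depletion_domains(track)
            expected = domains_by_gap_grouping(values, 10_000, 0.0, 20_000)
            assert [(d.start, d.end) for d in domains] == expected

    def test_reversed_track_yields_mirrored_domains(self, rng):
        values = rng.normal(0, 1, size=300)
        n = len(values)
        fwd, _ = epigenome.call_depletion_domains(_track(values))
        rev, _ = epigenome.call_depletion_domains(_track(values[::-1]))
        mirrored = sorted((n * 10_000 - d.end, n * 10_000 - d.start)
                          for d in rev)
        assert [(d.start, d.end) for d in fwd] == mirrored

    def test_planted_domains_recovered(self, small_config):
        """Jaccard >= 0.9 at effect -1 log2 and 30 reads per 10 kb bin."""
        ip, inp = simulate.simulate_chip_tracks(small_config, "mutant")
        track = epigenome.enrichment_track(
            ip, inp, coarse_bin=small_config.track_bin, scale=1.0)
        domains, _ = epigenome.call_depletion_domains(track)
        ov = statstests.domain_overlap(domains, small_config.planted_domains)
        assert ov.jaccard >= 0.9


class TestPeakSpecificity:
    @pytest.mark.parametrize("xi,xa,score", [
        (5, 0, 100.0), (0, 7, -100.0), (4, 4, 0.0), (3, 1, 50.0)])
    def test_occupancy_ratio_score(self, xi, xa, score):
        peak = epigenome.AllelicPeak(GenomicDomain("chrX", 0, 100), xi, xa)
        assert epigenome.allelic_specificity_score(peak) == \
            pytest.approx(score)

    def test_score_antisymmetric_under_swap(self, rng):
        for _ in range(20):
            xi, xa = rng.integers(0, 50, 2)
            if xi + xa == 0:
                continue
            iv = GenomicDomain("chrX", 0, 100)
            s1 = epigenome.allelic_specificity_score(
                epigenome.AllelicPeak(iv, xi, xa))
            s2 = epigenome.allelic_specificity_score(
                epigenome.AllelicPeak(iv, xa, xi))
            assert s1 == -s2

    def test_zero_total_is_flagged(self):
        peak = epigenome.AllelicPeak(GenomicDomain("chrX", 0, 100), 0, 0)
        with pytest.raises(DataError):
            epigenome.allelic_specificity_score(peak)

    @pytest.mark.parametrize("frac_xi,expected", [
        (0.95, "Xi-specific"), (0.90, "both"), (0.50, "both"),
        (0.05, "Xa-specific")])
    def test_exclusivity_threshold_is_strict(self, frac_xi, expected):
        peak = epigenome.AllelicPeak(GenomicDomain("chrX", 0, 100),
                                     100 * frac_xi, 100 * (1 - frac_xi))
        assert epigenome.classify_peak_allelicity(peak) == expected


class TestSimplePeaks:
    def test_flat_zero_track_has_no_peaks(self):
        assert epigenome.call_peaks_simple(_track(np.zeros(20)), 1.0) == []

    def test_run_of_three_bins_is_one_peak(self):
        values = np.zeros(10)
        values[4:7] = 2.0
        peaks = epigenome.call_peaks_simple(_track(values), 2.0, min_bins=2)
        assert [(p.start, p.end) for p in peaks] == [(40_000, 70_000)]

    def test_planted_peaks_recovered_at_high_snr(self, rng):
        truth = np.zeros(500)
        starts = rng.choice(480, 10, replace=False)
        for s in starts:
            truth[s:s + 5] = 4.0
        noisy = truth + rng.normal(0, 1, 500)
        peaks = epigenome.call_peaks_simple(_track(noisy), 2.0, min_bins=2)
        hits = sum(any(p.start <= s * 10_000 < p.end for p in peaks)
                   for s in starts)
        assert hits >= 9


class TestMethylationTrack:
    def _sites(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "pos", "meth_count",
                                           "total_count"])

    def test_low_coverage_sites_excluded(self):
        sites = self._sites([("chrX", 100, 2, 2)])
        track = epigenome.methylation_track(sites, 10_000)
        assert np.isnan(track.log2_ratio[0])

    def test_bin_value_is_mean_of_site_percentages(self):
        sites = self._sites([("chrX", 100, 4, 5), ("chrX", 200, 1, 5)])
        track = epigenome.methylation_track(sites, 10_000)
        assert track.log2_ratio[0] == pytest.approx(50.0)

    def test_meth_exceeding_coverage_rejected(self):
        with pytest.raises(DataError):
            epigenome.methylation_track(self._sites([("chrX", 1, 6, 5)]))

    def test_values_bounded_zero_hundred(self, small_config):
        calls = simulate.simulate_methylation(small_config, 35.0)
        track = epigenome.methylation_track(calls, 10_000)
        v = track.log2_ratio[np.isfinite(track.log2_ratio)]
        assert (v >= 0).all() and (v <= 100).all()


class TestSiteValuesAndMetagene:
    def test_site_mean_over_two_bins(self):
        track = _track([10.0, 20.0, 99.0])
        sites = [GenomicDomain("chrX", 0, 20_000)]
        assert epigenome.values_at_sites(sites, track)[0] == \
            pytest.approx(15.0)

    def test_site_in_missing_region_is_nan(self):
        track = _track([np.nan, np.nan, 1.0])
        sites = [GenomicDomain("chrX", 0, 20_000)]
        assert np.isnan(epigenome.values_at_sites(sites, track)[0])

    def test_ordering_is_a_permutation_with_coordinate_ties(self):
        sites = [GenomicDomain("chrX", s, s + 10) for s in (30, 10, 20)]
        order = epigenome.order_sites_by_value(sites,
                                               np.array([1.0, 1.0, 2.0]))
        assert sorted(order) == [0, 1, 2]
        assert order == [2, 1, 0]  # highest value first, then coordinate

    def test_constant_signal_gives_flat_profile(self):
        track = _track(np.full(100, 70.0), bin_size=1000)
        genes = [GenomicDomain("chrX", 20_000, 50_000)]
        prof = epigenome.metagene_profile(genes, track, flank=5_000,
                                          n_body_bins=10)
        assert np.allclose(prof[np.isfinite(prof)], 70.0)

    def test_step_profile_for_body_only_signal(self):
        values = np.zeros(100)
        values[20:50] = 100.0
        track = _track(values, bin_size=1000)
        genes = [GenomicDomain("chrX", 20_000, 50_000)]
        prof = epigenome.metagene_profile(genes, track, flank=5_000,
                                          n_body_bins=10)
        assert np.allclose(prof[5:15], 100.0)
        assert np.allclose(prof[:5], 0.0)
        assert np.allclose(prof[15:], 0.0)

    def test_minus_strand_gene_mirrors_plus_strand(self):
        values = np.linspace(0, 99, 100)
        track = _track(values, bin_size=1000)
        gene = [GenomicDomain("chrX", 20_000, 50_000)]
        plus = epigenome.metagene_profile(gene, track, flank=5_000,
                                          n_body_bins=10, strands=["+"])
        minus = epigenome.metagene_profile(gene, track, flank=5_000,
                                           n_body_bins=10, strands=["-"])
        assert np.allclose(plus, minus[::-1], equal_nan=True)
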