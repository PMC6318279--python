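"""Hi-C statistics against closed forms and brute-force oracles:
KR row-sum uniformity by independent summation, insulation equal to an
explicit double loop, eigenvector recovery of planted compartments,
noiseless distance-decay slopes, and TAD re-establishment scoring."""

import dataclasses

import numpy as np
import pytest

from xikit import hic, simulate
from xikit.core import ConfigurationError, ContactMatrix, DataError, \
    GenomicDomain
from xikit.simulate import SimulationConfig


def _matrix(counts, bin_size=100_000, chrom="chrX", hap=""):
    return ContactMatrix(chrom, hap, bin_size, np.asarray(counts, float))


def _random_symmetric(rng, n, low=1.0, high=10.0):
    a = rng.uniform(low, high, size=(n, n))
    return (a + a.T) / 2


# ---------------------------------------------------------------------------


class TestDownsampleEqualize:
    def _sample(self, rng, total, n=30):
        iu = np.triu_indices(n)
        c = np.zeros((n, n))
        vals = rng.multinomial(total, np.ones(len(iu[0])) / len(iu[0]))
        c[iu] = vals
        c = c + np.triu(c, 1).T
        return {"chrX": _matrix(c)}

    def test_totals_match_smallest_sample(self, rng):
        samples = {"a": self._sample(rng, 1000), "b": self._sample(rng, 800)}
        out = hic.downsample_equalize(samples, seed=3)
        assert out["a"]["chrX"].total == 800
        assert out["b"]["chrX"].total == 800

    def test_per_chromosome_totals_equalised(self, rng):
        samples = {
            "a": {"chr1": self._sample(rng, 600)["chrX"],
                  "chrX": self._sample(rng, 500)["chrX"]},
            "b": {"chr1": self._sample(rng, 300)["chrX"],
                  "chrX": self._sample(rng, 700)["chrX"]},
        }
        out = hic.downsample_equalize(samples, seed=1)
        for chrom in ("chr1", "chrX"):
            totals = {out[s][chrom].total for s in out}
            assert len(totals) == 1

    def test_symmetry_preserved_and_seed_reproducible(self, rng):
        samples = {"a": self._sample(rng, 2000), "b": self._sample(rng, 900)}
        out1 = hic.downsample_equalize(samples, seed=5)
        out2 = hic.downsample_equalize(samples, seed=5)
        m = out1["a"]["chrX"].counts
        assert np.array_equal(m, m.T)
        assert np.array_equal(m, out2["a"]["chrX"].counts)

    def test_empty_matrix_rejected(self, rng):
        samples = {"a": self._sample(rng, 100),
                   "b": {"chrX": _matrix(np.zeros((30, 30)))}}
        with pytest.raises(DataError):
            hic.downsample_equalize(samples)


class TestKRBalance:
    def test_closed_form_two_by_two(self):
        m = hic.kr_balance(_matrix([[0.0, 2.0], [2.0, 0.0]]))
        assert np.allclose(m.weights, 1 / np.sqrt(2), atol=1e-6)
        assert np.allclose(m.balanced(), [[0, 1], [1, 0]], atol=1e-6)

    def test_doubly_uniform_matrix_gets_equal_weights(self):
        m = hic.kr_balance(_matrix(np.full((8, 8), 3.0)))
        assert np.allclose(m.weights, m.weights[0])

    def test_row_sums_uniform_by_independent_summation(self, rng):
        """50 random symmetric positive 50x50 matrices, deviation < 1e-6."""
        for _ in range(50):
            counts = _random_symmetric(rng, 50)
            m = hic.kr_balance(_matrix(counts), tol=1e-6)
            b = m.balanced()
            # independent summation: explicit per-row loop over entries
            for i in range(50):
                row_sum = sum(b[i, j] for j in range(50))
                assert abs(row_sum - 1.0) < 1e-6

    def test_balancing_is_idempotent(self, rng):
        counts = _random_symmetric(rng, 30)
        m = hic.kr_balance(_matrix(counts))
        again = hic.kr_balance(_matrix(m.balanced()))
        assert np.allclose(again.weights, 1.0, atol=1e-5)

    def test_zero_marginal_bins_masked(self):
        counts = np.array([[0, 2, 0], [2, 0, 0], [0, 0, 0]], dtype=float)
        m = hic.kr_balance(_matrix(counts))
        assert m.mask[2]
        assert np.isnan(m.weights[2])
        b = m.balanced()
        assert np.nansum(b[0]) == pytest.approx(1.0, abs=1e-6)

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(DataError):
            hic.kr_balance(_matrix(np.zeros((5, 5))))


# -- insulation oracle -------------------------------------------------------

def insulation_raw_oracle(m, w):
    """Explicit double loop over the square window, same value order."""
    n = m.shape[0]
    raw = np.full(n, np.nan)
    for i in range(w, n - w):
        vals = []
        for a in range(i - w, i):
            for b in range(i + 1, i + w + 1):
                vals.append(m[a, b])
        vals = np.array(vals)
        if np.any(~np.isnan(vals)):
            raw[i] = np.nanmean(vals)
    return raw


class TestInsulation:
    def test_uniform_matrix_scores_zero(self):
        m = _matrix(np.ones((30, 30)))
        ins = hic.insulation_score(m, window=500_000, delta_span=200_000)
        defined = np.isfinite(ins.score)
        assert defined.sum() > 0
        assert np.allclose(ins.score[defined], 0.0)

    def test_two_block_matrix_minimum_at_junction(self):
        n = 40
        counts = np.ones((n, n))
        counts[:20, :20] = 10.0
        counts[20:, 20:] = 10.0
        ins = hic.insulation_score(_matrix(counts), window=500_000,
                                   delta_span=200_000)
        assert np.nanargmin(ins.score) in (19, 20)
        assert 19 in ins.boundaries or 20 in ins.boundaries

    def test_equals_brute_force_oracle_exactly(self, rng):
        for _ in range(5):
            counts = _random_symmetric(rng, 30)
            k = int(rng.integers(0, 30))
            counts[k, :] = 1.0
            counts[:, k] = 1.0
            m = _matrix(counts)
            ins = hic.insulation_score(m, window=500_000,
                                       delta_span=200_000)
            raw = insulation_raw_oracle(counts, 5)
            expected = np.log2(raw / np.nanmean(raw))
            finite = np.isfinite(expected)
            assert np.array_equal(np.isfinite(ins.score), finite)
            assert np.array_equal(ins.score[finite], expected[finite])

    def test_window_must_fit(self):
        with pytest.raises(ConfigurationError):
            hic.insulation_score(_matrix(np.ones((6, 6))), window=500_000)

    def test_boundary_scores_extracted_per_sample(self):
        n = 40
        counts = np.ones((n, n))
        counts[:20, :20] = 10
        counts[20:, 20:] = 10
        ins = hic.insulation_score(_matrix(counts))
        table = hic.insulation_at_boundaries(ins.boundaries,
                                             {"a": ins, "b": ins})
        assert (table["a"] == table["b"]).all()


class TestDistanceDecay:
    def _power_law_matrix(self, n, exponent, depth=1000.0):
        idx = np.arange(n)
        sep = np.abs(idx[:, None] - idx[None, :]).astype(float)
        counts = depth * np.maximum(sep, 1.0) ** exponent
        return _matrix(counts, bin_size=100_000)

    @pytest.mark.parametrize("exponent", [-1.0, -1.5])
    def test_noiseless_power_law_slope_recovered(self, exponent):
        m = self._power_law_matrix(120, exponent)
        decay = hic.distance_decay(m, fit_range=(200_000, 5_000_000))
        assert decay.slope == pytest.approx(exponent, abs=0.01)

    def test_probability_sums_to_one(self, rng):
        m = _matrix(_random_symmetric(rng, 50))
        decay = hic.distance_decay(m)
        assert decay.prob.sum() == pytest.approx(1.0)

    def test_single_separation_concentrates_probability(self):
        n = 30
        counts = np.zeros((n, n))
        for i in range(n - 1):
            counts[i, i + 1] = counts[i + 1, i] = 5.0
        decay = hic.distance_decay(_matrix(counts),
                                   fit_range=(100_000, 2_900_000))
        assert decay.prob[0] == pytest.approx(1.0)

    def test_too_narrow_fit_range_rejected(self):
        m = self._power_law_matrix(50, -1.0)
        with pytest.raises(ConfigurationError):
            hic.distance_decay(m, fit_range=(100_000, 150_000))


class TestCompartments:
    def _checkerboard_config(self, seed=21):
        return SimulationConfig(
            chrom_length=20_000_000, hic_bin=500_000, hic_depth=200.0,
            seed=seed, compartment_block=2_000_000, compartment_factor=2.0,
            tad_set=[], dispersion=0.05)

    def test_planted_checkerboard_recovered(self):
        cfg = self._checkerboard_config()
        m = simulate.simulate_hic(cfg, "active-like")
        labels = simulate.compartment_labels(cfg, cfg.hic_bin)
        planted = (labels == "A").astype(float)
        prof = hic.compartment_eigenvector(m, gene_density=planted)
        ok = np.isfinite(prof.eigenvector)
        assert (prof.labels[ok] == labels[ok]).mean() == 1.0
        r = np.corrcoef(prof.eigenvector[ok], planted[ok])[0, 1]
        assert abs(r) > 0.95

    def test_null_matrix_shows_no_compartments(self):
        cfg = dataclasses.replace(self._checkerboard_config(seed=22),
                                  compartment_factor_inactive=1.0,
                                  cross_mega_factor=1.0)
        m = simulate.simulate_hic(cfg, "inactive-like")
        planted = (simulate.compartment_labels(cfg, cfg.hic_bin) ==
                   "A").astype(float)
        prof = hic.compartment_eigenvector(m)
        ok = np.isfinite(prof.eigenvector)
        r = np.corrcoef(prof.eigenvector[ok], planted[ok])[0, 1]
        assert abs(r) < 0.3

    def test_orientation_follows_gene_density_sign(self):
        cfg = self._checkerboard_config()
        m = simulate.simulate_hic(cfg, "active-like")
        planted = (simulate.compartment_labels(cfg, cfg.hic_bin) ==
                   "A").astype(float)
        p1 = hic.compartment_eigenvector(m, gene_density=planted)
        p2 = hic.compartment_eigenvector(m, gene_density=1.0 - planted)
        ok = np.isfinite(p1.eigenvector)
        assert np.allclose(p1.eigenvector[ok], -p2.eigenvector[ok])
        assert ((p1.labels[ok] == "A") == (p2.labels[ok] == "B")).all()

    def test_eigenvector_invariant_under_global_scaling(self):
        cfg = self._checkerboard_config()
        m = simulate.simulate_hic(cfg, "active-like")
        scaled = _matrix(m.counts * 7.0, bin_size=m.bin_size)
        p1 = hic.compartment_eigenvector(m)
        p2 = hic.compartment_eigenvector(scaled)
        ok = np.isfinite(p1.eigenvector)
        r = np.corrcoef(p1.eigenvector[ok], p2.eigenvector[ok])[0, 1]
        assert abs(r) > 0.9999

    def test_correlation_trivial_cases(self):
        from xikit.core import CompartmentProfile
        v = np.array([1.0, -0.5, 0.3, 0.8, -0.2])
        labels = np.where(v >= 0, "A", "B")
        p = CompartmentProfile("chrX", 500_000, v, labels)
        q = CompartmentProfile("chrX", 500_000, -v, labels)
        assert hic.eigenvector_correlation(p, p) == pytest.approx(1.0)
        assert hic.eigenvector_correlation(p, q) == pytest.approx(-1.0)

    def test_independent_noise_uncorrelated(self, rng):
        from xikit.core import CompartmentProfile
        a = rng.normal(size=500)
        b = rng.normal(size=500)
        p = CompartmentProfile("chrX", 500_000, a, np.where(a >= 0, "A", "B"))
        q = CompartmentProfile("chrX", 500_000, b, np.where(b >= 0, "A", "B"))
        assert abs(hic.eigenvector_correlation(p, q)) < 0.15


class TestTadReestablishment:
    def test_score_arithmetic(self):
        n = 30
        wt = np.ones((n, n)) * 2
        mut = np.ones((n, n)) * 3
        tads = [GenomicDomain("chrX", 0, 1_000_000)]
        df = hic.tad_reestablishment(tads, _matrix(wt), _matrix(mut),
                                     min_sep=100_000)
        assert df["score"].iloc[0] == pytest.approx(0.5)

    def test_identical_matrices_score_exactly_zero(self, rng):
        counts = _random_symmetric(rng, 40)
        m = _matrix(counts)
        tads = [GenomicDomain("chrX", i * 1_000_000, (i + 1) * 1_000_000)
                for i in range(4)]
        df = hic.tad_reestablishment(tads, m, m)
        assert (df["score"] == 0.0).all()

    def test_min_separation_excludes_short_range_pairs(self):
        n = 10
        wt = np.ones((n, n))
        mut = wt.copy()
        mut[0, 1] = mut[1, 0] = 100.0  # adjacent-bin pair, sep <= 100 kb
        tads = [GenomicDomain("chrX", 0, 1_000_000)]
        df = hic.tad_reestablishment(tads, _matrix(wt), _matrix(mut))
        assert df["score"].iloc[0] == 0.0

    def test_planted_restored_tads_classified(self, small_config):
        cfg = dataclasses.replace(small_config, chrom_length=20_000_000,
                                  hic_depth=100.0)
        cfg = simulate.default_config(seed=31, chrom_length=20_000_000,
                                      hic_depth=100.0)
        wt = simulate.simulate_hic(cfg, "inactive-like")
        mut = simulate.simulate_hic(cfg, "mutant-inactive-like")
        assert mut.total >= 1e5
        df = hic.tad_reestablishment(cfg.tad_set, wt, mut)
        restored = df["label"] == "restored"
        assert (df.loc[restored, "class"] != "weak").mean() >= 0.9
        assert (df.loc[~restored, "class"] == "weak").mean() >= 0.9


def test_mega_domain_cross_depletion_diagnostic():
    cfg = simulate.default_config(seed=41, chrom_length=20_000_000)
    m = hic.kr_balance(simulate.simulate_hic(cfg, "inactive-like"))
    diag = hic.mega_domain_contrast(m, cfg.mega_domain_boundary)
    assert diag["mean_cross_within_ratio"] < 1.0
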