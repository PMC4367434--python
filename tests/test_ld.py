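"""Allele frequencies, MAF filtering and pairwise r² estimators."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from netrend import (ComputationError, ConfigError, HaplotypeDataset,
                     LDConfig, PairSkipped, compute_pair_table,
                     enumerate_pairs, maf_filter, minor_allele_frequency,
                     r2_genotype, r2_haplotype, simulate_wright_fisher,
                     SimulationSpec)
from netrend.io import MISSING

import oracles
from conftest import make_marker_map, random_genotype_dataset


class TestMAF:
    @pytest.mark.parametrize("counts,expected", [
        ([0, 1, 2, 2], 0.375),      # p = 5/8 -> min(p, 1-p)
        ([0, 0, 0], 0.0),
        ([1, 1], 0.5),
        ([0, 1, MISSING, 2], 0.5),  # missing entry ignored: p = 3/6
    ])
    def test_values(self, counts, expected):
        assert minor_allele_frequency(np.array(counts)) == pytest.approx(
            expected, abs=1e-15)

    def test_all_missing_column_is_an_error(self):
        with pytest.raises(ComputationError, match="missing"):
            minor_allele_frequency(np.array([MISSING, MISSING]))


class TestMAFFilter:
    def build(self, columns):
        counts = np.array(columns, dtype=np.int8).T
        ds = random_genotype_dataset(np.random.default_rng(0),
                                     n_ind=counts.shape[0],
                                     n_markers=counts.shape[1])
        ds.counts[:] = counts
        return ds

    def test_threshold_keeps_at_or_above(self):
        # MAFs 0.0, 0.05, 0.30 with threshold 0.05: the boundary marker is
        # kept, the monomorphic one always removed
        ds = self.build([[0] * 10,
                         [1] + [0] * 9,
                         [2, 2, 1, 1, 0, 0, 0, 0, 0, 0]])
        out, report = maf_filter(ds, 0.05)
        assert out.n_markers == 2
        assert report == {"1": 1}

    def test_zero_threshold_still_drops_monomorphic(self):
        ds = self.build([[0] * 4, [0, 1, 1, 2]])
        out, _ = maf_filter(ds, 0.0)
        assert out.n_markers == 1

    def test_all_removed_is_an_error(self):
        ds = self.build([[0] * 4])
        with pytest.raises(ComputationError, match="no markers survive"):
            maf_filter(ds, 0.05)

    def test_threshold_out_of_range(self):
        ds = self.build([[0, 1, 1, 2]])
        with pytest.raises(ConfigError):
            maf_filter(ds, 0.5)


class TestR2Genotype:
    def test_hand_checked_value(self):
        r2, n = r2_genotype(np.array([0, 1, 2, 2]), np.array([0, 1, 1, 2]))
        assert n == 4
        assert r2 == pytest.approx(4 / 5.5, abs=1e-12)

    def test_self_correlation_is_one(self):
        v = np.array([0, 1, 2, 1])
        r2, _ = r2_genotype(v, v)
        assert r2 == pytest.approx(1.0, abs=1e-15)

    def test_zero_variance_skipped(self):
        with pytest.raises(PairSkipped, match="monomorphic"):
            r2_genotype(np.array([0, 1, 2, 1]), np.array([1, 1, 1, 1]))

    def test_too_few_complete_observations_skipped(self):
        x = np.array([0, 1, MISSING, MISSING])
        y = np.array([0, MISSING, 1, 2])
        with pytest.raises(PairSkipped, match="insufficient"):
            r2_genotype(x, y)

    @given(st.lists(st.integers(0, 2), min_size=4, max_size=20),
           st.data())
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_symmetry_and_allele_swap_invariance(self, xs, data):
        ys = data.draw(st.lists(st.integers(0, 2), min_size=len(xs),
                                max_size=len(xs)))
        x, y = np.array(xs), np.array(ys)
        try:
            r_xy, _ = r2_genotype(x, y)
        except PairSkipped:
            return
        r_yx, _ = r2_genotype(y, x)
        assert r_xy == r_yx
        # counting the other allele at either locus leaves r2 unchanged
        r_swap, _ = r2_genotype(2 - x, y)
        assert r_swap == pytest.approx(r_xy, abs=1e-12)


class TestR2Haplotype:
    def test_complete_coupling(self):
        a = np.array([1, 1, 1, 0, 0, 0, 1, 0])
        assert r2_haplotype(a, a)[0] == pytest.approx(1.0, abs=1e-15)

    def test_independence_gives_zero(self):
        # p_AB = p_A * p_B exactly (p_A = p_B = 1/2, p_AB = 1/4)
        a = np.array([1, 1, 0, 0])
        b = np.array([1, 0, 1, 0])
        a = np.tile(a, 2)
        b = np.tile(b, 2)
        assert r2_haplotype(a, b)[0] == pytest.approx(0.0, abs=1e-15)

    def test_frequency_counting_value(self):
        # 10 haplotypes: p_A=0.6, p_B=0.5, p_AB=0.4 -> 0.01/0.06
        a = np.array([1, 1, 1, 1, 1, 1, 0, 0, 0, 0])
        b = np.array([1, 1, 1, 1, 0, 0, 1, 0, 0, 0])
        r2, n = r2_haplotype(a, b)
        assert r2 == pytest.approx(1 / 6, abs=1e-12)
        assert n == 5


class TestOracleAgreement:
    """Both estimators against naive reference implementations."""

    @pytest.mark.parametrize("missing_rate", [0.0, 0.15])
    def test_genotype_estimator(self, rng, missing_rate):
        for _ in range(20):
            ds = random_genotype_dataset(
                rng, n_ind=int(rng.integers(5, 31)),
                n_markers=10, missing_rate=missing_rate)
            for i in range(ds.n_markers):
                for j in range(i + 1, ds.n_markers):
                    expected = oracles.pearson_r2_bruteforce(
                        ds.counts[:, i].tolist(), ds.counts[:, j].tolist())
                    try:
                        got = r2_genotype(ds.counts[:, i], ds.counts[:, j])
                    except PairSkipped:
                        got = None
                    if expected is None:
                        assert got is None
                    else:
                        assert got[1] == expected[1]
                        assert got[0] == pytest.approx(expected[0],
                                                       abs=1e-12)

    def test_haplotype_estimator(self, rng):
        for _ in range(20):
            n_hap = 2 * int(rng.integers(4, 16))
            haps = rng.integers(0, 2, size=(n_hap, 8)).astype(np.int8)
            haps[rng.random(haps.shape) < 0.1] = MISSING
            for i in range(8):
                for j in range(i + 1, 8):
                    expected = oracles.haplotype_r2_bruteforce(
                        haps[:, i].tolist(), haps[:, j].tolist())
                    try:
                        got = r2_haplotype(haps[:, i], haps[:, j])
                    except PairSkipped:
                        got = None
                    if expected is None:
                        assert got is None
                    else:
                        assert got[0] == pytest.approx(expected[0],
                                                       abs=1e-12)


class TestPairEnumeration:
    def test_distance_window(self, rng):
        ds = random_genotype_dataset(rng, n_ind=20, n_markers=4)
        ds.markers.position_bp[:] = [100_000, 200_000, 300_000, 4_000_000]
        cfg = LDConfig(min_distance_bp=50_000, max_distance_bp=500_000)
        pairs = list(enumerate_pairs(ds, cfg))
        dists = sorted(p.distance_bp for p in pairs)
        assert dists == [100_000, 100_000, 200_000]

    def test_no_pairs_across_chromosomes(self, rng):
        ds = random_genotype_dataset(rng, n_ind=20, n_markers=4,
                                     chrom=["1", "1", "2", "2"])
        cfg = LDConfig(min_distance_bp=1, max_distance_bp=10**9)
        for p in enumerate_pairs(ds, cfg):
            assert p.chromosome in ("1", "2")
        table = compute_pair_table(ds, cfg)
        # only within-chromosome combinations appear
        assert len(table) <= 2

    def test_chromosome_filter(self, rng):
        ds = random_genotype_dataset(rng, n_ind=20, n_markers=6,
                                     chrom=["1"] * 3 + ["2"] * 3)
        cfg = LDConfig(min_distance_bp=1, max_distance_bp=10**9,
                       chromosomes={"2"})
        assert all(p.chromosome == "2" for p in enumerate_pairs(ds, cfg))

    def test_blocked_scan_matches_per_pair_estimator(self, rng):
        ds = random_genotype_dataset(rng, n_ind=25, n_markers=15,
                                     missing_rate=0.1)
        cfg = LDConfig(min_distance_bp=1, max_distance_bp=10**9)
        table = compute_pair_table(ds, cfg)
        pos_to_col = {p: i for i, p in enumerate(ds.markers.position_bp)}
        assert len(table) > 0
        for row in table.itertuples(index=False):
            i, j = pos_to_col[row.pos_a], pos_to_col[row.pos_b]
            r2, n = r2_genotype(ds.counts[:, i], ds.counts[:, j])
            assert row.r2 == pytest.approx(r2, abs=1e-10)
            assert row.n_obs == n

    def test_thread_count_does_not_change_results(self):
        out = simulate_wright_fisher(SimulationSpec(
            pop_size=60, sample_n=30, n_markers=300,
            chrom_length_bp=30_000_000, recomb_rate_per_bp=1e-8,
            generations=100, seed=42))
        ds, _ = maf_filter(out.dataset, 0.05)
        t1 = compute_pair_table(ds, LDConfig(threads=1))
        t4 = compute_pair_table(ds, LDConfig(threads=4))
        assert t1.equals(t4)


class TestPhasedUnphasedConsistency:
    def test_genotype_r2_approaches_haplotype_pool_r2(self, rng):
        """Individuals built from independently paired haplotypes: the
        genotype-count r2 converges on the haplotype r2 of the pool."""
        # pool with known haplotype frequencies (AB, Ab, aB, ab)
        freqs = {(1, 1): 0.4, (1, 0): 0.2, (0, 1): 0.1, (0, 0): 0.3}
        pool = list(freqs)
        probs = np.array(list(freqs.values()))
        p_a, p_b, p_ab = 0.6, 0.5, 0.4
        truth = (p_ab - p_a * p_b) ** 2 / (
            p_a * (1 - p_a) * p_b * (1 - p_b))
        n = 4000
        draws = rng.choice(len(pool), size=2 * n, p=probs)
        hap = np.array([pool[k] for k in draws])
        counts = hap[0::2] + hap[1::2]
        r2, _ = r2_genotype(counts[:, 0], counts[:, 1])
        assert r2 == pytest.approx(truth, abs=4 / np.sqrt(n))


class TestLDConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"maf_threshold": 0.5},
        {"maf_threshold": -0.01},
        {"min_distance_bp": 10, "max_distance_bp": 10},
        {"estimator": "em"},
        {"threads": 0},
    ])
    def test_rejects_bad_settings(self, kwargs):
        with pytest.raises(ConfigError):
            LDConfig(**kwargs)

    def test_haplotype_estimator_needs_phased_data(self, rng):
        ds = random_genotype_dataset(rng)
        with pytest.raises(ConfigError, match="phased"):
            compute_pair_table(ds, LDConfig(estimator="haplotype",
                                            min_distance_bp=1,
                                            max_distance_bp=10**9))
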