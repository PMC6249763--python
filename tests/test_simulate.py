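import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import mapanchor as ma
from mapanchor.io_formats import MISSING_CALL
from mapanchor.simulate import true_map


class TestKosambi:
    def test_zero_distance(self):
        assert ma.kosambi_cm(0.0) == 0.0
        assert ma.kosambi_r(0.0) == 0.0

    def test_closed_form_quarter(self):
        # d = 25 ln((1+0.5)/(1-0.5)) = 25 ln 3
        assert ma.kosambi_cm(0.25) == pytest.approx(25 * math.log(3), abs=1e-12)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            ma.kosambi_cm(0.5)
        with pytest.raises(ValueError):
            ma.kosambi_r(-1.0)

    @given(st.floats(min_value=0.0, max_value=0.499))
    @settings(max_examples=200, deadline=None)
    def test_inverse_identity(self, r):
        assert ma.kosambi_r(ma.kosambi_cm(r)) == pytest.approx(r, abs=1e-12)

    def test_r_monotone_and_bounded(self):
        assert ma.kosambi_r(100.0) < 0.5
        assert ma.kosambi_r(10.0) < ma.kosambi_r(20.0)


class TestSimulateGenome:
    def test_scaffold_lengths_conserved(self):
        truth, scafs = ma.simulate_genome(n_chrom=2, chrom_len=1_000_000,
                                          n_scaffolds=10, seed=5)
        assert scafs.total_bp() == 2_000_000

    def test_deterministic_for_fixed_seed(self):
        a = ma.simulate_genome(n_chrom=2, chrom_len=200_000, n_scaffolds=8, seed=7)
        b = ma.simulate_genome(n_chrom=2, chrom_len=200_000, n_scaffolds=8, seed=7)
        assert a[0].scaffold_truth == b[0].scaffold_truth
        assert [r.sequence for r in a[1].records] == [r.sequence for r in b[1].records]

    def test_one_scaffold_per_chromosome(self):
        truth, scafs = ma.simulate_genome(n_chrom=3, chrom_len=100_000,
                                          n_scaffolds=3, seed=1)
        assert len(scafs) == 3
        assert all(r.length == 100_000 for r in scafs.records)

    def test_too_few_scaffolds_rejected(self):
        with pytest.raises(ValueError):
            ma.simulate_genome(n_chrom=4, chrom_len=100_000, n_scaffolds=2, seed=1)

    def test_true_cm_monotone_with_position(self):
        truth, _ = ma.simulate_genome(n_chrom=2, chrom_len=400_000,
                                      n_scaffolds=6, seed=9)
        for chrom, _len in truth.chromosomes:
            cms = [m.true_cm for m in truth.markers_on(chrom)]
            assert cms == sorted(cms)


class TestSimulateCross:
    def test_testcross_fraction_near_half(self):
        truth, _ = ma.simulate_genome(n_chrom=1, chrom_len=100_000,
                                      n_scaffolds=1, seed=2, markers_per_chrom=5)
        matrix = ma.simulate_cross(truth, n_offspring=10_000, missing_rate=0.0,
                                   seed=3)
        lm_rows = matrix.classes[matrix.classes == "lmxll"].index
        for mid in lm_rows:
            frac = (matrix.calls.loc[mid] == "lm").mean()
            # 3 sigma binomial bound at n=10000
            assert abs(frac - 0.5) < 3 * 0.5 / math.sqrt(10_000)

    def test_intercross_one_two_one(self):
        truth, _ = ma.simulate_genome(n_chrom=1, chrom_len=100_000,
                                      n_scaffolds=1, seed=21, markers_per_chrom=20)
        matrix = ma.simulate_cross(truth, n_offspring=8000, missing_rate=0.0, seed=4)
        hk_rows = matrix.classes[matrix.classes == "hkxhk"].index
        assert len(hk_rows) > 0
        counts = matrix.calls.loc[hk_rows[0]].value_counts()
        chi2, p = stats.chisquare(
            [counts.get("hh", 0), counts.get("hk", 0), counts.get("kk", 0)],
            [2000, 4000, 2000])
        assert p > 1e-4

    def test_no_missing_when_rate_zero(self):
        truth, _ = ma.simulate_genome(n_chrom=1, chrom_len=50_000,
                                      n_scaffolds=1, seed=2, markers_per_chrom=10)
        matrix = ma.simulate_cross(truth, n_offspring=100, missing_rate=0.0, seed=5)
        assert not (matrix.calls == MISSING_CALL).any().any()

    def test_cosegregation_at_zero_distance(self):
        # two markers forced to the same cM: identical gamete inheritance
        truth, _ = ma.simulate_genome(n_chrom=1, chrom_len=50_000,
                                      n_scaffolds=1, seed=2, markers_per_chrom=2)
        for m in truth.marker_truth:
            m.true_cm = 10.0
            m.seg_class = "lmxll"
            m.phase = (0, 0)
        matrix = ma.simulate_cross(truth, n_offspring=500, missing_rate=0.0, seed=6)
        a, b = matrix.calls.iloc[0], matrix.calls.iloc[1]
        assert (a == b).all()

    def test_two_point_recombination_matches_kosambi(self):
        # adjacent markers at a known distance: observed recombinant fraction
        # within 3 sigma of kosambi_r(d) at n=5000
        truth, _ = ma.simulate_genome(n_chrom=1, chrom_len=50_000,
                                      n_scaffolds=1, seed=2, markers_per_chrom=2)
        d = 12.0
        for i, m in enumerate(truth.marker_truth):
            m.true_cm = 10.0 + i * d
            m.seg_class = "lmxll"
            m.phase = (0, 0)
        n = 5000
        matrix = ma.simulate_cross(truth, n_offspring=n, missing_rate=0.0, seed=7)
        a = (matrix.calls.iloc[0] == "lm").to_numpy()
        b = (matrix.calls.iloc[1] == "lm").to_numpy()
        obs = (a != b).mean()
        r = ma.kosambi_r(d)
        assert abs(obs - r) < 3 * math.sqrt(r * (1 - r) / n)

    def test_depths_nonnegative_and_overdispersed(self):
        truth, _ = ma.simulate_genome(n_chrom=1, chrom_len=50_000,
                                      n_scaffolds=1, seed=2, markers_per_chrom=10)
        matrix = ma.simulate_cross(truth, n_offspring=2000, seed=8,
                                   depth_params=(30.0, 0.3))
        d = matrix.depths.to_numpy().ravel()
        assert (d >= 0).all()
        assert d.var() > d.mean()  # negative binomial, not Poisson


class TestPerturbMap:
    def test_identity_when_no_noise(self, small_world):
        truth, _s, maps = small_world
        out = ma.perturb_map(maps[0], jitter_cm=0, swap_rate=0, drop_rate=0)
        assert out.placements == maps[0].placements

    def test_drop_everything(self, small_world):
        truth, _s, maps = small_world
        out = ma.perturb_map(maps[0], drop_rate=1.0, seed=1)
        assert len(out) == 0

    def test_small_jitter_keeps_rank_order(self):
        truth, _ = ma.simulate_genome(n_chrom=1, chrom_len=4_000_000,
                                      n_scaffolds=4, seed=3,
                                      markers_per_chrom=100, cm_per_mb=25.0)
        base = true_map(truth, "t", 1.0)
        noisy = ma.perturb_map(base, jitter_cm=0.5, seed=9)
        true_cm = {m.marker_id: m.true_cm for m in truth.marker_truth}
        got = [(p.cm, true_cm[p.marker_id]) for p in noisy.placements]
        rho = stats.spearmanr([g[0] for g in got], [g[1] for g in got]).statistic
        assert rho > 0.99

    def test_invalid_rates_rejected(self, small_world):
        _t, _s, maps = small_world
        with pytest.raises(ValueError):
            ma.perturb_map(maps[0], drop_rate=1.5)


class TestSimulateBulks:
    def test_expected_delta_formula(self):
        # at the causal position r=0: indices 0.5 / 0.0, delta 0.5;
        # at r=0.25: delta 0.25; unlinked: delta 0
        for r, expected in [(0.0, 0.5), (0.25, 0.25), (0.5, 0.0)]:
            assert (1 - 2 * r) / 2 == pytest.approx(expected)

    def test_causal_region_enriched(self):
        truth, _ = ma.simulate_genome(n_chrom=3, chrom_len=2_000_000,
                                      n_scaffolds=6, seed=4, cm_per_mb=25.0)
        table = ma.simulate_bulks(truth, n_snps_per_chrom=2000,
                                  mean_depth=50, seed=5)
        df = ma.abs_delta(table)
        chrom, pos, _cm = truth.causal_locus
        near = df[(df["chrom"] == f"chr{chrom}") & (abs(df["pos"] - pos) < 50_000)]
        far = df[df["chrom"] != f"chr{chrom}"]
        assert near["abs_delta"].mean() > 0.4
        assert far["abs_delta"].mean() < 0.2

    def test_determinism(self):
        truth, _ = ma.simulate_genome(n_chrom=2, chrom_len=200_000,
                                      n_scaffolds=4, seed=4)
        t1 = ma.simulate_bulks(truth, n_snps_per_chrom=100, seed=6)
        t2 = ma.simulate_bulks(truth, n_snps_per_chrom=100, seed=6)
        assert t1.frame.equals(t2.frame)

    def test_bad_depth_rejected(self, small_world):
        truth, _s, _m = small_world
        with pytest.raises(ValueError):
            ma.simulate_bulks(truth, mean_depth=0)
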