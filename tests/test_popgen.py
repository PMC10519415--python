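"""VCF filtering, diversity statistics, LD, and mating-type classification."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from htrscan import simulate
from htrscan.popgen import (
    FilterThresholds,
    PloidyError,
    TajimaDNullBank,
    diversity,
    filter_vcf,
    ld_decay,
    ld_prune,
    mating_type,
    mating_type_summary,
    tajima_d,
    tajima_d_null_interval,
    variant_table_from_matrix,
)
from htrscan.simulate import SimulationConfig, reference_idiomorphs, simulate_variants


def _vt(geno, positions=None, L=None):
    geno = np.asarray(geno, dtype=np.int8)
    if positions is None:
        positions = np.arange(1, geno.shape[0] + 1) * 100
    if L is None:
        L = int(max(positions, default=0)) + 100
    return variant_table_from_matrix(geno, positions, L)


class TestFilterVcf:
    def _write(self, tmp_path, seed=21, fail_fraction=0.0, theta=0.004):
        cfg = SimulationConfig(seed=seed, genome_length=100_000,
                               n_strains_per_species=5, theta=theta)
        path = tmp_path / "v.vcf"
        geno, pos, info = simulate_variants(cfg, out_vcf=path, method="fixed_s",
                                            fail_fraction=fail_fraction)
        return path, geno, pos, info

    def test_clean_vcf_fully_retained(self, tmp_path):
        path, geno, pos, _ = self._write(tmp_path)
        vt, tally = filter_vcf(path)
        assert tally["retained"] == pos.size
        assert sum(v for k, v in tally.items() if k != "retained") == 0
        assert np.array_equal(vt.genotypes, geno)
        assert np.array_equal(vt.positions, pos)
        assert vt.genome_length == 100_000
        assert vt.samples == [f"s{i}" for i in range(5)]

    def test_failing_sites_removed_and_tallied(self, tmp_path):
        path, _, pos, info = self._write(tmp_path, fail_fraction=0.4)
        vt, tally = filter_vcf(path)
        n_bad = int(((info["QD"] < 2) | (info["MQ"] < 40) | (info["FS"] > 60)).sum())
        assert tally["QD"] + tally["MQ"] + tally["FS"] == n_bad
        assert tally["retained"] == pos.size - n_bad
        assert vt.n_sites == tally["retained"]
        assert (vt.info["QD"] >= 2).all()

    def test_custom_thresholds(self, tmp_path):
        path, _, pos, info = self._write(tmp_path)
        strict = FilterThresholds(qd_min=50.0)  # everything fails QD
        vt, tally = filter_vcf(path, strict)
        assert tally["retained"] == 0 and vt.n_sites == 0

    def test_indel_and_multiallelic_removed(self, tmp_path):
        p = tmp_path / "m.vcf"
        p.write_text(
            "##fileformat=VCFv4.2\n"
            "##contig=<ID=chr1,length=10000>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts0\ts1\ts2\n"
            "chr1\t100\t.\tA\tAT\t100\tPASS\t.\tGT\t0\t1\t0\n"
            "chr1\t200\t.\tA\tG,T\t100\tPASS\t.\tGT\t0\t1\t2\n"
            "chr1\t300\t.\tA\tG\t100\tPASS\t.\tGT\t0\t1\t1\n"
        )
        vt, tally = filter_vcf(p)
        assert tally["indel"] == 1 and tally["non_biallelic"] == 1
        assert tally["retained"] == 1
        assert vt.genotypes.tolist() == [[0, 1, 1]]

    def test_excess_missingness_removed(self, tmp_path):
        p = tmp_path / "m.vcf"
        p.write_text(
            "##fileformat=VCFv4.2\n"
            "##contig=<ID=chr1,length=10000>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts0\ts1\ts2\ts3\n"
            "chr1\t100\t.\tA\tG\t100\tPASS\t.\tGT\t0\t1\t.\t.\n"
            "chr1\t200\t.\tA\tG\t100\tPASS\t.\tGT\t0\t1\t1\t0\n"
        )
        vt, tally = filter_vcf(p)
        assert tally["missing"] == 1 and tally["retained"] == 1

    def test_diploid_rejected(self, tmp_path):
        p = tmp_path / "d.vcf"
        p.write_text(
            "##fileformat=VCFv4.2\n"
            "##contig=<ID=chr1,length=10000>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts0\n"
            "chr1\t100\t.\tA\tG\t100\tPASS\t.\tGT\t0/1\n"
        )
        with pytest.raises(PloidyError, match="ploidy"):
            filter_vcf(p)


class TestDiversity:
    def test_worked_example(self):
        """n=4, L=100, 3 segregating sites with derived counts (1, 2, 1):
        pi_total = (3+4+3)/6 * ... computed by hand below."""
        geno = np.array([[1, 0, 0, 0], [1, 1, 0, 0], [0, 0, 0, 1]], dtype=np.int8)
        vt = _vt(geno, positions=[10, 50, 90], L=100)
        st_ = diversity(vt, compute_null=False, jackknife_block=None)
        # per-site pairwise diversity: 2*n0*n1/(n(n-1)) = (2*3*1 + 2*2*2 + 2*3*1)/12
        pi_total = (6 + 8 + 6) / 12
        assert st_.pi == pytest.approx(pi_total / 100)
        assert st_.pi == pytest.approx(0.0166667, abs=1e-6)
        a1 = 1 + 1 / 2 + 1 / 3
        assert st_.theta_w == pytest.approx(3 / (a1 * 100))
        assert st_.theta_w == pytest.approx(0.0163636, abs=1e-6)
        assert st_.S == 3
        # frozen value of Tajima's D for this configuration
        assert tajima_d(pi_total, 3, 4) == pytest.approx(st_.tajima_d)

    def test_missing_data_pairwise_complete(self):
        geno = np.array([[1, 0, 0, -1]], dtype=np.int8)
        vt = _vt(geno, positions=[10], L=100)
        st_ = diversity(vt, compute_null=False, jackknife_block=None)
        # 3 called strains, one derived: 2*2*1/(3*2) = 2/3
        assert st_.pi == pytest.approx((2 / 3) / 100)
        assert st_.S == 1

    def test_no_variation(self):
        vt = _vt(np.zeros((0, 5), dtype=np.int8), positions=[], L=1000)
        st_ = diversity(vt, compute_null=False, jackknife_block=None)
        assert st_.pi == 0.0 and st_.theta_w == 0.0 and st_.S == 0
        assert math.isnan(st_.tajima_d)

    def test_d_degenerate_below_four_samples(self):
        assert math.isnan(tajima_d(1.0, 2, 3))

    def test_d_sign_convention(self):
        """Excess of rare variants (singletons) pushes D negative; excess of
        intermediate-frequency variants pushes it positive."""
        n = 10
        singletons = np.zeros((20, n), dtype=np.int8)
        singletons[:, 0] = 1
        mid = np.zeros((20, n), dtype=np.int8)
        mid[:, : n // 2] = 1
        d_neg = diversity(_vt(singletons), compute_null=False,
                          jackknife_block=None).tajima_d
        d_pos = diversity(_vt(mid), compute_null=False, jackknife_block=None).tajima_d
        assert d_neg < 0 < d_pos

    def test_coalescent_estimates_recover_theta(self):
        cfg = SimulationConfig(seed=33, genome_length=400_000,
                               n_strains_per_species=8, theta=0.005)
        geno, pos, _ = simulate_variants(cfg, method="coalescent")
        vt = variant_table_from_matrix(geno, pos, cfg.genome_length)
        st_ = diversity(vt, compute_null=False, jackknife_block=100_000)
        assert st_.pi == pytest.approx(cfg.theta, rel=0.35)
        assert st_.theta_w == pytest.approx(cfg.theta, rel=0.35)
        assert st_.pi_se is not None and 0 < st_.pi_se < st_.pi

    def test_jackknife_se_scale(self):
        cfg = SimulationConfig(seed=35, genome_length=500_000,
                               n_strains_per_species=6, theta=0.004)
        geno, pos, _ = simulate_variants(cfg, method="fixed_s")
        vt = variant_table_from_matrix(geno, pos, cfg.genome_length)
        st_ = diversity(vt, compute_null=False, jackknife_block=100_000)
        # SE should be well below the estimate but nonzero
        assert 0 < st_.pi_se < 0.5 * st_.pi
        assert 0 < st_.theta_w_se < 0.5 * st_.theta_w


class TestTajimaNull:
    def test_bank_contains_zero_and_brackets_neutral(self):
        bank = TajimaDNullBank(8, n_sims=2000, seed=5)
        lo, hi = bank.interval(50)
        assert lo < 0 < hi
        assert -3 < lo < -1 and 1 < hi < 3

    def test_draws_cached_and_reproducible(self):
        bank = TajimaDNullBank(6, n_sims=500, seed=9)
        d1 = bank.draws(30)
        d2 = bank.draws(30)
        assert d1 is d2
        bank2 = TajimaDNullBank(6, n_sims=500, seed=9)
        assert np.allclose(bank2.draws(30), d1)

    def test_wrapper_matches_bank(self):
        lo, hi, ds = tajima_d_null_interval(6, 25, n_sims=500, seed=3)
        assert ds.size == 500 and lo < hi

    def test_preconditions(self):
        with pytest.raises(ValueError):
            TajimaDNullBank(3, n_sims=10)
        with pytest.raises(ValueError):
            tajima_d_null_interval(6, 0)

    def test_neutral_d_falls_inside_own_null(self):
        cfg = SimulationConfig(seed=41, genome_length=200_000,
                               n_strains_per_species=8, theta=0.004)
        geno, pos, _ = simulate_variants(cfg, method="coalescent")
        vt = variant_table_from_matrix(geno, pos, cfg.genome_length)
        st_ = diversity(vt, null_sims=2000, seed=1, jackknife_block=None)
        lo, hi = st_.d_null_ci
        assert lo <= st_.tajima_d <= hi


class TestLD:
    def test_clonal_r2_is_one(self):
        cfg = SimulationConfig(seed=51, genome_length=60_000,
                               n_strains_per_species=8, theta=0.004)
        geno, pos, _ = simulate_variants(cfg, method="clonal")
        vt = variant_table_from_matrix(geno, pos, cfg.genome_length)
        df = ld_decay(vt, window=15_000, maf_min=0.2)
        assert len(df) > 0
        assert np.allclose(df["mean_r2"], 1.0)

    def test_recombining_ld_decays(self):
        cfg = SimulationConfig(seed=53, genome_length=400_000,
                               n_strains_per_species=10, theta=0.005)
        geno, pos, _ = simulate_variants(cfg, method="coalescent")
        vt = variant_table_from_matrix(geno, pos, cfg.genome_length)
        df = ld_decay(vt, window=15_000, maf_min=0.2)
        near = df[df.distance_bin < 2_000]["mean_r2"].mean()
        far = df[df.distance_bin > 10_000]["mean_r2"].mean()
        assert near > far

    def test_ld_decay_empty_warns(self):
        vt = _vt(np.zeros((0, 5), dtype=np.int8), positions=[], L=1000)
        with pytest.warns(UserWarning, match="no qualifying"):
            df = ld_decay(vt)
        assert df.empty

    def test_prune_removes_duplicate_sites(self):
        row = np.array([0, 0, 1, 1, 0, 1], dtype=np.int8)
        geno = np.tile(row, (5, 1))
        vt = _vt(geno, positions=[100, 200, 300, 400, 500])
        out = ld_prune(vt, window=1000)
        assert out.n_sites == 1

    def test_prune_keeps_independent_sites(self, rng):
        geno = rng.integers(0, 2, size=(30, 12)).astype(np.int8)
        pos = np.sort(rng.choice(np.arange(1, 200_000), 30, replace=False))
        vt = _vt(geno, positions=pos, L=200_000)
        out = ld_prune(vt, window=1000)
        # fixed point: pruning again changes nothing
        again = ld_prune(out, window=1000)
        assert np.array_equal(again.genotypes, out.genotypes)

    def test_prune_maf_filter(self):
        # singleton sites (minor count 1) are dropped before pruning
        geno = np.zeros((3, 10), dtype=np.int8)
        geno[:, 0] = 1
        vt = _vt(geno, positions=[100, 5_000, 10_000])
        assert ld_prune(vt).n_sites == 0


class TestMatingType:
    def test_planted_idiomorphs_recovered(self, small_panel):
        _, assemblies, _, truth = small_panel
        refs = reference_idiomorphs()
        for strain, seq in assemblies.items():
            call, scores = mating_type(seq, refs)
            assert call == truth.planted_mating_type[strain]
            assert scores[call] > 0.9
            other = next(k for k in scores if k != call)
            assert scores[other] < 0.1

    def test_none_when_absent(self, rng):
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 20_000))
        call, scores = mating_type(seq, reference_idiomorphs())
        assert call == "none"
        assert all(v < 0.1 for v in scores.values())

    def test_both_when_both_present(self):
        refs = reference_idiomorphs()
        call, _ = mating_type(refs["MAT1-1"] + refs["MAT1-2"], refs)
        assert call == "both"

    def test_empty_references_rejected(self):
        with pytest.raises(ValueError, match="idiomorph"):
            mating_type("ACGT" * 100, {})

    def test_summary_counts(self):
        df = mating_type_summary(
            {"a": "MAT1-1", "b": "MAT1-2", "c": "MAT1-2", "d": "none"}
        )
        counts = dict(zip(df["mating_type"], df["n_strains"]))
        assert counts == {"MAT1-2": 2, "MAT1-1": 1, "none": 1}


class TestProperties:
    @given(
        n=st.integers(4, 12),
        m=st.integers(1, 40),
        seed=st.integers(0, 10_000),
    )
    @settings(max_examples=40, deadline=None)
    def test_pi_bounds_and_theta_positive(self, n, m, seed):
        r = np.random.default_rng(seed)
        geno = r.integers(0, 2, size=(m, n)).astype(np.int8)
        pos = np.sort(r.choice(np.arange(1, 100_000), m, replace=False))
        vt = _vt(geno, positions=pos, L=100_000)
        st_ = diversity(vt, compute_null=False, jackknife_block=None)
        assert 0.0 <= st_.pi <= 0.5  # per-site pi can never exceed 1/2 + eps
        assert st_.theta_w >= 0.0
        assert st_.S <= m

    @given(seed=st.integers(0, 5_000))
    @settings(max_examples=30, deadline=None)
    def test_prune_fixed_point(self, seed):
        r = np.random.default_rng(seed)
        geno = r.integers(0, 2, size=(25, 8)).astype(np.int8)
        pos = np.sort(r.choice(np.arange(1, 20_000), 25, replace=False))
        vt = _vt(geno, positions=pos, L=20_000)
        out = ld_prune(vt)
        again = ld_prune(out)
        assert np.array_equal(again.genotypes, out.genotypes)
        assert np.array_equal(again.positions, out.positions)
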