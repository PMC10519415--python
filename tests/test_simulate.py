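"""Synthetic panel / variant / MK-count generators and their invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from htrscan import simulate
from htrscan.simulate import (
    ConfigError,
    HTRSpec,
    SelectionSpec,
    SimulationConfig,
    simulate_mk_counts,
    simulate_panel,
    simulate_variants,
)


def _pairwise_identity(a: str, b: str) -> float:
    assert len(a) == len(b)
    return sum(x == y for x, y in zip(a, b)) / len(a)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs,field",
        [
            (dict(n_species=0), "n_species"),
            (dict(background_divergence=0.9), "background_divergence"),
            (dict(genome_length=0), "genome_length"),
            (dict(n_strains_per_species=0), "n_strains_per_species"),
            (dict(theta=-0.1), "theta"),
            (dict(te_density=1.5), "te_density"),
            (dict(htr_specs=(HTRSpec(0),)), "htr_specs"),
            (dict(htr_specs=(HTRSpec(60_000),), genome_length=100_000), "htr_specs"),
            (dict(htr_specs=(HTRSpec(1000, identity=1.5),)), "htr_specs"),
            (dict(htr_specs=(HTRSpec(1000, recipients=(5,)),)), "htr_specs"),
        ],
    )
    def test_invalid_config_names_field(self, kwargs, field):
        cfg = SimulationConfig(**kwargs)
        with pytest.raises(ConfigError, match=field):
            cfg.validate()


class TestPanel:
    def test_determinism(self, small_panel):
        cfg, assemblies, annotations, truth = small_panel
        a2, ann2, t2 = simulate_panel(cfg)
        assert a2 == assemblies
        assert ann2 == annotations
        assert t2.planted_htrs == truth.planted_htrs

    def test_strain_ids_and_lengths(self, small_panel):
        cfg, assemblies, _, _ = small_panel
        assert set(assemblies) == {"sp0_s0", "sp0_s1", "sp1_s0", "sp1_s1"}
        for seq in assemblies.values():
            # core genome plus one appended mating-type cassette
            assert len(seq) == cfg.genome_length + 900
            assert set(seq) <= set("ACGT")

    def test_truth_intervals_valid(self, small_panel):
        _, assemblies, _, truth = small_panel
        truth.validate_against({k: len(v) for k, v in assemblies.items()})
        for ivs in truth.planted_htrs.values():
            assert len(ivs) == 2

    def test_planted_identity_matches_spec(self, small_panel):
        """The planted copy in each recipient reference sits at the configured
        identity to the donor segment, hence cross-species copy identity is
        close to 2*identity - 1."""
        cfg, assemblies, _, truth = small_panel
        for (s0, e0, i0), (s1, e1, i1) in zip(
            sorted(truth.planted_htrs["sp0_s0"], key=lambda t: t[2]),
            sorted(truth.planted_htrs["sp1_s0"], key=lambda t: t[2]),
        ):
            assert i0 == i1
            spec = cfg.htr_specs[i0]
            obs = _pairwise_identity(
                assemblies["sp0_s0"][s0:e0], assemblies["sp1_s0"][s1:e1]
            )
            expect = 2 * spec.identity - 1
            assert obs == pytest.approx(expect, abs=0.004)

    def test_background_divergence_outside_htrs(self, small_panel):
        cfg, assemblies, _, truth = small_panel
        mask = np.zeros(cfg.genome_length, dtype=bool)
        for strain in ("sp0_s0", "sp1_s0"):
            for s, e, _ in truth.planted_htrs[strain]:
                mask[s:e] = True
        a = np.frombuffer(assemblies["sp0_s0"][: cfg.genome_length].encode(), np.uint8)
        b = np.frombuffer(assemblies["sp1_s0"][: cfg.genome_length].encode(), np.uint8)
        bg_identity = np.mean(a[~mask] == b[~mask])
        assert bg_identity == pytest.approx(1 - cfg.background_divergence, abs=0.01)

    def test_within_species_divergence_near_theta(self, small_panel):
        cfg, assemblies, _, _ = small_panel
        a = assemblies["sp0_s0"][: cfg.genome_length]
        b = assemblies["sp0_s1"][: cfg.genome_length]
        div = 1 - _pairwise_identity(a, b)
        # strain 1 carries Poisson(theta/2 * L) substitutions vs the reference
        assert div == pytest.approx(cfg.theta / 2, rel=0.5)

    def test_te_at_edges_planted(self, small_panel):
        cfg, _, annotations, truth = small_panel
        for strain, ivs in truth.planted_htrs.items():
            tes = [(s, e) for s, e, k in annotations[strain] if k == "TE"]
            for s, e, idx in ivs:
                if cfg.htr_specs[idx].te_at_edges:
                    assert any(ts < s < te for ts, te in tes)
                    assert any(ts < e < te for ts, te in tes)

    def test_write_panel_files(self, small_panel, tmp_path):
        from Bio import SeqIO

        cfg, assemblies, annotations, truth = small_panel
        written = simulate.write_panel(tmp_path, assemblies, annotations, truth)
        assert all(p.exists() for p in written)
        rec = next(SeqIO.parse(tmp_path / "sp0_s0.fasta", "fasta"))
        assert str(rec.seq) == assemblies["sp0_s0"]
        gff = (tmp_path / "annotations.gff3").read_text().splitlines()
        assert gff[0] == "##gff-version 3"
        bed_lines = (tmp_path / "truth_htrs.bed").read_text().splitlines()
        assert len(bed_lines) == sum(len(v) for v in truth.planted_htrs.values())
        first = bed_lines[0].split("\t")
        assert int(first[1]) < int(first[2])

    def test_mating_type_assignment(self):
        cfg = SimulationConfig(
            seed=3, genome_length=20_000, n_strains_per_species=2,
            mat1_1_strains=("sp0_s0", "sp1_s1"),
        )
        _, _, truth = simulate_panel(cfg)
        assert truth.planted_mating_type == {
            "sp0_s0": "MAT1-1", "sp0_s1": "MAT1-2",
            "sp1_s0": "MAT1-2", "sp1_s1": "MAT1-1",
        }

    def test_idiomorphs_are_stop_free_orfs(self):
        refs = simulate.reference_idiomorphs()
        assert set(refs) == {"MAT1-1", "MAT1-2"}
        for seq in refs.values():
            assert len(seq) % 3 == 0
            assert seq.startswith("ATG")
            codons = {seq[i : i + 3] for i in range(0, len(seq), 3)}
            assert not codons & {"TAA", "TAG", "TGA"}
        # determinism across calls
        assert simulate.reference_idiomorphs() == refs


class TestVariants:
    def test_coalescent_shapes_and_polymorphism(self):
        cfg = SimulationConfig(seed=5, genome_length=100_000, n_strains_per_species=6,
                               theta=0.005)
        geno, pos, info = simulate_variants(cfg, method="coalescent")
        assert geno.shape == (pos.size, 6)
        assert geno.dtype == np.int8
        assert np.all((geno == 0) | (geno == 1))
        assert np.all(np.diff(pos) > 0) and pos[0] >= 1 and pos[-1] <= 100_000
        counts = geno.sum(axis=1)
        # back-mutation under the binary model can leave a few sites
        # monomorphic; nearly all should segregate
        assert np.mean((counts >= 1) & (counts <= 5)) > 0.95
        assert list(info.columns) == ["QD", "MQ", "FS", "MQRankSum", "ReadPosRankSum"]
        assert len(info) == pos.size

    def test_coalescent_s_near_expectation(self):
        cfg = SimulationConfig(seed=7, genome_length=200_000, n_strains_per_species=6,
                               theta=0.005)
        geno, pos, _ = simulate_variants(cfg, method="coalescent")
        a1 = sum(1 / i for i in range(1, 6))
        expected_s = cfg.theta * a1 * cfg.genome_length
        assert pos.size == pytest.approx(expected_s, rel=0.35)

    def test_fixed_s_exact_count(self):
        cfg = SimulationConfig(seed=9, genome_length=100_000, n_strains_per_species=5,
                               theta=0.004)
        geno, pos, _ = simulate_variants(cfg, method="fixed_s")
        a1 = sum(1 / i for i in range(1, 5))
        assert pos.size == int(round(cfg.theta * a1 * cfg.genome_length))
        assert np.all((geno.sum(axis=1) >= 1) & (geno.sum(axis=1) <= 4))

    def test_clonal_two_lineages(self):
        cfg = SimulationConfig(seed=11, genome_length=50_000, n_strains_per_species=6,
                               theta=0.004)
        geno, pos, _ = simulate_variants(cfg, method="clonal")
        assert pos.size > 0
        # every site splits samples into the same two groups
        assert np.all(geno == geno[0])
        assert geno[0].sum() == 3

    def test_theta_zero_no_sites(self):
        cfg = SimulationConfig(seed=1, genome_length=50_000, n_strains_per_species=4,
                               theta=0.0)
        geno, pos, info = simulate_variants(cfg)
        assert pos.size == 0 and geno.shape == (0, 4) and len(info) == 0

    def test_single_strain_rejected(self):
        cfg = SimulationConfig(seed=1, genome_length=50_000, n_strains_per_species=1)
        with pytest.raises(ConfigError, match="n_strains_per_species"):
            simulate_variants(cfg)

    def test_fail_fraction_marks_sites(self):
        cfg = SimulationConfig(seed=13, genome_length=100_000, n_strains_per_species=5,
                               theta=0.005)
        _, _, info = simulate_variants(cfg, method="fixed_s", fail_fraction=0.3)
        failing = (info["QD"] < 2) | (info["MQ"] < 40) | (info["FS"] > 60)
        assert failing.mean() == pytest.approx(0.3, abs=0.06)

    def test_vcf_round_trip_positions(self, tmp_path):
        import pysam

        cfg = SimulationConfig(seed=15, genome_length=80_000, n_strains_per_species=4,
                               theta=0.003)
        geno, pos, _ = simulate_variants(cfg, out_vcf=tmp_path / "v.vcf",
                                         method="fixed_s")
        vf = pysam.VariantFile(str(tmp_path / "v.vcf"))
        recs = list(vf)
        assert [r.pos for r in recs] == list(pos)
        got = np.array([[r.samples[s]["GT"][0] for s in r.samples] for r in recs],
                       dtype=np.int8)
        assert np.array_equal(got, geno)


class TestMKCounts:
    def test_columns_and_classes(self):
        df = simulate_mk_counts(SelectionSpec(n_positive=10, n_negative=5), 50, seed=2)
        assert list(df.columns) == [
            "gene_id", "PS", "PR", "DS", "DR", "Lsyn", "Lrep",
            "true_class", "true_selection_effect",
        ]
        assert (df["true_class"] == "positive").sum() == 10
        assert (df["true_class"] == "negative").sum() == 5
        assert (df[["PS", "PR", "DS", "DR"]] >= 0).all().all()
        assert np.all(df["Lrep"] == 3 * df["Lsyn"])

    def test_effect_signs(self):
        df = simulate_mk_counts(SelectionSpec(5, 5, effect=1.5), 20, seed=4)
        assert np.all(df.loc[df.true_class == "positive", "true_selection_effect"] == 1.5)
        assert np.all(df.loc[df.true_class == "negative", "true_selection_effect"] == -1.5)
        assert np.all(np.abs(df.loc[df.true_class == "neutral",
                                    "true_selection_effect"]) < 1.0)

    def test_positive_selection_raises_dr(self):
        df = simulate_mk_counts(SelectionSpec(n_positive=100), 200, seed=6)
        pos = df[df.true_class == "positive"]
        neu = df[df.true_class == "neutral"]
        assert (pos["DR"] / pos["Lrep"]).mean() > 2 * (neu["DR"] / neu["Lrep"]).mean()

    def test_class_overflow_rejected(self):
        with pytest.raises(ConfigError, match="n_genes"):
            simulate_mk_counts(SelectionSpec(30, 30), 50, seed=0)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_counts_deterministic_in_seed(self, seed):
        a = simulate_mk_counts(SelectionSpec(2, 2), 10, seed=seed)
        b = simulate_mk_counts(SelectionSpec(2, 2), 10, seed=seed)
        assert a.equals(b)
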