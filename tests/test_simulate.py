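"""Synthetic CC population and expression generators."""

import filecmp

import numpy as np
import pandas as pd
import pytest

from cceqtl.genome import ConfigurationError, GenomeSpec
from cceqtl.simulate import (
    FounderDosageTable,
    IsoformGeneSpec,
    TraitSpec,
    assign_replicates,
    dosage_from_mosaic,
    ground_truth_table,
    read_trait_matrix,
    simulate_cc_population,
    simulate_isoform_ratios,
    simulate_total_expression,
    write_fixture,
)


class TestGenomeSpec:
    def test_intervals_tile_without_overlap(self):
        gs = GenomeSpec([("chr1", 5_000_000), ("chr2", 3_500_000)], 2_000_000)
        iv = gs.intervals()
        assert list(iv["start"]) == [0, 2_000_000, 4_000_000, 0, 2_000_000]
        assert list(iv["end"]) == [2_000_000, 4_000_000, 5_000_000, 2_000_000, 3_500_000]
        for chrom, sub in iv.groupby("chrom"):
            assert (sub["start"].to_numpy()[1:] == sub["end"].to_numpy()[:-1]).all()

    def test_rejects_bad_configuration(self):
        with pytest.raises(ConfigurationError):
            GenomeSpec([("chr1", 10)], 0)
        with pytest.raises(ConfigurationError):
            GenomeSpec([("chr1", 0)], 10)
        with pytest.raises(ConfigurationError):
            GenomeSpec([], 10)


class TestMosaics:
    def test_zero_recombination_gives_single_founder_lines(self, small_genome):
        mos = simulate_cc_population(12, small_genome, recomb_rate_per_mb=0.0, seed=3)
        for row in mos.founder:
            assert len(set(row.tolist())) == 1

    def test_same_seed_reproduces_mosaics(self, small_genome):
        a = simulate_cc_population(10, small_genome, 0.05, seed=11)
        b = simulate_cc_population(10, small_genome, 0.05, seed=11)
        np.testing.assert_array_equal(a.founder, b.founder)
        c = simulate_cc_population(10, small_genome, 0.05, seed=12)
        assert not np.array_equal(a.founder, c.founder)

    def test_founder_frequencies_near_uniform_across_lines(self):
        # 800 independent lines; at any single interval the founder counts
        # are multinomial(800, 1/8)
        gs = GenomeSpec([("chr1", 100_000_000)], 2_000_000)
        mos = simulate_cc_population(800, gs, recomb_rate_per_mb=0.05, seed=5)
        se = np.sqrt(0.125 * 0.875 / 800)
        for j in (0, 25, 49):
            freq = np.bincount(mos.founder[:, j], minlength=8) / 800
            assert np.all(np.abs(freq - 0.125) < 3 * se)

    def test_rejects_invalid_parameters(self, small_genome):
        with pytest.raises(ConfigurationError):
            simulate_cc_population(0, small_genome, 0.05, seed=1)
        with pytest.raises(ConfigurationError):
            simulate_cc_population(5, small_genome, -0.1, seed=1)


class TestDosages:
    def test_zero_uncertainty_is_one_hot(self, small_population):
        dos = dosage_from_mosaic(small_population, uncertainty=0.0)
        assert set(np.unique(dos.dosages)) == {0.0, 1.0}
        np.testing.assert_allclose(dos.dosages.sum(axis=2), 1.0)

    def test_uncertainty_spreads_mass_uniformly(self, small_population):
        dos = dosage_from_mosaic(small_population, uncertainty=0.14)
        truth = small_population.founder
        assert np.isclose(dos.dosages[0, 0, truth[0, 0]], 0.86)
        others = np.delete(dos.dosages[0, 0], truth[0, 0])
        np.testing.assert_allclose(others, 0.02)
        np.testing.assert_allclose(dos.dosages.sum(axis=2), 1.0, atol=1e-12)

    def test_rejects_out_of_range_uncertainty(self, small_population):
        for bad in (-0.1, 1.0, 1.5):
            with pytest.raises(ValueError):
                dosage_from_mosaic(small_population, uncertainty=bad)

    def test_frame_round_trip(self, small_dosage):
        back = FounderDosageTable.from_frame(small_dosage.to_frame())
        assert back.line_ids == small_dosage.line_ids
        np.testing.assert_allclose(back.dosages, small_dosage.dosages)


def _spec(trait_id="T1", causal=None, alpha=None, sigma_line=0.0, sigma_eps=0.0, baseline=1.0):
    return TraitSpec(
        trait_id=trait_id,
        gene_id=f"g_{trait_id}",
        kind="total",
        tss=("chr1", 5_000_000),
        causal_interval=causal,
        alpha=np.zeros(8) if alpha is None else np.asarray(alpha, dtype=float),
        sigma_line=sigma_line,
        sigma_eps=sigma_eps,
        baseline=baseline,
    )


class TestTotalExpression:
    def test_noiseless_limit_is_constant_exp_baseline(self, small_dosage):
        tm = simulate_total_expression(small_dosage, [_spec(baseline=1.3)], 2, seed=0)
        np.testing.assert_allclose(tm.values.to_numpy(), np.exp(1.3))

    def test_outputs_nonnegative(self, small_dosage):
        spec = _spec(sigma_line=1.0, sigma_eps=2.0, baseline=-3.0)
        tm = simulate_total_expression(small_dosage, [spec], (0.3, 0.5, 0.2), seed=1)
        assert (tm.values.to_numpy() >= 0).all()

    def test_carrier_lines_shift_upward(self):
        # Monte-Carlo group-mean oracle: founder-1 carriers should exceed
        # non-carriers when founder 1 carries a large positive effect
        gs = GenomeSpec([("chr1", 4_000_000)], 4_000_000)
        mos = simulate_cc_population(400, gs, 0.0, seed=9)
        dos = dosage_from_mosaic(mos)
        alpha = np.zeros(8)
        alpha[0] = 2.0
        spec = _spec(causal=0, alpha=alpha - alpha.mean(), sigma_line=0.3, sigma_eps=0.3)
        tm = simulate_total_expression(dos, [spec], 1, seed=2)
        latent = np.log(tm.values.to_numpy()[0])
        carrier = mos.founder[:, 0] == 0
        assert latent[carrier].mean() > latent[~carrier].mean() + 1.0

    def test_unknown_causal_interval_raises(self, small_dosage):
        spec = _spec(causal=99, alpha=np.array([1, -1, 0, 0, 0, 0, 0, 0], dtype=float))
        with pytest.raises(ValueError, match="99"):
            simulate_total_expression(small_dosage, [spec], 2, seed=0)

    def test_spec_consistency_enforced(self):
        with pytest.raises(ValueError, match="causal"):
            _spec(causal=None, alpha=np.ones(8))
        with pytest.raises(ValueError, match="causal"):
            _spec(causal=3, alpha=None)

    def test_heritability_decomposition(self):
        # latent variance ~ genetic + line + residual at large n
        gs = GenomeSpec([("chr1", 4_000_000)], 4_000_000)
        mos = simulate_cc_population(300, gs, 0.0, seed=4)
        dos = dosage_from_mosaic(mos)
        alpha = np.array([1.0, 1.0, 1.0, 1.0, -1.0, -1.0, -1.0, -1.0])
        spec = _spec(causal=0, alpha=alpha, sigma_line=0.5, sigma_eps=0.7)
        tm = simulate_total_expression(dos, [spec], 2, seed=5)
        latent = np.log(tm.values.to_numpy()[0])
        expected = 1.0 + 0.25 + 0.49
        assert abs(np.var(latent) - expected) < 0.25


def _gene_spec(gene_id="ig1", causal=None, alpha=None, n_iso=3, sigma_line=0.0, sigma_eps=0.0):
    return IsoformGeneSpec(
        gene_id=gene_id,
        tss=("chr1", 5_000_000),
        isoform_baselines=np.linspace(0.5, -0.5, n_iso),
        causal_interval=causal,
        alpha=np.zeros(8) if alpha is None else np.asarray(alpha, dtype=float),
        sigma_line=sigma_line,
        sigma_eps=sigma_eps,
        target_isoform=0,
    )


class TestIsoformRatios:
    def test_percentages_sum_to_100_per_gene_and_sample(self, small_dosage):
        tm = simulate_isoform_ratios(
            small_dosage,
            [_gene_spec("ig1", sigma_eps=0.5), _gene_spec("ig2", n_iso=4, sigma_eps=0.5)],
            (0.3, 0.5, 0.2),
            seed=6,
        )
        sums = tm.values.groupby(tm.meta.set_index("trait_id")["gene_id"]).sum()
        np.testing.assert_allclose(sums.to_numpy(), 100.0, atol=1e-9)

    def test_zero_noise_zero_effect_is_constant(self, small_dosage):
        tm = simulate_isoform_ratios(small_dosage, [_gene_spec()], 2, seed=0)
        vals = tm.values.to_numpy()
        assert np.allclose(vals, vals[:, [0]])

    def test_carrier_founder_raises_target_isoform_share(self):
        gs = GenomeSpec([("chr1", 4_000_000)], 4_000_000)
        mos = simulate_cc_population(400, gs, 0.0, seed=8)
        dos = dosage_from_mosaic(mos)
        alpha = np.zeros(8)
        alpha[0] = 2.0
        spec = _gene_spec("ig1", causal=0, alpha=alpha - alpha.mean(), sigma_eps=0.3)
        tm = simulate_isoform_ratios(dos, [spec], 1, seed=9)
        iso1 = tm.values.loc["ig1.iso1"].to_numpy()
        carrier = mos.founder[:, 0] == 0
        assert iso1[carrier].mean() > iso1[~carrier].mean() + 5.0

    def test_single_isoform_gene_rejected(self):
        with pytest.raises(ValueError, match="2 isoforms"):
            _gene_spec(n_iso=1)


class TestReplicates:
    def test_fixed_count_and_mapping(self):
        sheet = assign_replicates(["A", "B"], 2, seed=0)
        assert list(sheet["line_id"]) == ["A", "A", "B", "B"]

    def test_distribution_draws_in_1_2_3(self):
        sheet = assign_replicates([f"L{i}" for i in range(200)], (0.3, 0.5, 0.2), seed=1)
        counts = sheet.groupby("line_id").size()
        assert set(counts.unique()) <= {1, 2, 3}
        assert abs(counts.mean() - 1.9) < 0.2

    def test_rejects_invalid_counts(self):
        with pytest.raises(ValueError):
            assign_replicates(["A"], 4, seed=0)
        with pytest.raises(ValueError):
            assign_replicates(["A"], (0.5, 0.5, 0.5), seed=0)


class TestFixtureIO:
    def _study(self, small_dosage, small_genome):
        alpha = np.array([1.0, -1.0, 0, 0, 0, 0, 0, 0])
        specs = [
            _spec("T1", causal=2, alpha=alpha, sigma_line=0.2, sigma_eps=0.2),
            _spec("T2", sigma_line=0.2, sigma_eps=0.2),
        ]
        tm = simulate_total_expression(small_dosage, specs, 2, seed=3)
        ann = pd.DataFrame(
            {"gene_id": ["g_T1", "g_T2"], "chrom": "chr1", "tss": 5_000_000, "strand": "+"}
        )
        truth = ground_truth_table(small_genome, specs, [])
        return tm, ann, truth

    def test_round_trip_and_ground_truth(self, small_dosage, small_genome, tmp_path):
        tm, ann, truth = self._study(small_dosage, small_genome)
        paths = write_fixture(small_dosage, [tm], ann, tmp_path, ground_truth=truth)
        back = read_trait_matrix(paths["traits_total"])
        np.testing.assert_allclose(back.values.to_numpy(), tm.values.to_numpy())
        assert list(back.meta["trait_id"]) == list(tm.meta["trait_id"])
        truth_back = pd.read_csv(paths["ground_truth"], sep="\t")
        assert (truth_back["causal_start"] >= 0).sum() == 1  # one causal trait
        dos_back = FounderDosageTable.from_frame(pd.read_csv(paths["dosages"], sep="\t"))
        np.testing.assert_allclose(dos_back.dosages, small_dosage.dosages)

    def test_fixed_seed_writes_byte_identical_files(self, small_dosage, small_genome, tmp_path):
        tm, ann, truth = self._study(small_dosage, small_genome)
        p1 = write_fixture(small_dosage, [tm], ann, tmp_path / "a", ground_truth=truth)
        p2 = write_fixture(small_dosage, [tm], ann, tmp_path / "b", ground_truth=truth)
        for key in p1:
            assert filecmp.cmp(p1[key], p2[key], shallow=False), key

    def test_id_mismatch_is_reported(self, small_dosage, small_genome, tmp_path):
        tm, ann, truth = self._study(small_dosage, small_genome)
        bad_ann = ann[ann["gene_id"] != "g_T2"]
        with pytest.raises(ValueError, match="g_T2"):
            write_fixture(small_dosage, [tm], bad_ann, tmp_path, ground_truth=truth)


class TestScanDegeneracy:
    def test_zero_recombination_gives_flat_lr_along_chromosome(self):
        # rate 0 + uncertainty 0: each line has one founder genome-wide, so
        # every interval carries identical genotypes and identical LR
        from cceqtl.scan import scan_trait
        from cceqtl.transform import normal_scores

        gs = GenomeSpec([("chr1", 10_000_000)], 2_000_000)
        mos = simulate_cc_population(20, gs, 0.0, seed=13)
        dos = dosage_from_mosaic(mos)
        alpha = np.array([2.0, -2.0, 0, 0, 0, 0, 0, 0])
        spec = _spec("T1", causal=0, alpha=alpha, sigma_line=0.1, sigma_eps=0.1)
        tm = simulate_total_expression(dos, [spec], 2, seed=14)
        u = normal_scores(tm.values.to_numpy()[0])
        res = scan_trait(
            u, tm.samples["line_id"].to_numpy(), dos, ("chr1", 5_000_000),
            window=100_000_000,
        )
        np.testing.assert_allclose(res.lr, res.lr[0])
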