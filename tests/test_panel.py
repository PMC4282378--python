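"""Synthetic panel generation and reference-panel IO."""

import numpy as np
import pytest

import snpsieve as sv
from snpsieve.panel import (MafSpectrum, RegionProfile, generate_panel,
                            interpolate_map, load_panel, panel_maf,
                            read_recombination_map, write_panel,
                            write_recombination_map)


def _pairwise_r2(panel):
    return np.corrcoef(panel.alleles.T.astype(float)) ** 2


class TestGeneration:
    def test_deterministic_given_seed(self):
        prof = RegionProfile(n_snps=50, seed=7)
        a = generate_panel(prof, 200)
        b = generate_panel(prof, 200)
        assert np.array_equal(a.alleles, b.alleles)
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.map_cM, b.map_cM)

    def test_two_founders_one_block_gives_perfect_ld(self):
        # exact founder copying with no copy error forces r2 = 1 everywhere
        prof = RegionProfile(n_snps=20, region_length_bp=50_000,
                             mean_block_kb=1e6, n_founders=2, copy_error=0.0,
                             seed=3, maf_spectrum=MafSpectrum(low=0.35, high=0.5))
        panel = generate_panel(prof, 200)
        assert len(panel.block_bounds) == 1
        assert _pairwise_r2(panel).min() == pytest.approx(1.0)

    def test_realized_maf_respects_spectrum_floor(self):
        # spectrum floored at 0.05: realized MAFs stay above 0.03
        for seed in range(1, 21):
            prof = RegionProfile(n_snps=100, seed=seed,
                                 maf_spectrum=MafSpectrum(low=0.05, high=0.5))
            maf = panel_maf(generate_panel(prof, 2000))
            assert maf.min() >= 0.03
            assert maf.max() <= 0.5

    def test_all_snps_polymorphic(self, mixed_panel):
        assert panel_maf(mixed_panel).min() > 0

    def test_within_block_ld_exceeds_between_block(self):
        for block_kb in (8.0, 130.0):
            panel = generate_panel(
                RegionProfile(n_snps=150, mean_block_kb=block_kb, seed=5), 566)
            r2 = _pairwise_r2(panel)
            block_of = np.searchsorted(panel.block_bounds,
                                       np.arange(panel.n_snps), side="right")
            i, j = np.triu_indices(panel.n_snps, 1)
            same = block_of[i] == block_of[j]
            assert r2[i[same], j[same]].mean() > r2[i[~same], j[~same]].mean()

    def test_ld_regime_ordering_over_seeds(self):
        # mean r2 at <=50 kb must rank high > mixed > low LD profiles
        def mean_r2_short_range(block_kb, seed):
            panel = generate_panel(
                RegionProfile(n_snps=150, mean_block_kb=block_kb, seed=seed), 566)
            r2 = _pairwise_r2(panel)
            i, j = np.triu_indices(panel.n_snps, 1)
            near = (panel.positions[j] - panel.positions[i]) <= 50_000
            return r2[i[near], j[near]].mean()

        seeds = range(1, 11)
        high = np.mean([mean_r2_short_range(130.0, s) for s in seeds])
        mixed = np.mean([mean_r2_short_range(22.0, s) for s in seeds])
        low = np.mean([mean_r2_short_range(8.0, s) for s in seeds])
        assert high > mixed > low

    def test_map_monotone_with_hotspots_at_block_starts(self):
        prof = RegionProfile(n_snps=80, mean_block_kb=50.0, hotspot_cM=0.05,
                             cm_per_mb=1.0, seed=9)
        panel = generate_panel(prof, 200)
        assert np.all(np.diff(panel.map_cM) >= 0)
        # each interior block start adds the hotspot increment on top of the
        # background rate
        background = (panel.positions - panel.positions[0]) / 1e6
        extra = panel.map_cM - background
        n_interior = (panel.block_bounds > 0).sum()
        assert extra[-1] == pytest.approx(0.05 * n_interior, abs=1e-9)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            generate_panel(RegionProfile(n_snps=10, seed=0), 201)  # odd
        with pytest.raises(ValueError):
            generate_panel(RegionProfile(n_snps=10, n_founders=8, seed=0), 10)
        with pytest.raises(ValueError):
            RegionProfile(n_snps=1)
        with pytest.raises(ValueError):
            MafSpectrum(low=0.3, high=0.2)


class TestPanelMaf:
    @pytest.mark.parametrize("column, expected", [
        ((0, 0, 1, 1), 0.5),
        ((0, 0, 0, 0), 0.0),
        (tuple([1] * 3 + [0] * 17), 0.15),
    ])
    def test_known_columns(self, column, expected):
        h = len(column)
        alleles = np.zeros((h, 2), dtype=np.int8)
        alleles[:, 0] = column
        alleles[: h // 2, 1] = 1  # keep second column arbitrary
        panel = sv.HaplotypePanel(alleles, np.array([10, 20]),
                                  np.array([0.0, 0.1]), ["a", "b"])
        assert panel_maf(panel)[0] == pytest.approx(expected)


class TestIO:
    @pytest.mark.parametrize("fmt", ["impute-hap-legend", "phased-vcf"])
    def test_write_read_round_trip(self, tmp_path, mixed_panel, fmt):
        if fmt == "impute-hap-legend":
            hap, leg = tmp_path / "p.hap", tmp_path / "p.legend"
            write_panel(mixed_panel, hap, leg, format=fmt)
            again = load_panel(hap, legend_file=leg, format=fmt)
        else:
            vcf = tmp_path / "p.vcf"
            write_panel(mixed_panel, vcf, format=fmt)
            again = load_panel(vcf, format=fmt)
        assert np.array_equal(again.alleles, mixed_panel.alleles)
        assert np.array_equal(again.positions, mixed_panel.positions)
        assert again.snp_ids == mixed_panel.snp_ids

    def test_map_interpolation_and_extrapolation(self, tmp_path):
        mp = tmp_path / "genetic.map"
        mp.write_text("position rate map\n1000000 1.0 1.0\n2000000 1.0 2.0\n")
        pos, cum = read_recombination_map(mp)
        got = interpolate_map(np.array([500_000, 1_500_000, 2_500_000]), pos, cum)
        assert got == pytest.approx([1.0, 1.5, 2.0])  # constant beyond ends

    def test_map_round_trip_through_writer(self, tmp_path, mixed_panel):
        mp = tmp_path / "panel.map"
        write_recombination_map(mixed_panel, mp)
        pos, cum = read_recombination_map(mp)
        got = interpolate_map(mixed_panel.positions, pos, cum)
        assert np.allclose(got, mixed_panel.map_cM, atol=1e-6)

    def test_vcf_dimensions(self, tmp_path):
        vcf = tmp_path / "tiny.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "##contig=<ID=1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS0\tS1\n"
            "1\t100\trs1\tA\tG\t.\tPASS\t.\tGT\t0|1\t1|1\n"
            "1\t200\trs2\tA\tG\t.\tPASS\t.\tGT\t0|0\t0|1\n"
            "1\t300\trs3\tA\tG\t.\tPASS\t.\tGT\t1|0\t0|0\n")
        panel = load_panel(vcf, format="phased-vcf")
        assert panel.alleles.shape == (4, 3)
        assert panel.snp_ids == ["rs1", "rs2", "rs3"]

    def test_unphased_rejected_in_strict_mode(self, tmp_path):
        vcf = tmp_path / "bad.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "##contig=<ID=1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS0\n"
            "1\t100\trs1\tA\tG\t.\tPASS\t.\tGT\t0|1\n"
            "1\t200\trs2\tA\tG\t.\tPASS\t.\tGT\t0/1\n"
            "1\t300\trs3\tA\tG\t.\tPASS\t.\tGT\t1|1\n")
        with pytest.raises(ValueError, match="unphased"):
            load_panel(vcf, format="phased-vcf", strict=True)
        lenient = load_panel(vcf, format="phased-vcf", strict=False)
        assert lenient.n_snps == 1  # rs2 skipped, rs3 monomorphic -> dropped

    def test_monomorphic_sites_dropped_with_warning(self, tmp_path):
        hap, leg = tmp_path / "m.hap", tmp_path / "m.legend"
        leg.write_text("id position allele0 allele1\nrs1 10 A G\nrs2 20 A G\n")
        hap.write_text("0 1 0 1\n1 1 1 1\n")
        with pytest.warns(UserWarning, match="monomorphic"):
            panel = load_panel(hap, legend_file=leg)
        assert panel.snp_ids == ["rs1"]


class TestInvariants:
    def test_panel_validation_catches_bad_inputs(self):
        good = dict(alleles=np.array([[0, 1], [1, 0]], dtype=np.int8),
                    positions=np.array([5, 9]), map_cM=np.array([0.0, 0.2]),
                    snp_ids=["a", "b"])
        sv.HaplotypePanel(**good)
        with pytest.raises(ValueError):
            sv.HaplotypePanel(**{**good, "positions": np.array([9, 5])})
        with pytest.raises(ValueError):
            sv.HaplotypePanel(**{**good, "map_cM": np.array([0.2, 0.0])})
        with pytest.raises(ValueError):
            sv.HaplotypePanel(**{**good, "snp_ids": ["a", "a"]})
        with pytest.raises(ValueError):
            sv.HaplotypePanel(**{**good,
                                 "alleles": np.array([[0, 2], [1, 0]])})
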