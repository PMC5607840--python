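"""Synthetic-data generators: design density, signal model, determinism."""

import math

import numpy as np
import pandas as pd
import pytest

from exoncnv import (
    ArrayDesignParams,
    GeneRecord,
    Pedigree,
    TruthCnv,
    design_array,
    simulate_cohort,
    simulate_wes_variants,
    toy_gene_models,
)
from exoncnv.synthetic import (
    TOY_CHROM_LENGTHS,
    WesSimParams,
    expected_log2,
    make_validation_cohort,
    probes_per_exon,
    wes_boundary_fixture,
)


class TestDesignArray:
    def test_every_exon_of_a_small_gene_gets_min_probes(self):
        gene = GeneRecord(
            symbol="G", chrom="chr1",
            exons=((10_000, 10_199), (20_000, 20_199), (30_000, 30_199)),
        )
        design = design_array([gene], ArrayDesignParams(exon_coverage_fraction=1.0))
        counts = probes_per_exon(design, [gene])
        assert (counts["n_probes"] >= 3).all()

    def test_backbone_only_design(self):
        design = design_array([], ArrayDesignParams(), chrom_lengths={"chr1": 1_000_000})
        assert (design["probe_class"] == "backbone").all()
        assert len(design) == 1_000_000 // 30_000

    def test_density_postconditions_on_toy_design(self, gene_models, design):
        counts = probes_per_exon(design, gene_models)
        frac_covered = (counts["n_probes"] >= 3).mean()
        assert frac_covered >= 0.90
        assert counts["n_probes"].mean() >= 4.2

    def test_mean_probes_per_exon_on_uniform_genes(self):
        genes = [
            GeneRecord(
                symbol=f"G{i}", chrom="chr1",
                exons=tuple(
                    (500_000 * (i + 1) + k * 3_000, 500_000 * (i + 1) + k * 3_000 + 149)
                    for k in range(10)
                ),
            )
            for i in range(10)
        ]
        design = design_array(genes, ArrayDesignParams(seed=7))
        counts = probes_per_exon(design, genes)
        assert counts["n_probes"].mean() >= 4.2

    def test_positions_strictly_increase_within_chromosomes(self, design):
        for _, grp in design.groupby("chrom", sort=False):
            assert (np.diff(grp["pos"].to_numpy()) > 0).all()

    def test_deterministic_for_fixed_seed(self, gene_models):
        a = design_array(gene_models, ArrayDesignParams(seed=5))
        b = design_array(gene_models, ArrayDesignParams(seed=5))
        assert a.to_csv() == b.to_csv()

    def test_backbone_skips_segdups(self):
        segdup = [("chr1", 100_000, 500_000)]
        design = design_array(
            [], ArrayDesignParams(), chrom_lengths={"chr1": 1_000_000}, segdups=segdup
        )
        inside = design[(design["pos"] >= 100_000) & (design["pos"] <= 500_000)]
        assert inside.empty

    def test_unknown_chromosome_is_named_in_error(self):
        gene = GeneRecord(symbol="G", chrom="chr9", exons=((100, 300),))
        with pytest.raises(ValueError, match="chr9"):
            design_array([gene], ArrayDesignParams())

    def test_param_invariants(self):
        with pytest.raises(ValueError):
            ArrayDesignParams(intronic_spacing=0)
        with pytest.raises(ValueError):
            ArrayDesignParams(exon_coverage_fraction=0.0)
        with pytest.raises(ValueError):
            ArrayDesignParams(probes_per_exon_mean=2.0, probes_per_exon_min=3)


class TestSignalModel:
    def test_closed_forms(self):
        assert expected_log2("loss", "heterozygous", 1.0) == pytest.approx(-1.0)
        assert expected_log2("loss", "heterozygous", 0.4) == pytest.approx(
            math.log2(0.8)
        )
        assert expected_log2("gain", "heterozygous", 1.0) == pytest.approx(
            math.log2(1.5)
        )
        # hemizygous male-X loss bottoms out at the configured floor
        assert expected_log2("loss", "hemizygous", 1.0) == -3.0
        assert expected_log2("loss", "hemizygous", 1.0, hemizygous_floor=-5.0) == -5.0

    def test_zero_noise_probes_match_expectation_exactly(self, design, trio):
        truth = [
            TruthCnv("CH", "chr1", 1, 2_000_000, "loss", mosaic_fraction=0.4),
        ]
        profiles, _ = simulate_cohort(design, trio, truth, noise_sd=0.0, seed=0)
        prof = profiles["CH"]
        inside = prof[(prof["chrom"] == "chr1") & (prof["pos"] <= 2_000_000)]
        outside = prof.drop(inside.index)
        assert np.allclose(inside["log2"], math.log2(0.8))
        assert (outside["log2"] == 0.0).all()

    def test_no_truth_means_flat_profiles(self, design, trio):
        profiles, _ = simulate_cohort(design, trio, [], noise_sd=0.0, seed=0)
        for prof in profiles.values():
            assert (prof["log2"] == 0.0).all()

    def test_inherited_event_is_implanted_in_carrier_parent(self, design, trio):
        truth = [TruthCnv("CH", "chr2", 1, 1_000_000, "loss", origin="maternal")]
        profiles, _ = simulate_cohort(design, trio, truth, noise_sd=0.0, seed=0)
        mo = profiles["MO"]
        fa = profiles["FA"]
        hit = (mo["chrom"] == "chr2") & (mo["pos"] <= 1_000_000)
        assert (mo.loc[hit, "log2"] == -1.0).all()
        assert (fa["log2"] == 0.0).all()

    def test_undetectable_event_flagged_not_raised(self, design, trio):
        # between backbone probes: overlaps nothing
        truth = [TruthCnv("CH", "chr1", 30_001, 30_002, "loss")]
        with pytest.warns(UserWarning, match="overlaps no probes"):
            _, table = simulate_cohort(design, trio, truth, noise_sd=0.0, seed=0)
        assert (table["flag"] == "undetectable").all()

    def test_hemizygous_requires_male_x(self, design, trio):
        bad = [TruthCnv("MO", "chrX", 1, 100_000, "loss", allele_dosage="hemizygous")]
        with pytest.raises(ValueError, match="hemizygous"):
            simulate_cohort(design, trio, bad, seed=0)

    def test_truth_sample_must_be_in_pedigree(self, design, trio):
        with pytest.raises(ValueError, match="not in pedigree"):
            simulate_cohort(design, trio, [TruthCnv("ZZ", "chr1", 1, 2, "loss")], seed=0)

    def test_byte_identical_for_fixed_seed(self, design, trio):
        truth = [TruthCnv("CH", "chr1", 1, 500_000, "loss")]
        a, _ = simulate_cohort(design, trio, truth, noise_sd=0.15, seed=42)
        b, _ = simulate_cohort(design, trio, truth, noise_sd=0.15, seed=42)
        assert all(a[s].to_csv() == b[s].to_csv() for s in a)


class TestWesSimulator:
    def test_zero_rates_yield_only_boundary_fixture(self, gene_models):
        params = WesSimParams(lof_rate=0.0, missense_rate=0.0, include_boundary_set=False)
        table = simulate_wes_variants(gene_models, 10, params, seed=0)
        assert table.empty

    def test_empty_gene_list(self):
        assert simulate_wes_variants([], 10, WesSimParams(), seed=0).empty

    def test_boundary_fixture_straddles_every_cutoff(self, gene_models):
        fx = wes_boundary_fixture(gene_models[0])
        assert ((fx["total_reads"] == 20) & (fx["alt_reads"] == 10)).any()
        vaf = fx["alt_reads"] / fx["total_reads"]
        assert (vaf == 0.20).any() and (vaf == 0.19).any()
        for col, vals in (
            ("maf_esp", {9e-4, 1e-3, 1.1e-3}),
            ("maf_exac", {9e-5, 1e-4, 1.1e-4}),
        ):
            assert vals <= set(fx[col])
        assert (fx["functional_class"] == "missense").any()

    def test_log_uniform_maf_spectrum_median_at_1e4(self, gene_models):
        params = WesSimParams(
            lof_rate=0.5, missense_rate=0.0, zero_maf_fraction=0.0,
            include_boundary_set=False,
        )
        table = simulate_wes_variants(gene_models, 40, params, seed=3)
        frac = (table["maf_exac"] > 1e-4).mean()
        n = len(table)
        assert n > 500
        assert abs(frac - 0.5) < 3 * math.sqrt(0.25 / n)

    def test_deterministic(self, gene_models):
        a = simulate_wes_variants(gene_models, 5, WesSimParams(), seed=9)
        b = simulate_wes_variants(gene_models, 5, WesSimParams(), seed=9)
        assert a.equals(b)


class TestValidationCohort:
    def test_truth_events_land_on_probes_with_clean_margins(self):
        cohort = make_validation_cohort(7, n_trios=5, n_cnvs=8)
        assert len(cohort.truth) == 8
        assert (cohort.truth_table["flag"] == "ok").all()
        assert (cohort.truth_table["n_probes"] >= 3).all()

    def test_pedigree_structure(self):
        cohort = make_validation_cohort(7, n_trios=4, n_cnvs=5)
        children = [p for p in cohort.pedigree if p.mother_id]
        assert len(children) == 4
        assert len(cohort.pedigree) == 12

    def test_x_events_in_boys_are_maternal_or_de_novo(self):
        cohort = make_validation_cohort(11, n_trios=20, n_cnvs=40)
        boys = {p.sample_id for p in cohort.pedigree if p.mother_id and p.sex == "male"}
        for t in cohort.truth:
            if t.chrom == "chrX" and t.sample_id in boys:
                assert t.origin in ("de_novo", "maternal")
                assert t.allele_dosage == "hemizygous"


def test_pedigree_rejects_self_parentage():
    with pytest.raises(ValueError):
        Pedigree("A", "male", mother_id="A")


def test_truth_cnv_validation():
    with pytest.raises(ValueError):
        TruthCnv("S", "chr1", 10, 5, "loss")
    with pytest.raises(ValueError):
        TruthCnv("S", "chr1", 1, 5, "loss", mosaic_fraction=0.0)
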