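"""Inheritance determination and the filtering cascade."""

import numpy as np
import pytest

from exoncnv import (
    AnnotatedCnv,
    CnvCall,
    GeneIndex,
    GeneRecord,
    Pedigree,
    determine_inheritance,
    extract_candidate_genes,
    overlap_genes,
    query_overlapping_deletions,
    run_cascade,
)
from exoncnv.pipeline import call_cohort
from exoncnv.synthetic import make_validation_cohort


def _call(sample, chrom, start, end, kind="loss"):
    return CnvCall(sample, chrom, start, end, kind, 3, -1.0 if kind == "loss" else 0.6)


@pytest.fixture
def ped_index(trio):
    return {p.sample_id: p for p in trio}


class TestDetermineInheritance:
    def test_both_parents_tested_negative_is_de_novo(self, ped_index):
        child = _call("CH", "chr1", 100, 200)
        inh = determine_inheritance(child, {"MO": [], "FA": []}, ped_index)
        assert inh.status == "de_novo" and inh.evidence == "both_parents_tested"

    def test_identical_maternal_call(self, ped_index):
        child = _call("CH", "chr1", 100, 200)
        inh = determine_inheritance(
            child, {"MO": [_call("MO", "chr1", 100, 200)], "FA": []}, ped_index
        )
        assert inh.status == "maternal"

    def test_one_parent_tested_negative_is_unknown(self, ped_index):
        child = _call("CH", "chr1", 100, 200)
        inh = determine_inheritance(child, {"FA": []}, ped_index)
        assert inh.status == "unknown" and inh.evidence == "one_parent_tested"

    def test_nobody_tested(self, ped_index):
        inh = determine_inheritance(_call("CH", "chr1", 1, 2), {}, ped_index)
        assert inh.status == "unknown" and inh.evidence == "none_tested"

    def test_both_parents_match(self, ped_index):
        child = _call("CH", "chr1", 100, 200)
        calls = {
            "MO": [_call("MO", "chr1", 100, 200)],
            "FA": [_call("FA", "chr1", 90, 210)],
        }
        assert determine_inheritance(child, calls, ped_index).status == "inherited_unknown_parent"

    def test_type_mismatch_is_not_a_match(self, ped_index):
        child = _call("CH", "chr1", 100, 200, "loss")
        calls = {"MO": [_call("MO", "chr1", 100, 200, "gain")], "FA": []}
        assert determine_inheritance(child, calls, ped_index).status == "de_novo"

    def test_reciprocal_overlap_threshold(self, ped_index):
        child = _call("CH", "chr1", 1, 1000)
        # parent call covers only 30% of the child interval
        calls = {"MO": [_call("MO", "chr1", 1, 300)], "FA": []}
        assert determine_inheritance(child, calls, ped_index).status == "de_novo"
        assert (
            determine_inheritance(child, calls, ped_index, min_reciprocal_overlap=0.2).status
            == "maternal"
        )

    def test_unknown_child_raises(self, ped_index):
        with pytest.raises(ValueError, match="pedigree"):
            determine_inheritance(_call("ZZ", "chr1", 1, 2), {}, ped_index)


def _annotate(calls, genes):
    index = GeneIndex(genes)
    return [overlap_genes(c, index) for c in calls]


class TestCascade:
    def _toy_cohort(self):
        genes = [
            GeneRecord(symbol="A1", chrom="chr1", exons=((10_000, 10_100), (20_000, 20_100))),
            GeneRecord(symbol="A2", chrom="chr2", exons=((10_000, 10_100), (20_000, 20_100))),
            GeneRecord(symbol="XG", chrom="chrX", exons=((10_000, 10_100), (20_000, 20_100))),
        ]
        ped = []
        for i in range(3):
            ped += [
                Pedigree(f"T{i}-MO", "female"),
                Pedigree(f"T{i}-FA", "male"),
                Pedigree(f"T{i}-CH", "male", mother_id=f"T{i}-MO", father_id=f"T{i}-FA"),
            ]
        calls = [
            _call("T0-CH", "chr1", 9_000, 21_000),            # de novo single-gene loss
            _call("T1-CH", "chr2", 9_000, 21_000),            # maternal loss
            _call("T1-MO", "chr2", 9_000, 21_000),
            _call("T2-CH", "chrX", 9_000, 21_000),            # male-X hemizygous loss
        ]
        return genes, ped, calls

    def test_toy_cohort_buckets(self):
        genes, ped, calls = self._toy_cohort()
        counts, routed = run_cascade(_annotate(calls, genes), ped)
        assert counts.bucket_counts["single_de_novo"] == 1
        assert counts.bucket_counts["single_inherited"] == 1
        assert counts.bucket_counts["single_x_male"] == 1
        assert counts.n_cnvs == 3  # parents' own calls are reference only
        assert counts.n_patients == 3

    def test_zero_call_cohort(self, trio):
        counts, routed = run_cascade([], trio)
        assert counts.n_cnvs == 0
        assert all(v == 0 for v in counts.bucket_counts.values())

    def test_conservation_on_random_cohorts(self):
        for seed in (3, 4):
            cohort = make_validation_cohort(seed, n_trios=10, n_cnvs=20)
            calls = [c for cl in call_cohort(cohort.profiles).values() for c in cl]
            annotated = _annotate(calls, cohort.gene_models)
            counts, routed = run_cascade(annotated, cohort.pedigree)
            probands = {p.sample_id for p in cohort.pedigree if p.mother_id}
            n_proband_calls = sum(1 for a in annotated if a.call.sample_id in probands)
            assert sum(counts.bucket_counts.values()) == n_proband_calls == counts.n_cnvs
            assert counts.n_single_gene == sum(
                counts.bucket_counts[b]
                for b in ("single_de_novo", "single_x_male", "single_inherited", "single_other")
            )
            assert counts.n_de_novo_autosomal == (
                counts.n_de_novo_autosomal_losses + counts.n_de_novo_autosomal_gains
            )
            assert counts.n_inherited == counts.n_inherited_losses + counts.n_inherited_gains

    def test_unknown_sex_chrx_call_routed_other_with_warning(self):
        genes = [GeneRecord(symbol="XG", chrom="chrX", exons=((10_000, 10_100),))]
        ped = [
            Pedigree("MO", "female"),
            Pedigree("FA", "male"),
            Pedigree("CH", "female", mother_id="MO", father_id="FA"),
        ]
        ann = _annotate([_call("CH", "chrX", 9_000, 11_000)], genes)
        with pytest.warns(UserWarning, match="sex unknown"):
            counts, routed = run_cascade(ann, ped, sexes={"MO": "female", "FA": "male"})
        assert counts.bucket_counts["single_other"] == 1


class TestCandidateExtraction:
    def test_known_disease_genes_are_not_emitted(self):
        ad = GeneRecord(symbol="KD", chrom="chr1", exons=((10_000, 10_100),), omim_mode={"AD"})
        ped = [
            Pedigree("MO", "female"), Pedigree("FA", "male"),
            Pedigree("CH", "male", mother_id="MO", father_id="FA"),
        ]
        ann = _annotate([_call("CH", "chr1", 9_000, 11_000)], [ad])
        _, routed = run_cascade(ann, ped)
        assert extract_candidate_genes(routed).empty

    def test_mixed_multigene_cnv_emits_only_novel_genes(self):
        genes = [
            GeneRecord(symbol="KD", chrom="chr1", exons=((10_000, 10_100),), omim_mode={"AD"}),
            GeneRecord(symbol="N1", chrom="chr1", exons=((20_000, 20_100),)),
            GeneRecord(symbol="N2", chrom="chr1", exons=((30_000, 30_100),)),
        ]
        ped = [
            Pedigree("MO", "female"), Pedigree("FA", "male"),
            Pedigree("CH", "male", mother_id="MO", father_id="FA"),
        ]
        ann = _annotate([_call("CH", "chr1", 9_000, 31_000)], genes)
        _, routed = run_cascade(ann, ped)
        rows = extract_candidate_genes(routed)
        assert sorted(rows["gene"]) == ["N1", "N2"]
        assert set(rows["tier"]) == {"multi_de_novo"}

    def test_x_male_deletion_of_novel_gene_tagged_x_male(self):
        xg = GeneRecord(symbol="XN", chrom="chrX", exons=((10_000, 10_100),))
        ped = [
            Pedigree("MO", "female"), Pedigree("FA", "male"),
            Pedigree("CH", "male", mother_id="MO", father_id="FA"),
        ]
        ann = _annotate([_call("CH", "chrX", 9_000, 11_000)], [xg])
        _, routed = run_cascade(ann, ped)
        rows = extract_candidate_genes(routed)
        assert list(rows["gene"]) == ["XN"] and list(rows["tier"]) == ["single_x_male"]


class TestDatabaseQuery:
    GENE = GeneRecord(symbol="G", chrom="chr1", exons=((1_000_000, 1_000_100), (1_500_000, 1_500_100)))

    def test_size_ceiling_excludes_large_deletions(self):
        db = [_call("P1", "chr1", 500_000, 6_600_000)]  # 6.1 Mb
        assert query_overlapping_deletions(self.GENE, db) == []

    def test_overlapping_small_deletions_returned(self):
        db = [
            _call("P1", "chr1", 990_000, 1_090_000),
            _call("P2", "chr1", 1_400_000, 1_510_000),
            _call("P3", "chr1", 5_000_000, 5_100_000),
            _call("P4", "chr1", 1_000_000, 1_200_000, "gain"),
        ]
        hits = query_overlapping_deletions(self.GENE, db)
        assert [c.sample_id for c in hits] == ["P1", "P2"]

    @pytest.mark.parametrize("seed", range(3))
    def test_random_database_matches_all_pairs_scan(self, seed):
        rng = np.random.default_rng(seed)
        db = []
        for i in range(300):
            start = int(rng.integers(1, 8_000_000))
            end = start + int(rng.integers(100, 6_000_000))
            kind = "loss" if rng.random() < 0.7 else "gain"
            db.append(_call(f"P{i}", "chr1", start, end, kind))
        gs, ge = self.GENE.span
        expected = sorted(
            (
                c.id
                for c in db
                if c.type == "loss" and c.size_bp <= 5_000_000
                and c.start <= ge and gs <= c.end
            ),
        )
        got = sorted(c.id for c in query_overlapping_deletions(self.GENE, db))
        assert got == expected
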