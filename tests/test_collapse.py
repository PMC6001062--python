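"""Consequence classification, MAF computation, and collapsing."""

import numpy as np
import pytest

from sorva.collapse import (
    Consequence,
    GenotypeMatrix,
    Individual,
    VariantRecord,
    classify_consequence,
    collapse_by_domain,
    collapse_by_gene,
    compute_cohort_maf,
    consequence_in_class,
    filter_variants,
    DomainInterval,
    read_gene_models,
)
from sorva.freqtable import ConsequenceClass, CountingMode, Zygosity


def variant(chrom="1", pos=100, csq=Consequence.MISSENSE_OR_INFRAME, genes=("G",)):
    return VariantRecord(chrom, pos, "A", "G", csq, frozenset(genes), frozenset())


def matrix_from(calls, variants=None, sexes=None):
    calls = np.asarray(calls, dtype=np.int8)
    n_var, n_ind = calls.shape
    if variants is None:
        variants = [variant(pos=100 + 10 * i) for i in range(n_var)]
    inds = [
        Individual(f"S{i}", sex=(sexes[i] if sexes else "F"))
        for i in range(n_ind)
    ]
    return GenotypeMatrix(inds, variants, calls)


class TestClassifyConsequence:
    @pytest.mark.parametrize(
        "term,expected,in_lof,in_pa",
        [
            ("stop_gained", Consequence.STOP_GAIN, True, True),
            ("frameshift_variant", Consequence.FRAMESHIFT, True, True),
            ("splice_donor_variant", Consequence.SPLICE_SITE, True, True),
            ("missense_variant", Consequence.MISSENSE_OR_INFRAME, False, True),
            ("synonymous", Consequence.OTHER, False, False),
        ],
    )
    def test_vocabulary_and_class_membership(self, term, expected, in_lof, in_pa):
        csq = classify_consequence(term)
        assert csq is expected
        assert consequence_in_class(csq, ConsequenceClass.LOF_ONLY) is in_lof
        assert consequence_in_class(csq, ConsequenceClass.PROTEIN_ALTERING) is in_pa

    def test_unknown_term_strict_raises(self):
        with pytest.raises(ValueError, match="unknown consequence"):
            classify_consequence("made_up_term")

    def test_unknown_term_lenient_warns(self):
        with pytest.warns(UserWarning):
            assert classify_consequence("made_up_term", strict=False) is Consequence.OTHER


class TestCohortMaf:
    def test_het_carriers_direct_count(self):
        calls = np.zeros((1, 2504), dtype=np.int8)
        calls[0, :5] = 1
        m = matrix_from(calls)
        assert compute_cohort_maf(m, 0) == pytest.approx(5 / 5008)

    def test_male_x_contributes_one_allele(self):
        """1 hemizygous male carrier among 2 males + 2 females: MAF = 1/6."""
        v = [variant(chrom="X")]
        calls = np.array([[2, 0, 0, 0]])  # hemizygous alt recoded as dosage 2
        m = matrix_from(calls, variants=v, sexes=["M", "M", "F", "F"])
        assert compute_cohort_maf(m, 0) == pytest.approx(1 / 6)

    def test_folding_to_minor_allele(self):
        calls = np.full((1, 10), 2, dtype=np.int8)
        calls[0, :2] = 1  # alt frequency 0.9
        m = matrix_from(calls)
        assert compute_cohort_maf(m, 0) == pytest.approx(0.1)

    def test_all_missing_rejected(self):
        m = matrix_from(np.full((1, 4), -1, dtype=np.int8))
        with pytest.raises(ValueError, match="missing"):
            compute_cohort_maf(m, 0)

    def test_missing_excluded_from_denominator(self):
        calls = np.array([[1, -1, 0, 0]])
        m = matrix_from(calls)
        assert compute_cohort_maf(m, 0) == pytest.approx(1 / 6)

    def test_het_male_x_call_rejected(self):
        v = [variant(chrom="X")]
        with pytest.raises(ValueError, match="heterozygous male X"):
            matrix_from(np.array([[1, 0]]), variants=v, sexes=["M", "F"])


class TestFilterVariants:
    def _matrix(self):
        variants = [
            variant(pos=100, csq=Consequence.MISSENSE_OR_INFRAME),
            variant(pos=110, csq=Consequence.STOP_GAIN),
            variant(pos=120, csq=Consequence.OTHER),
        ]
        calls = np.zeros((3, 100), dtype=np.int8)
        calls[0, :10] = 1  # maf 0.05 exactly
        calls[1, :2] = 1  # maf 0.01
        calls[2, :1] = 1
        return matrix_from(calls, variants=variants)

    def test_threshold_is_strict(self):
        m = self._matrix()
        kept = filter_variants(m, 0.05, ConsequenceClass.PROTEIN_ALTERING)
        assert 0 not in kept  # MAF exactly at threshold is excluded
        assert 1 in kept

    def test_class_mismatch_excluded(self):
        m = self._matrix()
        kept = filter_variants(m, 0.05, ConsequenceClass.LOF_ONLY)
        assert kept == [1]

    def test_other_class_never_qualifies(self):
        m = self._matrix()
        kept = filter_variants(m, 0.5, ConsequenceClass.PROTEIN_ALTERING)
        assert 2 not in kept


class TestCollapseByGene:
    def _two_site_matrix(self, calls):
        variants = [variant(pos=100), variant(pos=110)]
        return matrix_from(calls, variants=variants)

    def test_het_at_two_variants_counts_once_binary(self):
        m = self._two_site_matrix([[1, 0], [1, 0]])
        t = collapse_by_gene(m, [0, 1], Zygosity.HET)
        assert t.count("G") == 1

    def test_same_individual_counts_twice_in_multiplicity(self):
        m = self._two_site_matrix([[1, 0], [1, 0]])
        t = collapse_by_gene(m, [0, 1], Zygosity.HET, CountingMode.VARIANT_MULTIPLICITY)
        assert t.count("G") == 2

    def test_single_het_does_not_qualify_as_hom(self):
        m = self._two_site_matrix([[1, 0], [0, 0]])
        t = collapse_by_gene(m, [0, 1], Zygosity.HOM)
        assert t.count("G") == 0

    def test_two_hets_qualify_as_compound_het(self):
        m = self._two_site_matrix([[1, 0], [1, 0]])
        t = collapse_by_gene(m, [0, 1], Zygosity.CHET_OR_HOM)
        assert t.count("G") == 1

    def test_single_het_does_not_qualify_as_compound_het(self):
        m = self._two_site_matrix([[1, 0], [0, 0]])
        t = collapse_by_gene(m, [0, 1], Zygosity.CHET_OR_HOM)
        assert t.count("G") == 0

    def test_hom_qualifies_as_compound_het(self):
        m = self._two_site_matrix([[2, 0], [0, 0]])
        t = collapse_by_gene(m, [0, 1], Zygosity.CHET_OR_HOM)
        assert t.count("G") == 1

    def test_chet_with_multiplicity_rejected(self):
        m = self._two_site_matrix([[1, 0], [1, 0]])
        with pytest.raises(ValueError, match="CHET_OR_HOM"):
            collapse_by_gene(m, [0, 1], Zygosity.CHET_OR_HOM, CountingMode.VARIANT_MULTIPLICITY)

    def test_permutation_invariance_in_individual_order(self):
        rng = np.random.default_rng(3)
        calls = rng.choice([0, 1, 2], size=(4, 30), p=[0.8, 0.15, 0.05]).astype(np.int8)
        variants = [variant(pos=100 + 10 * i) for i in range(4)]
        m = matrix_from(calls, variants=variants)
        perm = rng.permutation(30)
        m2 = matrix_from(calls[:, perm], variants=[
            variant(pos=100 + 10 * i) for i in range(4)
        ])
        for zyg in Zygosity:
            assert collapse_by_gene(m, range(4), zyg).count("G") == collapse_by_gene(
                m2, range(4), zyg
            ).count("G")


class TestCollapseByDomain:
    def _setup(self):
        variants = [
            variant(pos=100),  # inside DOM1
            variant(pos=200),  # inside DOM2
            variant(pos=300),  # in gene, outside both domains
        ]
        calls = np.array([[1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=np.int8)
        m = matrix_from(calls, variants=variants)
        domains = [
            DomainInterval("G:DOM1:1", "DOM1", "G", "G.t1", [("1", 90, 120)]),
            DomainInterval("G:DOM2:1", "DOM2", "G", "G.t1", [("1", 190, 210)]),
        ]
        return m, domains

    def test_variant_inside_domain_counted(self):
        m, domains = self._setup()
        t = collapse_by_domain(m, [0, 1, 2], domains, Zygosity.BOTH)
        assert t.count("G:DOM1:1") == 1
        assert t.count("G:DOM2:1") == 1

    def test_gene_count_bounds_every_domain_count(self):
        m, domains = self._setup()
        gene_t = collapse_by_gene(m, [0, 1, 2], Zygosity.BOTH)
        dom_t = collapse_by_domain(m, [0, 1, 2], domains, Zygosity.BOTH)
        assert gene_t.count("G") == 3
        for d in domains:
            assert dom_t.count(d.instance_id) <= gene_t.count("G")

    def test_empty_domain_skipped_with_warning(self):
        m, _ = self._setup()
        empty = DomainInterval("G:EMPTY:1", "EMPTY", "G", "G.t1", [])
        with pytest.warns(UserWarning, match="no mapped intervals"):
            t = collapse_by_domain(m, [0], [empty], Zygosity.BOTH)
        assert "G:EMPTY:1" not in t


class TestMonotonicity:
    """Counts never decrease when filters widen, on a simulated cohort."""

    def test_monotone_in_maf_class_and_zygosity(self, small_matrix):
        from sorva.collapse import build_all_tables
        from sorva.freqtable import FilterKey, Population

        tables = build_all_tables(small_matrix, populations=[Population.ALL])
        genes = {g for v in small_matrix.variants for g in v.gene_ids}
        mafs = sorted({k.maf_threshold for k in tables})
        for gene in genes:
            for key, table in tables.items():
                # LOF subset of protein-altering
                if key.consequence_class.value == "LOF_ONLY":
                    wider = tables[
                        FilterKey(key.population, key.maf_threshold, ConsequenceClass.PROTEIN_ALTERING, key.zygosity, key.mode)
                    ]
                    assert table.count(gene) <= wider.count(gene)
                # HOM <= BOTH <= cohort size
                if key.zygosity is Zygosity.HOM:
                    both = tables[
                        FilterKey(key.population, key.maf_threshold, key.consequence_class, Zygosity.BOTH, key.mode)
                    ]
                    assert table.count(gene) <= both.count(gene) <= table.cohort_size
            # non-decreasing in MAF threshold
            for lo, hi in zip(mafs, mafs[1:]):
                for key in tables:
                    if key.maf_threshold != lo:
                        continue
                    hi_key = FilterKey(key.population, hi, key.consequence_class, key.zygosity, key.mode)
                    assert tables[key].count(gene) <= tables[hi_key].count(gene)


class TestGeneModels:
    def test_transcript_length_and_overlap_check(self, tmp_path):
        path = tmp_path / "genes.tsv"
        path.write_text(
            "#chrom\tstart\tend\tgene\ttranscript\tstrand\n"
            "1\t100\t200\tG\tG.t1\t+\n"
            "1\t300\t400\tG\tG.t1\t+\n"
        )
        models = read_gene_models(path)
        assert models["G"].transcript_length("G.t1") == 200

    def test_overlapping_exons_rejected(self, tmp_path):
        path = tmp_path / "genes.tsv"
        path.write_text("1\t100\t200\tG\tG.t1\t+\n1\t150\t250\tG\tG.t1\t+\n")
        with pytest.raises(ValueError, match="overlapping"):
            read_gene_models(path)
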