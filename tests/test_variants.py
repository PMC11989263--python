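"""Variant filtering (inclusive thresholds, rejection attribution) and
consequence classification against rebuild/translation oracles."""

from __future__ import annotations

import numpy as np
import pytest

from soyhap import synthetic
from soyhap.errors import UnsupportedVariantError, ValidationError
from soyhap.models import VariantRecord
from soyhap.variants import (
    FilterThresholds,
    classify_consequence,
    filter_variants,
    mutate_cds,
)

from conftest import (
    random_exonic_indel,
    random_exonic_snv,
    rebuild_cds,
    translate_full,
)


def _rec(qual=100.0, dp=50.0, qd=20.0, mq=55.0, genotypes=None, alts=None,
         position=10):
    genotypes = genotypes or ["ref"] * 8 + ["alt"] * 2
    return VariantRecord(
        chromosome="chr1", position=position, ref_allele="A",
        alt_alleles=alts or ["G"], qual=qual, depth=dp,
        quality_by_depth=qd, mapping_quality=mq,
        samples=[f"S{i}" for i in range(len(genotypes))],
        genotypes=genotypes,
    )


class TestFilter:
    def test_exact_boundary_record_retained(self):
        """All comparisons are inclusive: a record sitting exactly on
        every threshold passes."""
        genotypes = ["missing"] + ["ref"] * 49  # missing rate exactly 0.1
        genotypes[1] = "alt"  # MAF = 1/49... need exactly 0.01: use het
        # 49 called, one het = 0.5 alt alleles -> MAF 0.5/49 ~ 0.0102 >= 0.01
        genotypes[1] = "het"
        rec = _rec(qual=50.0, dp=5.0, qd=5.0, mq=30.0,
                   genotypes=["missing"] * 5 + genotypes[1:2] * 1
                   + ["ref"] * 44)
        assert rec.missing_rate == pytest.approx(0.1)
        retained, rejections = filter_variants([rec])
        assert retained == [rec]
        assert sum(rejections.values()) == 0

    def test_qual_just_below_rejected_and_attributed(self):
        rec = _rec(qual=49.9)
        retained, rejections = filter_variants([rec])
        assert retained == []
        assert rejections["qual"] == 1

    def test_absent_field_fails_its_criterion(self, caplog):
        rec = _rec(mq=None)
        with caplog.at_level("WARNING"):
            retained, rejections = filter_variants([rec])
        assert retained == []
        assert rejections["mq"] == 1
        assert "MQ" in caplog.text

    def test_ten_record_hand_filter(self):
        """Constructed panel: 4 planted failures, 6 retained; the tally
        attributes each rejection to its first failing criterion and
        sums to the input count."""
        base_gt = ["ref"] * 60 + ["alt"] * 40
        records = [
            _rec(genotypes=base_gt, position=1),                  # pass
            _rec(qual=49.9, genotypes=base_gt, position=2),       # fail qual
            _rec(dp=4.0, genotypes=base_gt, position=3),          # fail dp
            _rec(genotypes=base_gt, alts=["G", "T"], position=4),  # multiallelic
            _rec(genotypes=["ref"] * 99 + ["het"], position=5),   # MAF 0.005
            _rec(genotypes=base_gt, position=6),                  # pass
            _rec(qd=5.0, genotypes=base_gt, position=7),          # boundary pass
            _rec(mq=30.0, genotypes=base_gt, position=8),         # boundary pass
            _rec(genotypes=base_gt, position=9),                  # pass
            _rec(qual=50.0, genotypes=base_gt, position=10),      # boundary pass
        ]
        retained, rejections = filter_variants(records)
        assert [r.position for r in retained] == [1, 6, 7, 8, 9, 10]
        assert rejections == {"max_missing": 0, "qual": 1, "dp": 1,
                              "qd": 0, "mq": 0, "biallelic": 1, "maf": 1}
        assert len(retained) + sum(rejections.values()) == 10

    def test_retained_set_order_independent(self):
        """The retained set (not the tally) is the same regardless of
        which criterion order is used for attribution."""
        rng = np.random.default_rng(11)
        records = []
        for i in range(50):
            records.append(_rec(
                qual=float(rng.uniform(30, 70)),
                dp=float(rng.uniform(2, 10)),
                qd=float(rng.uniform(2, 10)),
                mq=float(rng.uniform(20, 40)),
                position=i + 1,
                genotypes=[str(rng.choice(["ref", "alt", "missing"],
                                          p=[0.6, 0.3, 0.1]))
                           for _ in range(40)]))
        retained, _ = filter_variants(records)
        th = FilterThresholds()
        oracle = [r for r in records
                  if r.missing_rate <= th.max_missing
                  and r.qual >= th.min_qual and r.depth >= th.min_depth
                  and r.quality_by_depth >= th.min_quality_by_depth
                  and r.mapping_quality >= th.min_mapping_quality
                  and r.is_biallelic and r.maf >= th.min_maf]
        assert retained == oracle

    def test_het_counts_half_toward_maf(self):
        rec = _rec(genotypes=["het"] + ["ref"] * 99)
        assert rec.maf == pytest.approx(0.005)


class TestMutateCds:
    def test_direct_substitution(self, plus_gene):
        gene, _ = plus_gene
        gene.cds_sequence = "ATGCAATAG"  # keep exon layout, swap CDS
        variant = VariantRecord(chromosome="chrT",
                                position=gene.cds_to_genomic(4),
                                ref_allele="C", alt_alleles=["T"])
        mutated, cds_pos = mutate_cds(gene, variant)
        assert mutated == "ATGTAATAG"
        assert cds_pos == 4

    def test_intronic_snv_noncoding(self, plus_gene):
        gene, _ = plus_gene
        variant = VariantRecord(chromosome="chrT", position=8,  # intron
                                ref_allele="C", alt_alleles=["T"])
        assert mutate_cds(gene, variant) is None

    def test_reference_mismatch_detected(self, plus_gene):
        gene, _ = plus_gene
        variant = VariantRecord(chromosome="chrT", position=3,
                                ref_allele="C", alt_alleles=["T"])  # truly A
        with pytest.raises(ValidationError):
            mutate_cds(gene, variant)

    def test_deletion_spanning_exon_boundary_unsupported(self, plus_gene):
        gene, chrom = plus_gene
        # exon1 ends at 6; delete bases 6..12 (exon+intron+exon)
        variant = VariantRecord(chromosome="chrT", position=5,
                                ref_allele=chrom[4:12], alt_alleles=[chrom[4]])
        with pytest.raises(UnsupportedVariantError):
            mutate_cds(gene, variant)

    @pytest.mark.parametrize("kind", ["snv", "indel"])
    def test_rebuild_oracle_random_variants(self, kind):
        """Random exonic edits on random genes (both strands): the
        coordinate-mapped edit equals an oracle that rebuilds the CDS
        from the edited chromosome."""
        genes, chroms = synthetic.gen_genes(
            synthetic.SyntheticConfig(seed=31, n_genes=10))
        rng = np.random.default_rng(77)
        assert {g.strand for g in genes} == {"+", "-"}
        for gene in genes:
            chrom = chroms[gene.chromosome]
            for _ in range(20):
                if kind == "snv":
                    variant = random_exonic_snv(gene, chrom, rng)
                else:
                    variant = random_exonic_indel(gene, chrom, rng)
                result = mutate_cds(gene, variant)
                assert result is not None
                assert result[0] == rebuild_cds(chrom, gene, variant)


class TestClassify:
    def test_stop_gain_pattern(self, plus_gene):
        """Mid-CDS C>T turning CAA into TAA is stop_gained."""
        gene, _ = plus_gene
        gene.cds_sequence = "ATGCAATAG"
        variant = VariantRecord(chromosome="chrT",
                                position=gene.cds_to_genomic(4),
                                ref_allele="C", alt_alleles=["T"])
        cons = classify_consequence(gene, variant)
        assert cons.consequence_class == "stop_gained"
        assert (cons.ref_codon, cons.alt_codon) == ("CAA", "TAA")
        assert (cons.ref_aa, cons.alt_aa) == ("Q", "*")

    def test_single_base_deletion_is_frameshift(self, minus_gene):
        gene, chrom = minus_gene
        pos = gene.exons[0][0]  # delete the second exon base
        variant = VariantRecord(chromosome="chrT", position=pos,
                                ref_allele=chrom[pos - 1:pos + 1],
                                alt_alleles=[chrom[pos - 1]])
        cons = classify_consequence(gene, variant)
        assert cons.consequence_class == "frameshift"

    def test_synonymous_third_position(self, plus_gene):
        gene, _ = plus_gene
        gene.cds_sequence = "ATGGGATAG"  # GGA glycine at codon 2
        variant = VariantRecord(chromosome="chrT",
                                position=gene.cds_to_genomic(6),
                                ref_allele="A", alt_alleles=["G"])
        cons = classify_consequence(gene, variant)
        assert cons.consequence_class == "synonymous"
        assert (cons.ref_codon, cons.alt_codon) == ("GGA", "GGG")

    def test_gene_offset_reported(self, plus_gene):
        gene, _ = plus_gene
        variant = VariantRecord(chromosome="chrT", position=12,
                                ref_allele="A", alt_alleles=["G"])
        cons = classify_consequence(gene, variant)
        assert cons.gene_offset == 12 - gene.span_start + 1

    def test_full_translation_oracle_random_variants(self):
        """Codon-level classification agrees with an oracle that fully
        translates the reference and mutated CDS and compares proteins;
        indels are never synonymous; stop-gains truncate the protein."""
        genes, chroms = synthetic.gen_genes(
            synthetic.SyntheticConfig(seed=13, n_genes=10))
        rng = np.random.default_rng(99)
        checked = 0
        while checked < 500:
            gene = genes[int(rng.integers(0, len(genes)))]
            chrom = chroms[gene.chromosome]
            if rng.random() < 0.6:
                variant = random_exonic_snv(gene, chrom, rng)
            else:
                variant = random_exonic_indel(gene, chrom, rng)
            cons = classify_consequence(gene, variant)
            mutated, _ = mutate_cds(gene, variant)
            assert cons.consequence_class == _oracle_class(
                gene.cds_sequence, mutated)
            if cons.consequence_class == "stop_gained":
                ref_protein = translate_full(gene.cds_sequence).split("*")[0]
                mut_protein = translate_full(mutated).split("*")[0]
                assert len(mut_protein) < len(ref_protein)
            if len(variant.ref_allele) != len(variant.alt_allele):
                assert cons.consequence_class in {"frameshift",
                                                  "inframe_indel"}
            checked += 1


def _oracle_class(ref_cds: str, mut_cds: str) -> str:
    """Independent classifier from whole-protein comparison."""
    if len(ref_cds) != len(mut_cds):
        return ("frameshift" if abs(len(ref_cds) - len(mut_cds)) % 3
                else "inframe_indel")
    ref_protein = translate_full(ref_cds)
    mut_protein = translate_full(mut_cds)
    if ref_protein == mut_protein:
        return "synonymous"
    diffs = [(i, a, b) for i, (a, b) in
             enumerate(zip(ref_protein, mut_protein)) if a != b]
    (i, a, b), = diffs
    if b == "*" and i < len(ref_protein) - 1:
        return "stop_gained"
    if a == "*":
        return "stop_lost"
    return "missense"
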