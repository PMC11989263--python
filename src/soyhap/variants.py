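"""Variant quality filtering and coding-consequence classification.

Filtering applies the resequencing-style site filters (missingness,
QUAL, DP, QD, MQ, biallelic, MAF) with inclusive thresholds.
Consequence calling maps each exonic variant through the gene's exon
structure onto the CDS (strand-aware), edits the CDS, and classifies
the edit by comparing the affected codon (SNVs) or the length change
(indels) under the standard nuclear genetic code.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from collections.abc import Sequence

from Bio.Data import CodonTable

from .errors import UnsupportedVariantError, ValidationError
from .models import Consequence, GeneModel, VariantRecord, revcomp

logger = logging.getLogger(__name__)

_TABLE = CodonTable.unambiguous_dna_by_id[1]  # standard nuclear code
CODON_TO_AA = dict(_TABLE.forward_table)
CODON_TO_AA.update({codon: "*" for codon in _TABLE.stop_codons})
STOP_CODONS = frozenset(_TABLE.stop_codons)


def translate_codon(codon: str) -> str:
    try:
        return CODON_TO_AA[codon.upper()]
    except KeyError as exc:
        raise ValidationError(f"cannot translate codon {codon!r}") from exc


# ---------------------------------------------------------------------------
# Quality filtering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FilterThresholds:
    """Inclusive site-filter thresholds.

    Defaults follow the resequencing QC used for this kind of panel:
    max-missing <= 0.1 (equivalently >=90% of samples genotyped, so the
    sample-coverage criterion is folded into missingness), QUAL >= 50,
    DP >= 5, QD >= 5, MQ >= 30, biallelic only, MAF >= 0.01.
    """

    max_missing: float = 0.1
    min_qual: float = 50.0
    min_depth: float = 5.0
    min_quality_by_depth: float = 5.0
    min_mapping_quality: float = 30.0
    biallelic_only: bool = True
    min_maf: float = 0.01


#: Criterion evaluation order used for rejection attribution (a rejected
#: record is attributed to its first failing criterion in this order).
CRITERION_ORDER = ("max_missing", "qual", "dp", "qd", "mq", "biallelic", "maf")


def _failing_criterion(rec: VariantRecord, th: FilterThresholds) -> str | None:
    """First failing criterion name, or None if the record passes all."""
    if rec.missing_rate > th.max_missing:
        return "max_missing"
    for name, value, minimum in (
        ("qual", rec.qual, th.min_qual),
        ("dp", rec.depth, th.min_depth),
        ("qd", rec.quality_by_depth, th.min_quality_by_depth),
        ("mq", rec.mapping_quality, th.min_mapping_quality),
    ):
        if value is None:
            logger.warning("%s:%d: %s absent; record fails that criterion",
                           rec.chromosome, rec.position, name.upper())
            return name
        if value < minimum:
            return name
    if th.biallelic_only and not rec.is_biallelic:
        return "biallelic"
    if rec.maf < th.min_maf:
        return "maf"
    return None


def filter_variants(records: Sequence[VariantRecord],
                    thresholds: FilterThresholds | None = None,
                    ) -> tuple[list[VariantRecord], dict[str, int]]:
    """Retain records passing every criterion; tally rejections by the
    first failing criterion. Retained + rejected counts sum to the input
    count."""
    th = thresholds or FilterThresholds()
    retained: list[VariantRecord] = []
    rejections = {name: 0 for name in CRITERION_ORDER}
    for rec in records:
        failing = _failing_criterion(rec, th)
        if failing is None:
            retained.append(rec)
        else:
            rejections[failing] += 1
    return retained, rejections


# ---------------------------------------------------------------------------
# CDS editing
# ---------------------------------------------------------------------------

def _normalize_alleles(variant: VariantRecord) -> tuple[str, str, str]:
    """Classify a biallelic variant as ('snv'|'ins'|'del', ref, alt)."""
    if not variant.is_biallelic:
        raise UnsupportedVariantError(
            f"{variant.chromosome}:{variant.position}: multi-allelic record; "
            "apply the biallelic filter first"
        )
    ref, alt = variant.ref_allele.upper(), variant.alt_allele.upper()
    if len(ref) == 1 and len(alt) == 1:
        return "snv", ref, alt
    if len(alt) > len(ref) and alt.startswith(ref):
        return "ins", ref, alt
    if len(ref) > len(alt) and ref.startswith(alt):
        return "del", ref, alt
    raise UnsupportedVariantError(
        f"{variant.chromosome}:{variant.position}: complex allele pair "
        f"{ref}>{alt} not supported"
    )


def mutate_cds(gene: GeneModel, variant: VariantRecord,
               ) -> tuple[str, int] | None:
    """Apply a variant to the gene's CDS.

    Returns (mutated_cds, cds_position_of_first_affected_base) with the
    CDS position 1-based on the coding strand, or None when the variant
    touches no exon (noncoding). Alleles are reverse-complemented for
    minus-strand genes. A deletion that removes both exonic and
    non-exonic bases cannot be resolved and raises
    UnsupportedVariantError.
    """
    if variant.chromosome != gene.chromosome:
        raise ValueError(
            f"variant on {variant.chromosome} does not match gene "
            f"{gene.gene_id} on {gene.chromosome}"
        )
    kind, ref, alt = _normalize_alleles(variant)
    cds = gene.cds_sequence
    minus = gene.strand == "-"

    if kind == "snv":
        cds_pos = gene.genomic_to_cds(variant.position)
        if cds_pos is None:
            return None
        expected = revcomp(ref) if minus else ref
        if cds[cds_pos - 1] != expected:
            raise ValidationError(
                f"{gene.gene_id} CDS position {cds_pos}: reference allele "
                f"{ref!r} does not match CDS base {cds[cds_pos - 1]!r}"
            )
        new_base = revcomp(alt) if minus else alt
        return cds[:cds_pos - 1] + new_base + cds[cds_pos:], cds_pos

    if kind == "del":
        first = variant.position + len(alt)
        last = variant.position + len(ref) - 1
        exonic = [gene.contains_exonic(p) for p in range(first, last + 1)]
        if not any(exonic):
            return None
        if not all(exonic):
            raise UnsupportedVariantError(
                f"{gene.gene_id}: deletion {variant.position} {ref}>{alt} "
                "spans an exon boundary"
            )
        cds_positions = [gene.genomic_to_cds(p) for p in range(first, last + 1)]
        lo, hi = min(cds_positions), max(cds_positions)
        if hi - lo != last - first:
            raise UnsupportedVariantError(
                f"{gene.gene_id}: deletion {variant.position} {ref}>{alt} "
                "spans an exon boundary"
            )
        return cds[:lo - 1] + cds[hi:], lo

    # insertion between anchor and anchor+1 on the genomic scale
    anchor = variant.position + len(ref) - 1
    ins = alt[len(ref):]
    same_exon = any(s <= anchor and anchor + 1 <= e for s, e in gene.exons)
    if not same_exon:
        return None
    c0 = gene.genomic_to_cds(anchor) - 1  # 0-based
    if minus:
        return cds[:c0] + revcomp(ins) + cds[c0:], c0 + 1
    return cds[:c0 + 1] + ins + cds[c0 + 1:], c0 + 2


# ---------------------------------------------------------------------------
# Consequence classification
# ---------------------------------------------------------------------------

def classify_consequence(gene: GeneModel, variant: VariantRecord) -> Consequence:
    """Classify one biallelic variant's coding consequence on a gene.

    SNVs compare the affected codon before and after the edit:
    stop-gained when the new codon is a stop before the terminal codon,
    stop-lost when a stop codon is destroyed, synonymous/missense by the
    amino-acid comparison. Exonic indels are frameshift when the length
    change is not a multiple of 3, in-frame otherwise. Variants touching
    no exon are noncoding.
    """
    base = dict(
        gene_id=gene.gene_id,
        chromosome=variant.chromosome,
        position=variant.position,
        ref_allele=variant.ref_allele,
        alt_allele=variant.alt_allele,
        gene_offset=variant.position - gene.span_start + 1,
    )
    edit = mutate_cds(gene, variant)
    if edit is None:
        return Consequence(consequence_class="noncoding", **base)
    mutated, cds_pos = edit

    if variant.is_snv:
        codon_idx = (cds_pos - 1) // 3
        ref_codon = gene.cds_sequence[codon_idx * 3:codon_idx * 3 + 3]
        alt_codon = mutated[codon_idx * 3:codon_idx * 3 + 3]
        ref_aa, alt_aa = translate_codon(ref_codon), translate_codon(alt_codon)
        last_codon = len(gene.cds_sequence) // 3 - 1
        if alt_aa == "*" and ref_aa != "*" and codon_idx < last_codon:
            cls = "stop_gained"
        elif ref_aa == "*" and alt_aa != "*":
            cls = "stop_lost"
        elif ref_aa == alt_aa:
            cls = "synonymous"
        else:
            cls = "missense"
        return Consequence(
            consequence_class=cls, cds_position=cds_pos,
            ref_codon=ref_codon, alt_codon=alt_codon,
            ref_aa=ref_aa, alt_aa=alt_aa, **base,
        )

    cls = "frameshift" if abs(variant.indel_length) % 3 != 0 else "inframe_indel"
    return Consequence(consequence_class=cls, cds_position=cds_pos, **base)


def annotate_all(genes: Sequence[GeneModel],
                 variants: Sequence[VariantRecord],
                 ) -> list[Consequence]:
    """Classify every variant against the gene on its chromosome whose
    span covers it (candidate-gene panels: at most one gene applies)."""
    out = []
    for variant in variants:
        for gene in genes:
            if (gene.chromosome == variant.chromosome
                    and gene.span_start <= variant.position <= gene.span_end):
                out.append(classify_consequence(gene, variant))
                break
    return out


def touches_exon(gene: GeneModel, variant: VariantRecord) -> bool:
    """True when the variant's coding consequence is not noncoding."""
    return mutate_cds(gene, variant) is not None
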