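"""Exon-haplotype construction and frequency comparisons.

Cultivars are partitioned per gene by their allele string over the
gene's retained exonic variant sites. The panel is fully inbred, so a
heterozygous call is treated as missing for assignment; by default a
cultivar with any missing site at a gene is left unassigned (tolerance
configurable). Labels H1, H2, ... are ordered by descending membership
count with ties broken lexicographically by allele string, and the
all-reference string (the Williams 82-like haplotype) is additionally
tagged as the reference label. Labelling is deterministic but
data-derived, so it need not match any externally published numbering.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from collections.abc import Mapping, Sequence

from scipy import stats

from .errors import AnalysisError
from .models import FrequencyComparison, GeneModel, HaplotypeTable, VariantRecord
from .variants import touches_exon

logger = logging.getLogger(__name__)

_ALLELE_CHAR = {"ref": "R", "alt": "A", "het": ".", "missing": "."}


def site_id(variant: VariantRecord) -> str:
    return f"{variant.chromosome}:{variant.position}:{variant.ref_allele}>" \
           f"{','.join(variant.alt_alleles)}"


def build_haplotypes(gene: GeneModel,
                     variants: Sequence[VariantRecord],
                     max_missing_sites: int = 0) -> HaplotypeTable:
    """Partition cultivars by their exonic allele strings at one gene.

    ``variants`` is the retained (filtered) variant list; only sites
    touching this gene's exons are used. Cultivars whose string has more
    than ``max_missing_sites`` unresolved sites (missing or heterozygous
    calls) are unassigned; partially missing cultivars within the
    tolerance are assigned to the unique compatible haplotype when one
    exists.
    """
    exonic = sorted(
        (v for v in variants
         if v.chromosome == gene.chromosome and v.is_biallelic
         and touches_exon(gene, v)),
        key=lambda v: v.position,
    )
    samples = exonic[0].samples if exonic else []
    if not exonic:
        logger.info("gene %s: no exonic variants; single all-reference "
                    "haplotype", gene.gene_id)

    strings: dict[str, str] = {}
    for idx, cultivar in enumerate(samples):
        strings[cultivar] = "".join(
            _ALLELE_CHAR[v.genotypes[idx]] for v in exonic)

    complete = [s for s in strings.values() if "." not in s]
    counts = Counter(complete)
    # H1.. by descending count, ties lexicographic by allele string
    ordered = sorted(counts, key=lambda s: (-counts[s], s))
    haplotypes = {f"H{i}": s for i, s in enumerate(ordered, 1)}
    label_of = {s: lab for lab, s in haplotypes.items()}

    membership: dict[str, str | None] = {}
    for cultivar, s in strings.items():
        n_missing = s.count(".")
        if n_missing == 0:
            membership[cultivar] = label_of[s]
        elif n_missing <= max_missing_sites:
            compatible = [lab for lab, hap in haplotypes.items()
                          if all(a == b for a, b in zip(s, hap) if a != ".")]
            membership[cultivar] = compatible[0] if len(compatible) == 1 else None
        else:
            membership[cultivar] = None

    all_ref = "R" * len(exonic)
    return HaplotypeTable(
        gene_id=gene.gene_id,
        sites=[site_id(v) for v in exonic],
        haplotypes=haplotypes,
        membership=membership,
        reference_label=label_of.get(all_ref),
    )


def haplotype_frequencies(table: HaplotypeTable,
                          grouping: Mapping[str, str],
                          ) -> tuple[dict[str, dict[str, int]],
                                     dict[str, dict[str, float]]]:
    """Haplotype counts and within-group proportions.

    ``grouping`` maps cultivar to group name; assigned cultivars without
    a group are ignored, and groups that end up empty are dropped with a
    warning. Returns (counts, proportions), both keyed
    [group][haplotype]; proportions within each group sum to 1.
    """
    counts: dict[str, dict[str, int]] = defaultdict(
        lambda: {lab: 0 for lab in table.haplotypes})
    for cultivar, label in table.membership.items():
        if label is None:
            continue
        group = grouping.get(cultivar)
        if group is not None:
            counts[group][label] += 1
    freqs: dict[str, dict[str, float]] = {}
    for group in list(counts):
        total = sum(counts[group].values())
        if total == 0:
            logger.warning("group %s empty for gene %s; dropped",
                           group, table.gene_id)
            del counts[group]
            continue
        freqs[group] = {lab: c / total for lab, c in counts[group].items()}
    return dict(counts), freqs


def compare_frequencies(counts: Mapping[str, Mapping[str, int]],
                        haplotype_set: Sequence[str] | frozenset[str],
                        group_a: str, group_b: str,
                        gene_id: str = "") -> FrequencyComparison:
    """Compare a haplotype set's carriage frequency between two groups.

    Builds the 2x2 table (in-set vs out-of-set carriers by group) and
    tests it with a continuity-corrected chi-square, falling back to
    Fisher's exact test when any expected count is below 5. Two-sided.
    """
    hap_set = frozenset(haplotype_set)
    in_a = sum(c for lab, c in counts[group_a].items() if lab in hap_set)
    in_b = sum(c for lab, c in counts[group_b].items() if lab in hap_set)
    total_a = sum(counts[group_a].values())
    total_b = sum(counts[group_b].values())
    if total_a == 0 or total_b == 0:
        raise AnalysisError("zero-total group in frequency comparison")
    table = [[in_a, total_a - in_a], [in_b, total_b - in_b]]
    expected = stats.contingency.expected_freq(table)
    if (expected < 5).any():
        res = stats.fisher_exact(table, alternative="two-sided")
        statistic, p, method = None, float(res.pvalue), "fisher"
    else:
        chi2 = stats.chi2_contingency(table, correction=True)
        statistic, p, method = float(chi2.statistic), float(chi2.pvalue), "chi2_cc"
    return FrequencyComparison(
        gene_id=gene_id, haplotype_set=hap_set,
        group_a=group_a, group_b=group_b,
        count_a=in_a, total_a=total_a, count_b=in_b, total_b=total_b,
        statistic=statistic, p_value=p, method=method,
    )


def mg_bin(rmg: float) -> str:
    """Two-way maturity-group bin: 'MG 0-00' for RMG above -1.0 (classes
    0 and 00), 'MG 000-0000' for RMG at or below -1.0."""
    return "MG 0-00" if round(rmg * 10) > -10 else "MG 000-0000"
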