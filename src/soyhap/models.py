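"""Domain types shared across the pipeline.

Coordinate conventions
----------------------
All genomic positions are 1-based inclusive, as in VCF and GFF3. CDS
positions are 1-based along the coding strand. Gene-local offsets in
reports are ``genomic_pos - span_start + 1`` so positions can be quoted
relative to the annotated gene start. Dates are ``datetime.date``; day
counts are plain calendar-day differences.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

from .errors import ValidationError

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse-complement a nucleotide string (IUPAC ACGTN only)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GeneModel:
    """A candidate gene: exon structure plus its coding sequence.

    ``exons`` are 1-based inclusive genomic intervals sorted by genomic
    position and non-overlapping; for minus-strand genes the CDS is the
    reverse complement of the concatenated exon sequence.
    """

    gene_id: str
    chromosome: str
    strand: str  # '+' or '-'
    span_start: int
    span_end: int
    exons: list[tuple[int, int]]
    cds_sequence: str

    def __post_init__(self) -> None:
        self.exons = sorted((int(a), int(b)) for a, b in self.exons)

    # -- invariants -----------------------------------------------------
    def validate(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValidationError(f"{self.gene_id}: strand must be '+' or '-'")
        prev_end = None
        for start, end in self.exons:
            if start > end:
                raise ValidationError(f"{self.gene_id}: exon {start}-{end} inverted")
            if start < self.span_start or end > self.span_end:
                raise ValidationError(
                    f"{self.gene_id}: exon {start}-{end} outside gene span "
                    f"{self.span_start}-{self.span_end}"
                )
            if prev_end is not None and start <= prev_end:
                raise ValidationError(f"{self.gene_id}: overlapping exons")
            prev_end = end
        if self.exon_length != len(self.cds_sequence):
            raise ValidationError(
                f"{self.gene_id}: concatenated exon length {self.exon_length} "
                f"!= CDS length {len(self.cds_sequence)}"
            )
        if len(self.cds_sequence) % 3 != 0:
            raise ValidationError(
                f"{self.gene_id}: CDS length {len(self.cds_sequence)} "
                "is not a multiple of 3"
            )

    @property
    def exon_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    # -- coordinate mapping ---------------------------------------------
    def contains_exonic(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.exons)

    def genomic_to_cds(self, pos: int) -> int | None:
        """Map a genomic position to its 1-based CDS position, or None if
        the position falls outside every exon."""
        offset = 0
        plus_index = None
        for start, end in self.exons:
            if start <= pos <= end:
                plus_index = offset + (pos - start)
                break
            offset += end - start + 1
        if plus_index is None:
            return None
        if self.strand == "+":
            return plus_index + 1
        return len(self.cds_sequence) - plus_index

    def cds_to_genomic(self, cds_pos: int) -> int:
        """Inverse of :meth:`genomic_to_cds` (1-based both sides)."""
        n = len(self.cds_sequence)
        if not 1 <= cds_pos <= n:
            raise ValueError(f"CDS position {cds_pos} outside 1..{n}")
        plus_index = cds_pos - 1 if self.strand == "+" else n - cds_pos
        offset = 0
        for start, end in self.exons:
            length = end - start + 1
            if plus_index < offset + length:
                return start + (plus_index - offset)
            offset += length
        raise AssertionError("unreachable: exon lengths match CDS length")


@dataclass
class SiteEnvironment:
    """One location-year trial environment."""

    env_id: str
    site: str
    year: int
    latitude_deg: float
    longitude_deg: float
    altitude_m: float
    sowing_date: _dt.date
    first_frost_date: _dt.date

    def validate(self) -> None:
        if self.first_frost_date <= self.sowing_date:
            raise ValidationError(
                f"{self.env_id}: first frost {self.first_frost_date} not "
                f"after sowing {self.sowing_date}"
            )


@dataclass
class PhenologyRecord:
    """One cultivar's developmental stage dates in one environment.

    ``r7_date`` is absent (None) when the cultivar did not reach
    physiological maturity before scoring stopped (first-frost censoring).
    """

    cultivar_id: str
    env_id: str
    ve_date: _dt.date
    r1_date: _dt.date
    r7_date: _dt.date | None = None

    def validate(self) -> None:
        if self.r1_date < self.ve_date:
            raise ValidationError(
                f"{self.cultivar_id}/{self.env_id}: R1 {self.r1_date} before "
                f"VE {self.ve_date}"
            )
        if self.r7_date is not None and self.r7_date < self.r1_date:
            raise ValidationError(
                f"{self.cultivar_id}/{self.env_id}: R7 before R1"
            )

    @property
    def dtb_days(self) -> int:
        """Days from emergence (VE) to beginning bloom (R1)."""
        return (self.r1_date - self.ve_date).days

    @property
    def ve_r7_days(self) -> int | None:
        """Days from emergence to physiological maturity, None if censored."""
        if self.r7_date is None:
            return None
        return (self.r7_date - self.ve_date).days


@dataclass
class ReferenceCultivar:
    """A maturity-group standard with a known assigned RMG."""

    cultivar_id: str
    assigned_rmg: float


@dataclass
class RMGModel:
    """Fitted linear map from VE-R7 days to relative maturity group."""

    slope: float  # RMG units per day
    intercept: float  # RMG units
    r_squared: float
    n_points: int
    residual_sd: float  # in RMG units

    def predict(self, ve_r7_days: float) -> float:
        return self.slope * ve_r7_days + self.intercept


@dataclass
class RMGAssignment:
    cultivar_id: str
    rmg: float  # rounded to 0.1
    mg_label: str


@dataclass
class VariantRecord:
    """One VCF site with site-level quality fields and per-cultivar calls.

    Genotype calls are collapsed to {'ref', 'alt', 'het', 'missing'};
    the cultivars are fully inbred so heterozygous calls are treated as
    noise downstream. Quality fields that were absent from the input are
    None. ``alt_alleles`` keeps all ALT alleles; multi-allelic records are
    flagged by the biallelic filter rather than split.
    """

    chromosome: str
    position: int  # 1-based genomic (VCF convention)
    ref_allele: str
    alt_alleles: list[str]
    qual: float | None = None
    depth: float | None = None  # INFO DP
    quality_by_depth: float | None = None  # INFO QD
    mapping_quality: float | None = None  # INFO MQ
    samples: list[str] = field(default_factory=list)
    genotypes: list[str] = field(default_factory=list)  # aligned with samples

    def __post_init__(self) -> None:
        bad = set(self.genotypes) - {"ref", "alt", "het", "missing"}
        if bad:
            raise ValidationError(f"unknown genotype codes: {sorted(bad)}")
        if len(self.samples) != len(self.genotypes):
            raise ValidationError("samples and genotypes differ in length")

    @property
    def alt_allele(self) -> str:
        """The single ALT allele; only meaningful for biallelic records."""
        return self.alt_alleles[0]

    @property
    def is_biallelic(self) -> bool:
        return len(self.alt_alleles) == 1

    @property
    def is_snv(self) -> bool:
        return self.is_biallelic and len(self.ref_allele) == 1 and len(self.alt_allele) == 1

    @property
    def indel_length(self) -> int:
        """len(alt) - len(ref); negative for deletions, 0 for SNVs/MNVs."""
        return len(self.alt_allele) - len(self.ref_allele)

    @property
    def missing_rate(self) -> float:
        if not self.genotypes:
            return 0.0
        return self.genotypes.count("missing") / len(self.genotypes)

    @property
    def maf(self) -> float:
        """Minor allele frequency over non-missing calls; heterozygous
        calls contribute half an alternate allele."""
        n_called = sum(1 for g in self.genotypes if g != "missing")
        if n_called == 0:
            return 0.0
        alt = sum(1.0 if g == "alt" else 0.5 if g == "het" else 0.0
                  for g in self.genotypes)
        freq = alt / n_called
        return min(freq, 1.0 - freq)

    def genotype_of(self, cultivar_id: str) -> str:
        return self.genotypes[self.samples.index(cultivar_id)]


CONSEQUENCE_CLASSES = (
    "synonymous",
    "missense",
    "stop_gained",
    "stop_lost",
    "frameshift",
    "inframe_indel",
    "noncoding",
)


@dataclass
class Consequence:
    """Coding consequence of one variant on one gene."""

    gene_id: str
    chromosome: str
    position: int  # genomic, 1-based
    ref_allele: str
    alt_allele: str
    consequence_class: str
    cds_position: int | None = None  # 1-based within CDS; None if noncoding
    gene_offset: int | None = None  # genomic_pos - span_start + 1
    ref_codon: str | None = None  # SNVs only
    alt_codon: str | None = None
    ref_aa: str | None = None
    alt_aa: str | None = None

    def __post_init__(self) -> None:
        if self.consequence_class not in CONSEQUENCE_CLASSES:
            raise ValidationError(
                f"unknown consequence class {self.consequence_class!r}"
            )


@dataclass
class HaplotypeTable:
    """Per-gene partition of cultivars by their exonic allele strings.

    Allele strings are over {'R' (reference), 'A' (alternate)} in site
    order. ``membership`` maps cultivar to label, or None when the
    cultivar could not be assigned (too many missing/heterozygous sites).
    ``reference_label`` is the label of the all-reference string when that
    string is observed (the Williams 82-like haplotype).
    """

    gene_id: str
    sites: list[str]  # variant identifiers, ordered by genomic position
    haplotypes: dict[str, str]  # label -> allele string
    membership: dict[str, str | None]  # cultivar -> label or None
    reference_label: str | None = None

    def counts(self) -> dict[str, int]:
        out = {label: 0 for label in self.haplotypes}
        for label in self.membership.values():
            if label is not None:
                out[label] += 1
        return out

    @property
    def n_assigned(self) -> int:
        return sum(1 for v in self.membership.values() if v is not None)


@dataclass
class FrequencyComparison:
    """Two-group comparison of a haplotype set's carriage frequency."""

    gene_id: str
    haplotype_set: frozenset[str]
    group_a: str
    group_b: str
    count_a: int  # carriers in group a
    total_a: int
    count_b: int
    total_b: int
    statistic: float | None  # chi-square (continuity-corrected); None for Fisher
    p_value: float
    method: str  # 'chi2_cc' or 'fisher'

    @property
    def freq_a(self) -> float:
        return self.count_a / self.total_a

    @property
    def freq_b(self) -> float:
        return self.count_b / self.total_b


@dataclass
class BlueEstimate:
    """Best linear unbiased estimate of a cultivar's VE-R7 days across
    environments (cultivar fixed, environment random)."""

    cultivar_id: str
    blue_value: float  # days
    n_environments_observed: int
    trait: str = "ve_r7_days"


@dataclass
class HaplotypeStats:
    label: str
    n: int
    mean_blue: float
    letters: str  # Duncan letter display, e.g. 'a', 'ab'


@dataclass
class AssociationResult:
    """Per-gene haplotype-maturity association summary."""

    gene_id: str
    anova_f: float
    anova_p: float
    df_between: int
    df_within: int
    haplotype_stats: list[HaplotypeStats]
    early_set: frozenset[str]
    late_set: frozenset[str]
    t_statistic: float | None = None  # two-haplotype case only

    def stats_for(self, label: str) -> HaplotypeStats:
        for hs in self.haplotype_stats:
            if hs.label == label:
                return hs
        raise KeyError(label)


@dataclass
class SensitivityResult:
    """Photothermal sensitivity statistics for one cultivar.

    Percentages are None when the required site-mean DTB is unavailable.
    """

    cultivar_id: str
    dtb_hh: float | None
    dtb_bjc: float | None
    dtb_lbdl: float | None
    ts_percent: float | None
    ptcrs_percent: float | None
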