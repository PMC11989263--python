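"""Seeded synthetic datasets with the statistical structure the pipeline
assumes: an inbred cultivar panel genotyped at a small candidate-gene
set, phenotyped for phenology at three sites (a baseline site plus a
higher-latitude and a higher-altitude site) over two years each, with
maturity-group reference cultivars for RMG calibration.

The generative model
--------------------
Each cultivar carries one haplotype per gene (fully inbred, so true
genotypes are homozygous; heterozygosity and missingness appear only as
injected call noise). Days from emergence to maturity are additive:

    VE-R7 = base + offset + polygenic + sum_g effect_g(hap) + env + noise

rounded to whole days; the maturity date is censored (absent) when it
would fall after the environment's first frost. Bloom timing is driven
by per-cultivar temperature and photothermal sensitivities constructed
so that later cultivars (higher RMG) are less temperature-sensitive and
more photothermally sensitive, matching the field pattern. Reference
cultivars lie noise-free on the true RMG-to-days line.

All outputs are bit-for-bit reproducible from the seed.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .models import (
    GeneModel,
    PhenologyRecord,
    ReferenceCultivar,
    SiteEnvironment,
    VariantRecord,
    revcomp,
)
from . import io_formats

_STOPS = ("TAA", "TAG", "TGA")
# sense codons that one C>T edit at the first base turns into a stop
_STOP_GAINABLE = ("CAA", "CAG", "CGA")
_BASES = "ACGT"
_SENSE_CODONS = tuple(a + b + c for a in _BASES for b in _BASES for c in _BASES
                      if a + b + c not in _STOPS)


def default_environments() -> list[SiteEnvironment]:
    """The six default trial environments: three sites by two years.

    HH is the baseline site; BJC sits ~3 degrees further north (longer
    days, cooler); LBDL shares HH's latitude at +423 m altitude
    (cooler). First-frost dates are ordered so the baseline site censors
    least: nearly the whole panel matures at HH while roughly a third
    matures at BJC and LBDL.
    """
    def env(site, year, lat, lon, alt, frost_md):
        return SiteEnvironment(
            env_id=f"{site}{year}", site=site, year=year,
            latitude_deg=lat, longitude_deg=lon, altitude_m=alt,
            sowing_date=_dt.date(year, 5, 9),
            first_frost_date=_dt.date(year, *frost_md),
        )

    return [
        env("HH", 2020, 50.25, 127.47, 154.0, (9, 28)),
        env("HH", 2021, 50.25, 127.47, 154.0, (9, 28)),
        env("BJC", 2020, 53.47, 122.35, 295.0, (9, 3)),
        env("BJC", 2021, 53.47, 122.35, 295.0, (9, 3)),
        env("LBDL", 2020, 50.25, 120.32, 577.0, (9, 5)),
        env("LBDL", 2021, 50.25, 120.32, 577.0, (9, 5)),
    ]


def default_haplotype_effects(n_genes: int) -> dict[str, dict[str, float]]:
    """Per-gene haplotype effects in days (negative = earlier maturity).

    The first gene carries a stop-gain haplotype, the second a
    frameshift haplotype — both strongly early, as premature-termination
    alleles of photoreceptor genes are in the field — and three genes
    are phenotypically neutral (distinct haplotypes, zero effect).
    """
    template = [-5.0, -4.0, -3.0, 0.0, -6.0, -2.0, 0.0, -4.0, -3.0, 0.0,
                -5.0, -2.0]
    return {
        f"gene{i + 1:02d}": {"H1": 0.0, "H2": template[i % len(template)]}
        for i in range(n_genes)
    }


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic study.

    Defaults emulate the study conditions: 438 inbred cultivars, 12
    candidate genes, 6 environments, maturity noise of 3 days, a
    10-day-per-RMG-unit calibration line over references spanning RMG
    -2.2 to 0.5, and light heterozygous/missing call noise.
    """

    seed: int = 0
    n_cultivars: int = 438
    n_genes: int = 12
    n_reference_cultivars: int = 28
    reference_rmg_range: tuple[float, float] = (-2.2, 0.5)
    day_length_per_rmg: float = 10.0  # days per RMG unit on the true line
    base_ve_r7_days: float = 115.0  # days at RMG 0 on the true line
    cultivar_offset_days: float = 6.0  # shifts the panel earlier/later
    polygenic_sd: float = 3.0  # background genetic spread, days
    env_effects: dict[str, float] = field(default_factory=lambda: {
        "HH2020": 0.0, "HH2021": 1.0, "BJC2020": 4.0, "BJC2021": 5.0,
        "LBDL2020": 3.0, "LBDL2021": 4.0,
    })
    haplotype_effects: dict[str, dict[str, float]] | None = None
    haplotype_freqs: dict[str, list[float]] | None = None  # per gene
    noise_sd: float = 3.0  # residual days, per record
    emergence_days: int = 8  # sowing to VE
    # bloom model: TS and PTCRS per cultivar as linear functions of true RMG
    dtb_hh_base: float = 42.0
    dtb_per_rmg: float = 2.0
    ts_base_percent: float = 20.0
    ts_per_rmg: float = -3.0  # negative RMG-TS correlation
    ptcrs_base_percent: float = 25.0
    ptcrs_per_rmg: float = 4.0  # positive RMG-PTCRS correlation
    sensitivity_noise_percent: float = 1.0
    dtb_year_noise_sd: float = 0.7
    het_rate: float = 0.01
    missing_rate: float = 0.02
    stop_gain_gene_index: int | None = 0  # gene whose H2 site is a stop-gain
    frameshift_gene_index: int | None = 1  # gene whose H2 site is a 1-bp del

    def __post_init__(self) -> None:
        for name, rate in (("het_rate", self.het_rate),
                           ("missing_rate", self.missing_rate)):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_genes < 1 or self.n_cultivars < 1:
            raise ValueError("need at least one gene and one cultivar")
        if self.haplotype_effects is None:
            self.haplotype_effects = default_haplotype_effects(self.n_genes)

    def cultivar_ids(self) -> list[str]:
        return [f"CV{i + 1:04d}" for i in range(self.n_cultivars)]


@dataclass
class SyntheticBundle:
    """Everything one seeded run produces, before serialization."""

    config: SyntheticConfig
    environments: list[SiteEnvironment]
    genes: list[GeneModel]
    chromosomes: dict[str, str]  # chromosome -> genomic sequence
    variants: list[VariantRecord]
    truth_haplotypes: dict[str, dict[str, str]]  # gene -> cultivar -> label
    genetic_values: dict[str, float]  # cultivar -> genetic VE-R7 days
    phenology: list[PhenologyRecord]
    references: list[ReferenceCultivar]


# ---------------------------------------------------------------------------
# Genes
# ---------------------------------------------------------------------------

def gen_genes(config: SyntheticConfig,
              rng: np.random.Generator | None = None,
              ) -> tuple[list[GeneModel], dict[str, str]]:
    """Generate gene models with valid CDSs (start codon, single terminal
    stop, length a multiple of 3) and 1-5 exons each, one gene per
    chromosome. Returns (genes, chromosome sequences)."""
    rng = rng or np.random.default_rng(config.seed)
    genes: list[GeneModel] = []
    chroms: dict[str, str] = {}
    for i in range(config.n_genes):
        gene_id = f"gene{i + 1:02d}"
        chrom = f"Chr{i + 1:02d}"
        n_codons = int(rng.integers(60, 151))
        codons = [
            _SENSE_CODONS[j]
            for j in rng.integers(0, len(_SENSE_CODONS), n_codons)
        ]
        # guarantee a stop-gainable codon away from both CDS ends
        if not any(c in _STOP_GAINABLE for c in codons[5:-5]):
            codons[n_codons // 2] = _STOP_GAINABLE[
                int(rng.integers(0, len(_STOP_GAINABLE)))]
        cds = "ATG" + "".join(codons) + _STOPS[int(rng.integers(0, 3))]
        strand = "+" if rng.random() < 0.5 else "-"
        coding = cds if strand == "+" else revcomp(cds)

        n_exons = int(rng.integers(1, 6))
        # cut points on a 9-bp grid so every exon chunk is >= 9 bp
        cuts = sorted(rng.choice(
            np.arange(9, len(coding) - 8, 9), size=n_exons - 1, replace=False,
        )) if n_exons > 1 else []
        bounds = [0, *map(int, cuts), len(coding)]
        chunks = [coding[a:b] for a, b in zip(bounds[:-1], bounds[1:])]
        chunks = [c for c in chunks if c]

        flank = "".join(_BASES[j] for j in rng.integers(0, 4, 100))
        pos = len(flank) + 1
        seq_parts = [flank]
        exons = []
        for k, chunk in enumerate(chunks):
            if k > 0:
                intron_len = int(rng.integers(30, 121))
                intron = "".join(_BASES[j]
                                 for j in rng.integers(0, 4, intron_len))
                seq_parts.append(intron)
                pos += intron_len
            exons.append((pos, pos + len(chunk) - 1))
            seq_parts.append(chunk)
            pos += len(chunk)
        tail = "".join(_BASES[j] for j in rng.integers(0, 4, 100))
        seq_parts.append(tail)
        chroms[chrom] = "".join(seq_parts)
        gene = GeneModel(
            gene_id=gene_id, chromosome=chrom, strand=strand,
            span_start=exons[0][0], span_end=exons[-1][1],
            exons=exons, cds_sequence=cds,
        )
        gene.validate()
        genes.append(gene)
    return genes, chroms


# ---------------------------------------------------------------------------
# Variants + true haplotypes
# ---------------------------------------------------------------------------

def _pick_stop_gain_site(gene: GeneModel, chrom_seq: str,
                         rng: np.random.Generator) -> tuple[int, str, str]:
    """Genomic (pos, ref, alt) for a C>T CDS edit creating a premature
    stop (codon CAA/CAG/CGA -> TAA/TAG/TGA) away from the CDS ends."""
    cds = gene.cds_sequence
    candidates = [idx for idx in range(1, len(cds) // 3 - 1)
                  if cds[idx * 3:idx * 3 + 3] in _STOP_GAINABLE]
    codon_idx = candidates[int(rng.integers(0, len(candidates)))]
    cds_pos = codon_idx * 3 + 1  # first base of the codon (the C)
    genomic = gene.cds_to_genomic(cds_pos)
    ref = chrom_seq[genomic - 1]
    alt = "T" if gene.strand == "+" else "A"
    assert ref == ("C" if gene.strand == "+" else "G")
    return genomic, ref, alt


def _pick_frameshift_site(gene: GeneModel, chrom_seq: str, taken: set[int],
                          rng: np.random.Generator) -> tuple[int, str, str]:
    """Genomic (pos, ref, alt) for a 1-bp exonic deletion (anchor base
    kept), with both anchor and deleted base inside one exon and the
    edit away from the CDS ends."""
    options = []
    for start, end in gene.exons:
        for pos in range(start, end):  # anchor pos, deleted pos+1
            cds_a = gene.genomic_to_cds(pos)
            cds_b = gene.genomic_to_cds(pos + 1)
            lo = min(cds_a, cds_b)
            if 7 <= lo <= len(gene.cds_sequence) - 6 \
                    and pos not in taken and pos + 1 not in taken:
                options.append(pos)
    pos = options[int(rng.integers(0, len(options)))]
    return pos, chrom_seq[pos - 1:pos + 1], chrom_seq[pos - 1]


def gen_variants(genes: list[GeneModel], chromosomes: dict[str, str],
                 config: SyntheticConfig,
                 rng: np.random.Generator | None = None,
                 ) -> tuple[list[VariantRecord], dict[str, dict[str, str]]]:
    """Plant exonic variants defining each gene's haplotypes and emit
    genotypes per cultivar consistent with the returned truth table,
    apart from injected heterozygous/missing call noise.

    Haplotype H1 is all-reference; each further haplotype Hk carries the
    alternate allele at its own site. The configured stop-gain gene gets
    a premature-stop SNV and the frameshift gene a 1-bp deletion as
    their H2-defining sites.
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    cultivars = config.cultivar_ids()
    records: list[VariantRecord] = []
    truth: dict[str, dict[str, str]] = {}

    for gi, gene in enumerate(genes):
        effects = config.haplotype_effects[gene.gene_id]
        labels = sorted(effects, key=lambda lab: int(lab[1:]))
        n_sites = len(labels) - 1
        chrom_seq = chromosomes[gene.chromosome]

        exon_positions = [p for s, e in gene.exons for p in range(s, e + 1)]
        if n_sites > len(exon_positions):
            raise ValueError(
                f"{gene.gene_id}: {n_sites} variant sites requested but only "
                f"{len(exon_positions)} exonic bases available"
            )
        taken: set[int] = set()
        sites: list[tuple[int, str, str]] = []
        for si in range(n_sites):
            if si == 0 and gi == config.stop_gain_gene_index:
                site = _pick_stop_gain_site(gene, chrom_seq, rng)
            elif si == 0 and gi == config.frameshift_gene_index:
                site = _pick_frameshift_site(gene, chrom_seq, taken, rng)
            else:
                while True:
                    pos = exon_positions[
                        int(rng.integers(0, len(exon_positions)))]
                    if pos not in taken:
                        break
                ref = chrom_seq[pos - 1]
                alt = _BASES[int(rng.integers(0, 4))]
                while alt == ref:
                    alt = _BASES[int(rng.integers(0, 4))]
                site = (pos, ref, alt)
            taken.update(range(site[0], site[0] + len(site[1])))
            sites.append(site)

        freqs = (config.haplotype_freqs or {}).get(
            gene.gene_id, [1.0 / len(labels)] * len(labels))
        assignment = rng.choice(len(labels), size=len(cultivars), p=freqs)
        truth[gene.gene_id] = {c: labels[a]
                               for c, a in zip(cultivars, assignment)}

        for si, (pos, ref, alt) in enumerate(sites):
            carrier_label = labels[si + 1]
            genotypes = []
            for c in cultivars:
                call = "alt" if truth[gene.gene_id][c] == carrier_label \
                    else "ref"
                if rng.random() < config.het_rate:
                    call = "het"
                if rng.random() < config.missing_rate:
                    call = "missing"
                genotypes.append(call)
            records.append(VariantRecord(
                chromosome=gene.chromosome, position=pos,
                ref_allele=ref, alt_alleles=[alt],
                qual=float(np.round(rng.uniform(100, 1000), 1)),
                depth=float(rng.integers(300, 900)),
                quality_by_depth=float(np.round(rng.uniform(10, 30), 2)),
                mapping_quality=float(np.round(rng.uniform(50, 60), 2)),
                samples=list(cultivars), genotypes=genotypes,
            ))
    records.sort(key=lambda r: (r.chromosome, r.position))
    return records, truth


# ---------------------------------------------------------------------------
# Phenology
# ---------------------------------------------------------------------------

def gen_phenology(truth: dict[str, dict[str, str]],
                  config: SyntheticConfig,
                  environments: list[SiteEnvironment],
                  rng: np.random.Generator | None = None,
                  ) -> tuple[list[PhenologyRecord], list[ReferenceCultivar],
                             list[PhenologyRecord], dict[str, float]]:
    """Phenology for the panel and the references.

    Returns (panel records, reference cultivars, reference phenology
    records, per-cultivar genetic VE-R7 days). Panel maturity dates are
    frost-censored; reference cultivars are noise-free on the true
    RMG-to-days line and grown at the baseline (least censoring) site.
    """
    rng = rng or np.random.default_rng(config.seed + 2)
    cultivars = config.cultivar_ids()
    cfg = config

    genetic = {}
    polygenic = rng.normal(0.0, cfg.polygenic_sd, len(cultivars))
    for c, pg in zip(cultivars, polygenic):
        total_effect = sum(cfg.haplotype_effects[g][truth[g][c]]
                           for g in truth)
        genetic[c] = cfg.base_ve_r7_days + cfg.cultivar_offset_days \
            + float(pg) + total_effect

    # per-cultivar sensitivities as linear functions of the true RMG
    true_rmg = {c: (genetic[c] - cfg.base_ve_r7_days) / cfg.day_length_per_rmg
                for c in cultivars}
    ts = {c: cfg.ts_base_percent + cfg.ts_per_rmg * true_rmg[c]
          + rng.normal(0.0, cfg.sensitivity_noise_percent)
          for c in cultivars}
    pt = {c: cfg.ptcrs_base_percent + cfg.ptcrs_per_rmg * true_rmg[c]
          + rng.normal(0.0, cfg.sensitivity_noise_percent)
          for c in cultivars}
    dtb_hh = {c: cfg.dtb_hh_base + cfg.dtb_per_rmg * true_rmg[c]
              for c in cultivars}

    records: list[PhenologyRecord] = []
    for env in environments:
        env_effect = cfg.env_effects.get(env.env_id, 0.0)
        ve = env.sowing_date + _dt.timedelta(days=cfg.emergence_days)
        for c in cultivars:
            if env.site == "HH":
                dtb = dtb_hh[c]
            elif env.site == "LBDL":
                dtb = dtb_hh[c] / (1.0 - min(ts[c], 95.0) / 100.0)
            else:  # higher-latitude site
                dtb = dtb_hh[c] / (1.0 - min(pt[c], 95.0) / 100.0)
            dtb_days = max(1, round(dtb + rng.normal(0.0, cfg.dtb_year_noise_sd)))
            days = round(genetic[c] + env_effect
                         + rng.normal(0.0, cfg.noise_sd))
            r7 = ve + _dt.timedelta(days=int(days))
            records.append(PhenologyRecord(
                cultivar_id=c, env_id=env.env_id, ve_date=ve,
                r1_date=ve + _dt.timedelta(days=int(dtb_days)),
                r7_date=None if r7 > env.first_frost_date else r7,
            ))

    # reference cultivars: evenly spaced RMGs, noise-free days
    lo, hi = cfg.reference_rmg_range
    ref_rmgs = np.round(np.linspace(lo, hi, cfg.n_reference_cultivars), 1)
    references = [ReferenceCultivar(cultivar_id=f"REF{i + 1:03d}",
                                    assigned_rmg=float(r))
                  for i, r in enumerate(ref_rmgs)]
    ref_records: list[PhenologyRecord] = []
    for env in environments:
        if env.site != "HH":
            continue
        ve = env.sowing_date + _dt.timedelta(days=cfg.emergence_days)
        for ref in references:
            days = round(cfg.base_ve_r7_days
                         + cfg.day_length_per_rmg * ref.assigned_rmg)
            ref_records.append(PhenologyRecord(
                cultivar_id=ref.cultivar_id, env_id=env.env_id, ve_date=ve,
                r1_date=ve + _dt.timedelta(days=round(cfg.dtb_hh_base)),
                r7_date=ve + _dt.timedelta(days=int(days)),
            ))
    return records, references, ref_records, genetic


# ---------------------------------------------------------------------------
# Bundles
# ---------------------------------------------------------------------------

def generate_bundle(config: SyntheticConfig,
                    environments: list[SiteEnvironment] | None = None,
                    ) -> SyntheticBundle:
    """Generate a full dataset; every stream is derived from config.seed."""
    environments = environments or default_environments()
    genes, chroms = gen_genes(config)
    variants, truth = gen_variants(genes, chroms, config)
    phenology, references, ref_records, genetic = gen_phenology(
        truth, config, environments)
    return SyntheticBundle(
        config=config, environments=environments, genes=genes,
        chromosomes=chroms, variants=variants, truth_haplotypes=truth,
        genetic_values=genetic, phenology=phenology + ref_records,
        references=references,
    )


def write_bundle(bundle: SyntheticBundle, out_dir: str | Path) -> dict[str, Path]:
    """Serialize a bundle to plain-text files in ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genes_fasta": out / "genes.fa",
        "genes_gff": out / "genes.gff",
        "variants_vcf": out / "variants.vcf",
        "phenology": out / "phenology.tsv",
        "environments": out / "environments.tsv",
        "reference_cultivars": out / "reference_cultivars.tsv",
        "truth": out / "truth.json",
    }
    io_formats.write_fasta(bundle.chromosomes, paths["genes_fasta"])
    io_formats.write_gff(bundle.genes, paths["genes_gff"])
    io_formats.write_vcf(bundle.variants, paths["variants_vcf"],
                         contigs={c: len(s)
                                  for c, s in bundle.chromosomes.items()})
    io_formats.write_phenology(bundle.phenology, paths["phenology"])
    io_formats.write_environments(bundle.environments, paths["environments"])
    io_formats.write_reference_cultivars(bundle.references,
                                         paths["reference_cultivars"])
    truth_doc = {
        "haplotype_effects": bundle.config.haplotype_effects,
        "haplotypes": bundle.truth_haplotypes,
        "genetic_values": bundle.genetic_values,
    }
    paths["truth"].write_text(json.dumps(truth_doc, indent=1, sort_keys=True))
    return paths
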