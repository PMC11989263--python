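"""Readers and writers for the formats the pipeline touches.

FASTA is read through Biopython, GFF3 through gffutils (in-memory DB),
and VCF through cyvcf2. Delimited tables (phenology, environments,
reference cultivars) accept tab or comma with a sniffed dialect. All
writers emit plain text so a bundle round-trips through these readers.
"""

from __future__ import annotations

import datetime as _dt
import logging
from pathlib import Path

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FormatError, ValidationError
from .models import (
    GeneModel,
    PhenologyRecord,
    ReferenceCultivar,
    SiteEnvironment,
    VariantRecord,
    revcomp,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# FASTA / GFF gene models
# ---------------------------------------------------------------------------

def read_fasta(fasta_path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an id -> uppercase sequence dict."""
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(fasta_path), "fasta")}


def write_fasta(sequences: dict[str, str], fasta_path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in sequences.items()]
    SeqIO.write(records, str(fasta_path), "fasta")


def extract_cds(chrom_seq: str, exons: list[tuple[int, int]], strand: str) -> str:
    """Concatenate exon sequences (1-based inclusive intervals, sorted by
    genomic position) and reverse-complement for minus-strand genes."""
    concat = "".join(chrom_seq[s - 1:e] for s, e in sorted(exons))
    return revcomp(concat) if strand == "-" else concat


def read_gene_models(gff_path: str | Path, fasta_path: str | Path) -> list[GeneModel]:
    """Read gene models from a GFF3-like file plus the genomic FASTA.

    Expects ``gene`` features with an ``ID`` attribute and ``exon``
    features with a ``Parent`` attribute. The CDS is extracted
    strand-aware from the FASTA; every exon is treated as coding.
    """
    sequences = read_fasta(fasta_path)
    db = gffutils.create_db(
        str(gff_path), ":memory:", keep_order=True,
        merge_strategy="create_unique", force=True,
    )
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        gene_id = gene.attributes.get("ID", [gene.id])[0]
        exons = [(exon.start, exon.end)
                 for exon in db.children(gene, featuretype="exon")]
        if not exons:
            raise FormatError(f"gene {gene_id}: no exon features")
        for start, end in exons:
            if start < gene.start or end > gene.end:
                raise FormatError(
                    f"gene {gene_id}: exon {start}-{end} outside gene span "
                    f"{gene.start}-{gene.end}"
                )
        if gene.seqid not in sequences:
            raise FormatError(
                f"gene {gene_id}: chromosome {gene.seqid!r} absent from FASTA"
            )
        cds = extract_cds(sequences[gene.seqid], exons, gene.strand)
        model = GeneModel(
            gene_id=gene_id,
            chromosome=gene.seqid,
            strand=gene.strand,
            span_start=gene.start,
            span_end=gene.end,
            exons=sorted(exons),
            cds_sequence=cds,
        )
        model.validate()  # raises ValidationError naming the gene
        if not cds.startswith("ATG"):
            logger.warning("gene %s: CDS does not start with ATG", gene_id)
        if cds[-3:] not in {"TAA", "TAG", "TGA"}:
            logger.warning("gene %s: CDS does not end with a stop codon", gene_id)
        genes.append(model)
    return genes


def write_gff(genes: list[GeneModel], gff_path: str | Path) -> None:
    """Write gene + exon features as GFF3."""
    lines = ["##gff-version 3"]
    for g in genes:
        lines.append("\t".join([
            g.chromosome, "soyhap", "gene", str(g.span_start), str(g.span_end),
            ".", g.strand, ".", f"ID={g.gene_id}",
        ]))
        for i, (s, e) in enumerate(g.exons, 1):
            lines.append("\t".join([
                g.chromosome, "soyhap", "exon", str(s), str(e),
                ".", g.strand, ".", f"ID={g.gene_id}.exon{i};Parent={g.gene_id}",
            ]))
    Path(gff_path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_GT_CODE = {0: "ref", 1: "het", 2: "missing", 3: "alt"}  # cyvcf2 gt_types


def read_vcf(vcf_path: str | Path) -> list[VariantRecord]:
    """Read a VCF v4.x into VariantRecords (positions kept 1-based).

    INFO keys DP/QD/MQ and QUAL are parsed when present and recorded as
    None when absent. Multi-allelic records are kept whole (all ALT
    alleles listed) so the biallelic filter can flag them.
    """
    from cyvcf2 import VCF

    reader = VCF(str(vcf_path))
    samples = list(reader.samples)
    records: list[VariantRecord] = []
    for v in reader:
        genotypes = [_GT_CODE[t] for t in v.gt_types] if samples else []
        records.append(VariantRecord(
            chromosome=v.CHROM,
            position=v.POS,
            ref_allele=v.REF,
            alt_alleles=list(v.ALT),
            qual=v.QUAL,
            depth=_as_float(v.INFO.get("DP")),
            quality_by_depth=_as_float(v.INFO.get("QD")),
            mapping_quality=_as_float(v.INFO.get("MQ")),
            samples=samples,
            genotypes=genotypes,
        ))
    reader.close()
    return records


def _as_float(value) -> float | None:
    return None if value is None else float(value)


_GT_FIELD = {"ref": "0/0", "het": "0/1", "alt": "1/1", "missing": "./."}


def write_vcf(records: list[VariantRecord], vcf_path: str | Path,
              contigs: dict[str, int] | None = None) -> None:
    """Write VariantRecords as a minimal VCF v4.2 text file."""
    samples = records[0].samples if records else []
    lines = [
        "##fileformat=VCFv4.2",
        "##source=soyhap",
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="Total depth">',
        '##INFO=<ID=QD,Number=1,Type=Float,Description="Quality by depth">',
        '##INFO=<ID=MQ,Number=1,Type=Float,Description="Mapping quality">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    for name, length in (contigs or {}).items():
        lines.append(f"##contig=<ID={name},length={length}>")
    header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]
    if samples:
        header += ["FORMAT"] + list(samples)
    lines.append("\t".join(header))
    for rec in sorted(records, key=lambda r: (r.chromosome, r.position)):
        parts = []
        if rec.depth is not None:
            parts.append(f"DP={int(round(rec.depth))}")  # DP is a read count
        if rec.quality_by_depth is not None:
            parts.append(f"QD={rec.quality_by_depth:g}")
        if rec.mapping_quality is not None:
            parts.append(f"MQ={rec.mapping_quality:g}")
        info = ";".join(parts) or "."
        row = [rec.chromosome, str(rec.position), ".", rec.ref_allele,
               ",".join(rec.alt_alleles),
               "." if rec.qual is None else f"{rec.qual:g}", "PASS", info]
        if samples:
            row += ["GT"] + [_GT_FIELD[g] for g in rec.genotypes]
        lines.append("\t".join(row))
    Path(vcf_path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Delimited tables
# ---------------------------------------------------------------------------

def _read_table(path: str | Path) -> pd.DataFrame:
    """Read a delimited table, sniffing tab vs comma."""
    return pd.read_csv(path, sep=None, engine="python", dtype=str,
                       keep_default_na=False)


def _parse_date(text: str, context: str) -> _dt.date:
    try:
        return _dt.date.fromisoformat(text.strip())
    except ValueError as exc:
        raise FormatError(f"{context}: bad ISO date {text!r}") from exc


def read_environments(path: str | Path) -> list[SiteEnvironment]:
    """Read the site metadata table (env_id, site, year, latitude_deg,
    longitude_deg, altitude_m, sowing_date, first_frost_date)."""
    df = _read_table(path)
    envs = []
    for _, row in df.iterrows():
        env = SiteEnvironment(
            env_id=row["env_id"],
            site=row["site"],
            year=int(row["year"]),
            latitude_deg=float(row["latitude_deg"]),
            longitude_deg=float(row["longitude_deg"]),
            altitude_m=float(row["altitude_m"]),
            sowing_date=_parse_date(row["sowing_date"], row["env_id"]),
            first_frost_date=_parse_date(row["first_frost_date"], row["env_id"]),
        )
        env.validate()
        envs.append(env)
    ids = [e.env_id for e in envs]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate env_id in environments table")
    return envs


def write_environments(envs: list[SiteEnvironment], path: str | Path) -> None:
    pd.DataFrame([{
        "env_id": e.env_id, "site": e.site, "year": e.year,
        "latitude_deg": e.latitude_deg, "longitude_deg": e.longitude_deg,
        "altitude_m": e.altitude_m,
        "sowing_date": e.sowing_date.isoformat(),
        "first_frost_date": e.first_frost_date.isoformat(),
    } for e in envs]).to_csv(path, sep="\t", index=False)


def read_phenology(table_path: str | Path,
                   environments: list[SiteEnvironment]) -> list[PhenologyRecord]:
    """Read the phenology table (columns cultivar, env, VE, R1, R7).

    R7 may be empty (never matured: the record is kept with an absent
    maturity date). Rows with R1 before VE are rejected with a warning
    naming the line number; an unknown env id is an error.
    """
    known = {e.env_id for e in environments}
    df = _read_table(table_path)
    records: list[PhenologyRecord] = []
    for i, row in df.iterrows():
        line_no = i + 2  # header is line 1
        context = f"{table_path} line {line_no}"
        if row["env"] not in known:
            raise ValidationError(f"{context}: unknown env_id {row['env']!r}")
        ve = _parse_date(row["VE"], context)
        r1 = _parse_date(row["R1"], context)
        r7_text = row.get("R7", "").strip()
        r7 = _parse_date(r7_text, context) if r7_text else None
        if r1 < ve:
            logger.warning("%s: R1 %s before VE %s; row rejected",
                           context, r1, ve)
            continue
        rec = PhenologyRecord(cultivar_id=row["cultivar"], env_id=row["env"],
                              ve_date=ve, r1_date=r1, r7_date=r7)
        rec.validate()
        records.append(rec)
    return records


def write_phenology(records: list[PhenologyRecord], path: str | Path) -> None:
    pd.DataFrame([{
        "cultivar": r.cultivar_id, "env": r.env_id,
        "VE": r.ve_date.isoformat(), "R1": r.r1_date.isoformat(),
        "R7": "" if r.r7_date is None else r.r7_date.isoformat(),
    } for r in records]).to_csv(path, sep="\t", index=False)


def read_reference_cultivars(path: str | Path) -> list[ReferenceCultivar]:
    df = _read_table(path)
    return [ReferenceCultivar(cultivar_id=row["cultivar"],
                              assigned_rmg=float(row["assigned_rmg"]))
            for _, row in df.iterrows()]


def write_reference_cultivars(refs: list[ReferenceCultivar],
                              path: str | Path) -> None:
    pd.DataFrame([{"cultivar": r.cultivar_id, "assigned_rmg": r.assigned_rmg}
                  for r in refs]).to_csv(path, sep="\t", index=False)
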