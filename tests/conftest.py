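"""Shared fixtures: tiny hand-built gene models and seeded synthetic
bundles, plus independent oracle helpers used across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from soyhap import synthetic
from soyhap.io_formats import extract_cds
from soyhap.models import GeneModel, VariantRecord, revcomp


@pytest.fixture
def plus_gene() -> tuple[GeneModel, str]:
    """Two-exon plus-strand gene whose CDS is ATGAAATAG; returns
    (gene, chromosome sequence). Exons split the 9-bp CDS 4+5 around a
    5-bp intron."""
    chrom = "GG" + "ATGA" + "CCCCC" + "AATAG" + "GG"
    gene = GeneModel(
        gene_id="toy+", chromosome="chrT", strand="+",
        span_start=3, span_end=16,
        exons=[(3, 6), (12, 16)], cds_sequence="ATGAAATAG",
    )
    gene.validate()
    assert extract_cds(chrom, gene.exons, "+") == "ATGAAATAG"
    return gene, chrom


@pytest.fixture
def minus_gene() -> tuple[GeneModel, str]:
    """Same exon layout on the minus strand; genomic exon bases are the
    reverse complement of the CDS."""
    rc = revcomp("ATGAAATAG")  # CTATTTCAT
    chrom = "GG" + rc[:4] + "CCCCC" + rc[4:] + "GG"
    gene = GeneModel(
        gene_id="toy-", chromosome="chrT", strand="-",
        span_start=3, span_end=16,
        exons=[(3, 6), (12, 16)], cds_sequence="ATGAAATAG",
    )
    gene.validate()
    assert extract_cds(chrom, gene.exons, "-") == "ATGAAATAG"
    return gene, chrom


@pytest.fixture(scope="session")
def default_bundle() -> synthetic.SyntheticBundle:
    """The default study conditions: 438 cultivars, 12 genes, 6 envs."""
    return synthetic.generate_bundle(synthetic.SyntheticConfig(seed=20))


@pytest.fixture(scope="session")
def small_bundle() -> synthetic.SyntheticBundle:
    """A fast bundle for plumbing tests: 40 cultivars, 3 genes."""
    return synthetic.generate_bundle(
        synthetic.SyntheticConfig(seed=7, n_cultivars=40, n_genes=3))


# ---------------------------------------------------------------------------
# Oracles (kept independent of the implementation paths they check)
# ---------------------------------------------------------------------------

def translate_full(cds: str) -> str:
    """Full-length translation via Biopython, '*' for stops."""
    from Bio.Seq import Seq

    trimmed = cds[:len(cds) - len(cds) % 3]
    return str(Seq(trimmed).translate())


def rebuild_cds(chrom: str, gene: GeneModel, variant: VariantRecord) -> str:
    """Oracle: rebuild the CDS from scratch by editing a per-base list of
    (base, is_exonic) tags and concatenating the surviving exonic bases
    (reverse-complemented for minus-strand genes). No coordinate
    arithmetic is shared with the implementation under test."""
    pos, ref, alt = variant.position, variant.ref_allele, variant.alt_allele
    assert chrom[pos - 1:pos - 1 + len(ref)] == ref

    def exon_of(p: int) -> int | None:
        for k, (s, e) in enumerate(gene.exons):
            if s <= p <= e:
                return k
        return None

    entries = [(chrom[i], exon_of(i + 1) is not None)
               for i in range(len(chrom))]
    p0 = pos - 1
    if len(ref) == 1 and len(alt) == 1:
        entries[p0] = (alt, entries[p0][1])
    elif len(ref) > len(alt):  # deletion, alt is the kept prefix
        del entries[p0 + len(alt):p0 + len(ref)]
    else:  # insertion after the anchor run
        anchor = pos + len(ref) - 1
        inside = (exon_of(anchor) is not None
                  and exon_of(anchor) == exon_of(anchor + 1))
        inserted = [(b, inside) for b in alt[len(ref):]]
        entries[p0 + len(ref):p0 + len(ref)] = inserted
    coding = "".join(b for b, tag in entries if tag)
    return revcomp(coding) if gene.strand == "-" else coding


def random_exonic_snv(gene: GeneModel, chrom: str,
                      rng: np.random.Generator) -> VariantRecord:
    positions = [p for s, e in gene.exons for p in range(s, e + 1)]
    pos = int(positions[rng.integers(0, len(positions))])
    ref = chrom[pos - 1]
    alt = "ACGT"[int(rng.integers(0, 4))]
    while alt == ref:
        alt = "ACGT"[int(rng.integers(0, 4))]
    return VariantRecord(chromosome=gene.chromosome, position=pos,
                         ref_allele=ref, alt_alleles=[alt])


def random_exonic_indel(gene: GeneModel, chrom: str,
                        rng: np.random.Generator) -> VariantRecord:
    """A 1-bp insertion or deletion with anchor and edit inside one exon."""
    anchors = [p for s, e in gene.exons for p in range(s, e)]
    while True:
        pos = int(anchors[rng.integers(0, len(anchors))])
        if rng.random() < 0.5:  # deletion of the base after the anchor
            ref, alt = chrom[pos - 1:pos + 1], chrom[pos - 1]
        else:  # insertion after the anchor
            ref = chrom[pos - 1]
            alt = ref + "ACGT"[int(rng.integers(0, 4))]
        return VariantRecord(chromosome=gene.chromosome, position=pos,
                             ref_allele=ref, alt_alleles=[alt])
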