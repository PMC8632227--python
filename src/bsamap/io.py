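"""Readers and writers for the pipeline's on-disk formats.

FASTA and GFF3 go through Biopython/gffutils; VCF output is plain v4.2 text
(input parsing lives in :func:`bsamap.catalog.read_vcf` on top of cyvcf2);
panel, F2 and marker tables are TSV via pandas.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotate import GeneModel
from .catalog import VariantRecord
from .simulate import F2Population


def write_fasta(genome: Mapping[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=chrom, description="") for chrom, seq in genome.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {r.id: str(r.seq).upper() for r in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# GFF3


def write_gff3(genes: Sequence[GeneModel], path, seed: int | None = None) -> None:
    """Write gene models as GFF3 (1-based inclusive coordinates)."""
    lines = ["##gff-version 3"]
    if seed is not None:
        lines.append(f"# simulation-seed: {seed}")
    for g in sorted(genes, key=lambda g: (g.chrom, g.tx_start)):
        col = lambda ftype, s, e, phase, attrs: "\t".join(
            [g.chrom, "bsamap", ftype, str(s), str(e), ".", g.strand, phase, attrs]
        )
        lines.append(col("gene", g.tx_start, g.tx_end, ".", f"ID={g.gene_id}"))
        mrna = f"{g.gene_id}.1"
        lines.append(col("mRNA", g.tx_start, g.tx_end, ".", f"ID={mrna};Parent={g.gene_id}"))
        for i, (s, e) in enumerate(g.exons, 1):
            lines.append(col("exon", s, e, ".", f"ID={mrna}.exon{i};Parent={mrna}"))
        for s, e in g.utr5:
            lines.append(col("five_prime_UTR", s, e, ".", f"Parent={mrna}"))
        for s, e in g.utr3:
            lines.append(col("three_prime_UTR", s, e, ".", f"Parent={mrna}"))
        cds = g.cds if g.strand == "+" else list(reversed(g.cds))
        phase = 0
        for s, e in cds:
            lines.append(col("CDS", s, e, str(phase), f"ID={mrna}.cds;Parent={mrna}"))
            phase = (3 - ((e - s + 1 - phase) % 3)) % 3
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3(path) -> list[GeneModel]:
    """Parse a GFF3 with gene/mRNA/exon/CDS/UTR features into gene models.

    Only the first mRNA of each gene is used (single-transcript models).
    """
    db = gffutils.create_db(
        str(path), dbfn=":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes = []
    for gene in db.features_of_type("gene"):
        mrnas = list(db.children(gene, featuretype="mRNA"))
        target = mrnas[0] if mrnas else gene
        exons = [(f.start, f.end) for f in db.children(target, featuretype="exon")]
        cds = [(f.start, f.end) for f in db.children(target, featuretype="CDS")]
        utr5 = [(f.start, f.end) for f in db.children(target, featuretype="five_prime_UTR")]
        utr3 = [(f.start, f.end) for f in db.children(target, featuretype="three_prime_UTR")]
        genes.append(
            GeneModel(
                gene_id=gene.id,
                chrom=gene.seqid,
                strand=gene.strand,
                tx_start=gene.start,
                tx_end=gene.end,
                exons=sorted(exons),
                cds=sorted(cds),
                utr5=sorted(utr5),
                utr3=sorted(utr3),
            )
        )
    genes.sort(key=lambda g: (g.chrom, g.tx_start))
    return genes


# ---------------------------------------------------------------------------
# VCF


def write_vcf(
    variants: Sequence[VariantRecord],
    chrom_lengths: Mapping[str, int],
    path,
    seed: int | None = None,
    sample: str = "accession",
) -> None:
    """Write variants as a minimal VCF v4.2 with a single sample GT column."""
    lines = ["##fileformat=VCFv4.2", "##source=bsamap"]
    if seed is not None:
        lines.append(f"##simulation_seed={seed}")
    lines.append('##INFO=<ID=END,Number=1,Type=Integer,Description="SV end">')
    lines.append('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV class">')
    lines.append('##ALT=<ID=INV,Description="Inversion">')
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for chrom, length in chrom_lengths.items():
        lines.append(f"##contig=<ID={chrom},length={length}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample)
    for v in sorted(variants, key=lambda v: (v.chrom, v.pos)):
        info = "."
        if v.vclass == "INV":
            info = f"SVTYPE=INV;END={v.pos + v.sv_len}"
        gt = "1/1" if v.zygosity == "hom" else "0/1"
        lines.append(
            f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t50\tPASS\t{info}\tGT\t{gt}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# TSV tables


def write_panel(panel: pd.DataFrame, path) -> None:
    panel.to_csv(path, sep="\t", index_label="accession")


def read_panel(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="accession")


def write_f2(pop: F2Population, path) -> None:
    df = pop.genotypes.copy()
    df.insert(0, "phenotype", pop.phenotype)
    df.to_csv(path, sep="\t", index_label="individual")


def read_f2(path, marker_pos: Mapping[str, tuple[str, int]]) -> F2Population:
    """Load an F2 genotype/phenotype table.

    Populations loaded from disk carry genotypes and phenotypes only; the
    gamete-level recombination structure exists only for freshly simulated
    populations, so ``origin_matrix`` is unavailable on loaded data.
    """
    df = pd.read_csv(path, sep="\t", index_col="individual")
    phenotype = df.pop("phenotype")
    return F2Population(
        ids=list(df.index),
        phenotype=phenotype.to_numpy(),
        genotypes=df,
        gametes={},
        marker_pos=dict(marker_pos),
        causal_pos=None,
    )


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)
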