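"""Genomic-region assignment and coding-effect classification of variants.

Each homozygous variant is placed in exactly one genomic region (CDS, splice
region, UTR, intron, 5-kb upstream/downstream flank, or intergenic) and, when
it falls in coding sequence, classified by its effect on the protein
(synonymous, missense, stop gain/loss, start loss, frameshift, in-frame
InDel). Frameshifts, splice-site changes, start losses and stop gains/losses
are flagged as large-effect variants.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd
from Bio.Seq import Seq

from .catalog import VariantRecord

REGION_ORDER = [
    "cds",
    "splice_region",
    "utr5",
    "utr3",
    "intron",
    "upstream5kb",
    "downstream5kb",
    "intergenic",
]

LARGE_EFFECTS = {"frameshift", "splice_change", "start_loss", "stop_gain", "stop_loss"}


class ReferenceMismatchError(ValueError):
    """Variant REF allele disagrees with the reference sequence."""


@dataclass
class GeneModel:
    """A stranded protein-coding gene with a single annotated transcript.

    All coordinates are 1-based inclusive genomic positions; ``exons``,
    ``cds``, ``utr5`` and ``utr3`` are lists of ``(start, end)`` intervals
    sorted by genomic position regardless of strand.
    """

    gene_id: str
    chrom: str
    strand: str  # "+" | "-"
    tx_start: int
    tx_end: int
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]]
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        for name in ("exons", "cds", "utr5", "utr3"):
            ivs = sorted(getattr(self, name))
            setattr(self, name, ivs)
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                if s2 <= e1:
                    raise ValueError(f"overlapping {name} intervals in {self.gene_id}")
        if self.cds_length % 3 != 0:
            raise ValueError(f"CDS length of {self.gene_id} not divisible by 3")

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [
            (e1 + 1, s2 - 1)
            for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])
            if s2 - e1 > 1
        ]

    def coding_sequence(self, genome: Mapping[str, str]) -> str:
        """Spliced CDS on the coding strand."""
        chrom = genome[self.chrom]
        seq = "".join(chrom[s - 1 : e] for s, e in self.cds)
        if self.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        return seq

    def cds_offset(self, pos: int) -> int | None:
        """0-based offset of genomic ``pos`` within the coding sequence."""
        off = 0
        if self.strand == "+":
            for s, e in self.cds:
                if s <= pos <= e:
                    return off + pos - s
                off += e - s + 1
        else:
            for s, e in reversed(self.cds):
                if s <= pos <= e:
                    return off + e - pos
                off += e - s + 1
        return None


@dataclass
class EffectAnnotation:
    region: str
    effect: str = "none"
    gene_id: str | None = None
    aa_change: tuple[str, int, str] | None = None  # (refAA, 1-based codon, altAA)
    large_effect: bool = False

    def __post_init__(self):
        if self.region not in REGION_ORDER:
            raise ValueError(f"unknown region {self.region!r}")
        self.large_effect = self.effect in LARGE_EFFECTS


COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def _revcomp(s: str) -> str:
    return s.translate(COMPLEMENT)[::-1]


def affected_position(v: VariantRecord) -> int:
    """First reference base actually changed by the variant.

    SNP and INS report the VCF position itself (for an insertion that is the
    anchor base at the insertion point); DEL reports the first deleted base.
    """
    if v.vclass == "DEL":
        return v.pos + 1
    return v.pos


class GeneIndex:
    """Sorted per-chromosome gene lookup for region assignment."""

    def __init__(self, genes: Sequence[GeneModel], flank: int = 5000):
        self.flank = flank
        self._by_chrom: dict[str, list[GeneModel]] = {}
        self._starts: dict[str, list[int]] = {}
        for g in sorted(genes, key=lambda g: (g.chrom, g.tx_start)):
            self._by_chrom.setdefault(g.chrom, []).append(g)
        self._starts = {
            c: [g.tx_start for g in gs] for c, gs in self._by_chrom.items()
        }

    def near(self, chrom: str, pos: int) -> list[GeneModel]:
        genes = self._by_chrom.get(chrom, [])
        if not genes:
            return []
        starts = self._starts[chrom]
        i = bisect.bisect_right(starts, pos + self.flank)
        out = []
        for g in genes[max(0, i - 8) : i]:
            if g.tx_start - self.flank <= pos <= g.tx_end + self.flank:
                out.append(g)
        return out


def _in(ivs, pos):
    return any(s <= pos <= e for s, e in ivs)


def _region_in_gene(g: GeneModel, pos: int, splice_width: int) -> str | None:
    if not (g.tx_start <= pos <= g.tx_end):
        return None
    if _in(g.cds, pos):
        return "cds"
    for s, e in g.introns:
        if s <= pos <= e:
            if pos - s < splice_width or e - pos < splice_width:
                return "splice_region"
            return "intron"
    if _in(g.utr5, pos):
        return "utr5"
    if _in(g.utr3, pos):
        return "utr3"
    # inside the transcript but in none of the above (should not happen for
    # well-formed models); treat as intron
    return "intron"


def assign_region(
    v: VariantRecord,
    genes: GeneIndex | Sequence[GeneModel],
    splice_width: int = 2,
    flank: int = 5000,
) -> EffectAnnotation:
    """Assign a variant to exactly one genomic region.

    Precedence: cds > splice_region > utr5/utr3 > intron > upstream5kb >
    downstream5kb > intergenic. The splice region is the first/last
    ``splice_width`` bp of each intron; flanks are measured strand-aware from
    the transcript boundaries. When two genes' flanks both cover the variant,
    the nearer gene wins; at equal distance upstream beats downstream.
    """
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes, flank)
    pos = affected_position(v)
    best: tuple[int, int, str, str] | None = None  # (rank, dist, region, gene_id)
    for g in index.near(v.chrom, pos):
        region = _region_in_gene(g, pos, splice_width)
        dist = 0
        if region is None:
            if pos < g.tx_start:
                dist = g.tx_start - pos
                region = "upstream5kb" if g.strand == "+" else "downstream5kb"
            else:
                dist = pos - g.tx_end
                region = "downstream5kb" if g.strand == "+" else "upstream5kb"
            if dist > flank:
                continue
        rank = REGION_ORDER.index(region)
        # genic hits (dist 0) sort ahead of flank hits; for flank hits the
        # nearer gene wins and upstream breaks exact ties
        key = (0 if dist == 0 else 1, dist, rank)
        if best is None or key < best[0]:
            best = (key, rank, region, g.gene_id)
    if best is None:
        return EffectAnnotation(region="intergenic")
    return EffectAnnotation(region=best[2], gene_id=best[3])


def _translate_codon(codon: str) -> str:
    return str(Seq(codon).translate())


def classify_cds_effect(
    v: VariantRecord, gene: GeneModel, genome: Mapping[str, str]
) -> EffectAnnotation:
    """Classify the protein-level effect of a CDS variant.

    SNPs are translated through the standard nuclear code on the coding
    strand; InDels are frameshifts unless their length is a multiple of 3.
    """
    chrom_seq = genome[v.chrom]
    if chrom_seq[v.pos - 1 : v.pos - 1 + len(v.ref)] != v.ref:
        raise ReferenceMismatchError(
            f"REF {v.ref!r} does not match reference at {v.chrom}:{v.pos}"
        )
    ann = EffectAnnotation(region="cds", gene_id=gene.gene_id)
    if v.vclass != "SNP":
        if v.vclass == "INV":
            ann.effect = "none"
            return ann
        ann.effect = "frameshift" if v.indel_len % 3 else "inframe_indel"
        ann.__post_init__()
        return ann

    offset = gene.cds_offset(v.pos)
    if offset is None:
        raise ValueError(f"variant {v.chrom}:{v.pos} not in CDS of {gene.gene_id}")
    cds = gene.coding_sequence(genome)
    codon_i = offset // 3
    codon = cds[3 * codon_i : 3 * codon_i + 3]
    alt_base = v.alt if gene.strand == "+" else _revcomp(v.alt)
    within = offset % 3
    alt_codon = codon[:within] + alt_base + codon[within + 1 :]
    ref_aa = _translate_codon(codon)
    alt_aa = _translate_codon(alt_codon)

    if codon_i == 0 and codon == "ATG" and alt_codon != "ATG":
        ann.effect = "start_loss"
    elif ref_aa == alt_aa:
        ann.effect = "synonymous"
    elif ref_aa == "*":
        ann.effect = "stop_loss"
    elif alt_aa == "*":
        ann.effect = "stop_gain"
    else:
        ann.effect = "missense"
        ann.aa_change = (ref_aa, codon_i + 1, alt_aa)
    ann.__post_init__()
    return ann


def annotate_variants(
    variants: Sequence[VariantRecord],
    genes: Sequence[GeneModel],
    genome: Mapping[str, str],
    splice_width: int = 2,
    flank: int = 5000,
) -> list[EffectAnnotation]:
    """Region + effect annotation for a set of homozygous variants."""
    index = GeneIndex(genes, flank)
    by_id = {g.gene_id: g for g in genes}
    out = []
    for v in variants:
        ann = assign_region(v, index, splice_width=splice_width, flank=flank)
        if ann.region == "cds":
            ann = classify_cds_effect(v, by_id[ann.gene_id], genome)
        elif ann.region == "splice_region":
            ann.effect = "splice_change"
            ann.__post_init__()
        out.append(ann)
    return out


GENIC_REGIONS = {"utr5", "utr3", "intron", "splice_region", "cds"}
NONSYN_EFFECTS = {"missense", "stop_gain", "stop_loss", "start_loss"}


def ns_s_ratio(n_nonsynonymous: int, n_synonymous: int) -> float | None:
    """Non-synonymous to synonymous ratio; ``None`` when no synonymous SNPs."""
    if n_synonymous == 0:
        return None
    return n_nonsynonymous / n_synonymous


def proportion_pct(part: int, whole: int) -> float:
    """Percentage of ``part`` in ``whole`` (the arithmetic behind all the
    catalogue/annotation percentage statistics)."""
    if whole <= 0:
        raise ValueError("whole must be positive")
    return 100.0 * part / whole


def annotation_summary(annotations: Sequence[EffectAnnotation]) -> dict:
    """Counts and percentages per region and per coding effect.

    ``genic`` aggregates utr5 + utr3 + intron + splice_region + cds; the
    NS/S ratio counts missense + stop gain/loss + start loss over synonymous.
    """
    if not annotations:
        raise ValueError("empty annotation list")
    n = len(annotations)
    region_counts = {r: 0 for r in REGION_ORDER}
    effect_counts: dict[str, int] = {}
    for a in annotations:
        region_counts[a.region] += 1
        if a.effect != "none":
            effect_counts[a.effect] = effect_counts.get(a.effect, 0) + 1
    genic = sum(region_counts[r] for r in GENIC_REGIONS)
    n_syn = effect_counts.get("synonymous", 0)
    n_nonsyn = sum(effect_counts.get(e, 0) for e in NONSYN_EFFECTS)
    n_large = sum(1 for a in annotations if a.large_effect)
    return {
        "n_total": n,
        "region_counts": region_counts,
        "region_pct": {r: proportion_pct(c, n) for r, c in region_counts.items()},
        "n_genic": genic,
        "genic_pct": proportion_pct(genic, n),
        "effect_counts": effect_counts,
        "n_synonymous": n_syn,
        "n_nonsynonymous": n_nonsyn,
        "ns_s_ratio": ns_s_ratio(n_nonsyn, n_syn),
        "n_large_effect": n_large,
    }


def annotation_table(
    variants: Sequence[VariantRecord], annotations: Sequence[EffectAnnotation]
) -> pd.DataFrame:
    rows = []
    for v, a in zip(variants, annotations):
        rows.append(
            {
                "chrom": v.chrom,
                "pos": v.pos,
                "ref": v.ref,
                "alt": v.alt,
                "vclass": v.vclass,
                "region": a.region,
                "effect": a.effect,
                "gene_id": a.gene_id or "",
                "aa_change": (
                    f"{a.aa_change[0]}{a.aa_change[1]}{a.aa_change[2]}"
                    if a.aa_change
                    else ""
                ),
                "large_effect": a.large_effect,
            }
        )
    return pd.DataFrame(rows)
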