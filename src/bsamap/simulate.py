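"""Synthetic genomes, variants, accession panels and F2 populations.

This module builds everything the downstream stages need, scaled down from a
real resequencing study of two inbred crop accessions:

* a reference genome with protein-coding gene models (UTRs, multi-exon CDS),
* a divergent accession differing by transition-biased SNPs, InDels with a
  realistic length mixture, and occasional structural variants,
* a multi-accession genotype panel with per-locus allele-frequency priors
  (the substrate for marker informativeness screening),
* an F2 population from a cross between a mutagenized line carrying one
  recessive EMS-type (G→A) causal mutation and the divergent accession, and
* read-pool allele-frequency tables emulating pooled resequencing of
  phenotype-contrasted bulks.

Every generator is deterministic under a fixed seed: each draws from its own
substream of ``numpy.random.default_rng([seed, stream])``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotate import GeneModel, classify_cds_effect
from .catalog import VariantRecord

BASES = np.frombuffer(b"ACGT", dtype="S1")
STOPS = ("TAA", "TAG", "TGA")
_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]
NON_STOP_CODONS = [c for c in _CODONS if c not in STOPS]
TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}
COMPLEMENT = str.maketrans("ACGT", "TGCA")

REGION_CODES = {
    0: "intergenic",
    1: "downstream5kb",
    2: "upstream5kb",
    3: "intron",
    4: "utr3",
    5: "utr5",
    6: "splice_region",
    7: "cds",
}


class SizingError(ValueError):
    """Requested gene count does not fit the chromosome length."""


class PlacementError(ValueError):
    """The causal mutation cannot be placed as requested."""


@dataclass(frozen=True)
class CausalSpec:
    """Where to plant the recessive causal mutation: a G→A substitution on
    the coding strand near ``pos`` on ``chrom``."""

    chrom: str = "chr5"
    pos: int = 770_000


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the whole simulation.

    Rates are per bp; ``ts_bias`` is the probability a SNP is a transition;
    ``indel_len_mix`` gives the probabilities of the 1 bp / 2–20 bp /
    21–200 bp InDel length classes. Defaults mirror the densities and
    spectra observed in a deep resequencing comparison of two foxtail millet
    accessions (≈2720 SNPs and 486 InDels per Mb, Ts/Tv ≈ 2.73, ≈21% of SNP
    calls heterozygous, ≈48% single-base InDels) and a 982-individual F2
    cross segregating one recessive mutation 3:1.
    """

    seed: int = 0
    n_chromosomes: int = 9
    chrom_length: int = 1_000_000
    n_genes: int = 900
    snp_rate: float = 2.72e-3
    indel_rate: float = 4.86e-4
    ts_bias: float = 0.732
    indel_len_mix: tuple[float, float, float] = (0.4850, 0.4474, 0.0676)
    het_fraction: float = 0.2
    sv_rate: float = 4.0e-6
    sv_class_probs: tuple[float, float, float] = (0.242, 0.747, 0.011)  # INS/DEL/INV
    sv_len_range: tuple[int, int] = (100, 600)
    ems_rate: float = 5.0e-6
    gc_content: float = 0.46
    panel_size: int = 1826
    # per-locus allele-number weights and Dirichlet concentration for the
    # accession panel; None for panel_fixed_freq means "use the prior"
    panel_allele_weights: tuple[float, float, float] = (0.50, 0.30, 0.20)  # 2/3/4 alleles
    panel_dirichlet_alpha: float = 1.6
    panel_fixed_freq: float | None = None
    f2_size: int = 982
    causal: CausalSpec | None = field(default_factory=CausalSpec)

    def validate(self) -> None:
        if min(self.snp_rate, self.indel_rate, self.sv_rate, self.ems_rate) < 0:
            raise ValueError("rates must be >= 0")
        for p in (self.ts_bias, self.het_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        if abs(sum(self.indel_len_mix) - 1.0) > 1e-9:
            raise ValueError("indel_len_mix must sum to 1")
        if not 0.25 <= self.gc_content <= 0.65:
            raise ValueError("gc_content outside supported range")
        if self.n_chromosomes < 1 or self.chrom_length < 20_000:
            raise ValueError("need at least one chromosome of >= 20 kb")

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]

    def chrom_lengths(self) -> dict[str, int]:
        return {c: self.chrom_length for c in self.chrom_names()}

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


# rng substreams, one per generator so stages stay independent
_S_GENOME, _S_MUT, _S_PANEL, _S_F2, _S_POOL = 11, 13, 17, 19, 23


@dataclass
class SimTruth:
    """Ground truth of one simulated study."""

    variants: list[VariantRecord]  # inter-accession variants (the "VCF")
    region_labels: dict[tuple[str, int], str]  # truth region per variant
    causal_variant: VariantRecord | None
    causal_gene_id: str | None
    ems_variants: list[VariantRecord]  # mutant-parent private background
    chrom_lengths: dict[str, int]


# ---------------------------------------------------------------------------
# reference genome + gene models


def _random_seq_codes(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    at = (1.0 - gc) / 2.0
    p = np.array([at, gc / 2.0, gc / 2.0, at])
    return rng.choice(4, size=n, p=p).astype(np.uint8)


def _codes_to_str(codes: np.ndarray) -> str:
    return BASES[codes].tobytes().decode("ascii")


def _str_to_codes(s: str) -> np.ndarray:
    lut = np.full(128, 255, dtype=np.uint8)
    for i, b in enumerate("ACGT"):
        lut[ord(b)] = i
    return lut[np.frombuffer(s.encode("ascii"), dtype=np.uint8)]


def _rand_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    return _codes_to_str(_random_seq_codes(rng, n, gc))


def _gene_local_layout(rng: np.random.Generator, gc: float):
    """Compose one gene on its coding strand.

    Returns (sequence, piece list) where pieces are ``(kind, start, end)``
    half-open local intervals, kinds in {utr5, cds, intron, utr3}.
    """
    utr5 = int(rng.integers(60, 201))
    utr3 = int(rng.integers(100, 301))
    n_exons = int(rng.integers(2, 6))
    n_codons = int(rng.integers(80, 301))
    middle = rng.integers(0, len(NON_STOP_CODONS), size=n_codons - 2)
    cds_seq = (
        "ATG"
        + "".join(NON_STOP_CODONS[i] for i in middle)
        + STOPS[int(rng.integers(0, 3))]
    )
    cds_len = len(cds_seq)
    # split CDS across exons, every piece at least 10 bp
    while True:
        cuts = np.sort(rng.integers(10, cds_len - 10, size=n_exons - 1))
        parts = np.diff(np.concatenate([[0], cuts, [cds_len]]))
        if (parts >= 10).all():
            break
    intron_lens = [int(rng.integers(80, 401)) for _ in range(n_exons - 1)]

    pieces: list[tuple[str, int, int]] = []
    seq_parts: list[str] = []
    off = 0

    def emit(kind: str, s: str):
        nonlocal off
        pieces.append((kind, off, off + len(s)))
        seq_parts.append(s)
        off += len(s)

    emit("utr5", _rand_seq(rng, utr5, gc))
    cds_off = 0
    for i, part in enumerate(parts):
        emit("cds", cds_seq[cds_off : cds_off + part])
        cds_off += part
        if i < len(intron_lens):
            ilen = intron_lens[i]
            emit("intron", "GT" + _rand_seq(rng, ilen - 4, gc) + "AG")
    emit("utr3", _rand_seq(rng, utr3, gc))
    return "".join(seq_parts), pieces


def _map_local(pieces, gene_start: int, total: int, strand: str):
    """Map half-open local intervals to 1-based inclusive genomic intervals."""
    out: dict[str, list[tuple[int, int]]] = {"utr5": [], "cds": [], "intron": [], "utr3": []}
    for kind, s, e in pieces:
        if strand == "+":
            g = (gene_start + s, gene_start + e - 1)
        else:
            g = (gene_start + total - e, gene_start + total - 1 - s)
        out[kind].append(g)
    for k in out:
        out[k].sort()
    return out


def generate_reference(config: SimConfig):
    """Build the reference genome and its gene models.

    Returns ``(genome, genes)`` where ``genome`` maps chromosome name to
    sequence and ``genes`` is a list of :class:`GeneModel`. Genes are
    non-overlapping, each with >= 2 exons, both UTRs, and a CDS that starts
    with ATG, ends with a stop codon and has no premature stop.
    """
    config.validate()
    rng = config.rng(_S_GENOME)
    margin = 5_000
    per_chrom = _split_evenly(config.n_genes, config.n_chromosomes)
    genome: dict[str, str] = {}
    genes: list[GeneModel] = []
    for ci, chrom in enumerate(config.chrom_names()):
        codes = _random_seq_codes(rng, config.chrom_length, config.gc_content)
        k = per_chrom[ci]
        if k:
            usable = config.chrom_length - 2 * margin
            slot = usable // k
            if slot < 5_000:
                raise SizingError(
                    f"{k} genes do not fit on a {config.chrom_length} bp chromosome"
                )
            for gi in range(k):
                strand = "+" if rng.random() < 0.5 else "-"
                local_seq, pieces = _gene_local_layout(rng, config.gc_content)
                total = len(local_seq)
                if total > slot - 1_000:
                    raise SizingError("gene span exceeds its placement slot")
                lo = margin + gi * slot
                start = int(lo + rng.integers(0, slot - total - 500))  # 0-based
                genomic = local_seq if strand == "+" else local_seq.translate(COMPLEMENT)[::-1]
                codes[start : start + total] = _str_to_codes(genomic)
                iv = _map_local(pieces, start + 1, total, strand)
                exons = _merge_adjacent(
                    sorted(iv["utr5"] + iv["cds"] + iv["utr3"]), iv["intron"]
                )
                genes.append(
                    GeneModel(
                        gene_id=f"gene_{chrom[3:]}_{gi + 1:04d}",
                        chrom=chrom,
                        strand=strand,
                        tx_start=start + 1,
                        tx_end=start + total,
                        exons=exons,
                        cds=iv["cds"],
                        utr5=iv["utr5"],
                        utr3=iv["utr3"],
                    )
                )
        genome[chrom] = _codes_to_str(codes)
    genes.sort(key=lambda g: (g.chrom, g.tx_start))
    return genome, genes


def _split_evenly(total: int, k: int) -> list[int]:
    base, extra = divmod(total, k)
    return [base + (1 if i < extra else 0) for i in range(k)]


def _merge_adjacent(non_intron, introns):
    """Merge touching UTR/CDS intervals into exons (introns break runs)."""
    exons = []
    for s, e in non_intron:
        if exons and s == exons[-1][1] + 1:
            exons[-1] = (exons[-1][0], e)
        else:
            exons.append((s, e))
    return exons


# ---------------------------------------------------------------------------
# truth region labels (computed from the generator's own layout, kept
# deliberately separate from the annotator's interval logic)


def _region_label_arrays(config: SimConfig, genes: Sequence[GeneModel], flank=5000, splice=2):
    labels = {c: np.zeros(config.chrom_length, dtype=np.uint8) for c in config.chrom_names()}
    best_dist = {c: np.full(config.chrom_length, np.int64(1 << 60)) for c in config.chrom_names()}
    # flanks first: nearer gene wins, tie -> upstream
    for g in genes:
        lab, dist = labels[g.chrom], best_dist[g.chrom]
        L = config.chrom_length
        ls, le = max(0, g.tx_start - 1 - flank), g.tx_start - 1
        if le > ls:
            d = g.tx_start - np.arange(ls + 1, le + 1)
            code = 2 if g.strand == "+" else 1  # upstream on +, downstream on -
            _update_flank(lab, dist, ls, le, d, code)
        rs, re = g.tx_end, min(L, g.tx_end + flank)
        if re > rs:
            d = np.arange(rs + 1, re + 1) - g.tx_end
            code = 1 if g.strand == "+" else 2
            _update_flank(lab, dist, rs, re, d, code)
    # genic regions overwrite flanks
    for g in genes:
        lab = labels[g.chrom]
        for s, e in g.introns:
            lab[s - 1 : e] = 3
            lab[s - 1 : s - 1 + splice] = 6
            lab[e - splice : e] = 6
        for s, e in g.utr3:
            lab[s - 1 : e] = 4
        for s, e in g.utr5:
            lab[s - 1 : e] = 5
        for s, e in g.cds:
            lab[s - 1 : e] = 7
    return labels


def _update_flank(lab, dist, s, e, d, code):
    seg_d = dist[s:e]
    seg_l = lab[s:e]
    better = (d < seg_d) | ((d == seg_d) & (code == 2) & (seg_l == 1))
    seg_d[better] = d[better]
    seg_l[better] = code
    dist[s:e] = seg_d
    lab[s:e] = seg_l


# ---------------------------------------------------------------------------
# divergent accession


def mutate_accession(genome: Mapping[str, str], genes: Sequence[GeneModel], config: SimConfig):
    """Derive the divergent accession from the reference.

    Returns ``(alt_genome, variants, truth)``. Homozygous variants are
    applied to the alternate genome; heterozygous calls (an artifact of
    variant calling on inbred material, emitted at ``het_fraction``) are
    recorded in the truth set but not applied. The causal EMS mutation is
    private to the mutagenized line and is *not* part of the inter-accession
    variant list or the alternate genome.
    """
    config.validate()
    rng = config.rng(_S_MUT)
    L = config.chrom_length
    variants: list[VariantRecord] = []
    labels: dict[tuple[str, int], str] = {}
    label_arrays = _region_label_arrays(config, genes)
    alt_genome: dict[str, str] = {}

    for chrom in config.chrom_names():
        seq = genome[chrom]
        chrom_vars: list[VariantRecord] = []

        # SVs and InDels first; they block surrounding positions so events
        # never overlap each other
        n_indel = rng.binomial(L, config.indel_rate)
        n_sv = rng.binomial(L, config.sv_rate)
        blocked = np.zeros(L + 2, dtype=bool)
        sv_pos: list[int] = []
        for pos in np.sort(rng.integers(2, max(3, L - 800), size=n_sv)):
            pos = int(pos)
            if blocked[pos]:
                continue
            sv_pos.append(pos)
            blocked[max(0, pos - 650) : min(L, pos + 1050)] = True
        indel_pos: list[int] = []
        for pos in np.sort(rng.integers(2, max(3, L - 250), size=n_indel)):
            pos = int(pos)
            if blocked[pos]:
                continue
            indel_pos.append(pos)
            blocked[max(0, pos - 250) : min(L, pos + 450)] = True

        for pos in indel_pos:
            length = _draw_indel_len(rng, config.indel_len_mix)
            chrom_vars.append(_make_indel(rng, seq, chrom, pos, length, config))
        for pos in sv_pos:
            chrom_vars.append(_make_sv(rng, seq, chrom, pos, config))

        # SNPs avoid positions consumed by InDel/SV ref spans
        consumed = np.zeros(L + 2, dtype=bool)
        for v in chrom_vars:
            span = max(len(v.ref), v.sv_len if v.vclass == "INV" else 0)
            consumed[v.pos : v.pos + span + 1] = True
        n_snp = rng.binomial(L, config.snp_rate)
        cand = rng.choice(np.arange(2, L), size=min(n_snp + 2000, L - 2), replace=False)
        snp_pos = [int(p) for p in cand if not consumed[p]][:n_snp]
        for pos in sorted(snp_pos):
            ref = seq[pos - 1]
            alt = _draw_snp_alt(rng, ref, config.ts_bias)
            zyg = "het" if rng.random() < config.het_fraction else "hom"
            chrom_vars.append(VariantRecord(chrom, pos, ref, alt, zyg))

        chrom_vars.sort(key=lambda v: v.pos)
        lab = label_arrays[chrom]
        for v in chrom_vars:
            ap = v.pos + 1 if v.vclass == "DEL" else v.pos
            labels[(chrom, v.pos)] = REGION_CODES[int(lab[min(ap, L) - 1])]
        variants.extend(chrom_vars)
        alt_genome[chrom] = _apply_variants(seq, [v for v in chrom_vars if v.zygosity == "hom"])

    causal = causal_gene = None
    if config.causal is not None:
        causal, causal_gene = _place_causal(genome, genes, config.causal)

    ems = _ems_background(rng, genome, config, exclude=causal)
    truth = SimTruth(
        variants=variants,
        region_labels=labels,
        causal_variant=causal,
        causal_gene_id=causal_gene,
        ems_variants=ems,
        chrom_lengths=config.chrom_lengths(),
    )
    return alt_genome, variants, truth


def _draw_indel_len(rng, mix) -> int:
    cls = rng.choice(3, p=np.asarray(mix) / sum(mix))
    if cls == 0:
        return 1
    if cls == 1:
        return int(rng.integers(2, 21))
    return int(rng.integers(21, 201))


def _make_indel(rng, seq: str, chrom: str, pos: int, length: int, config: SimConfig):
    zyg = "het" if rng.random() < config.het_fraction else "hom"
    anchor = seq[pos - 1]
    if rng.random() < 0.5 and pos + length <= len(seq):  # deletion
        return VariantRecord(chrom, pos, seq[pos - 1 : pos + length], anchor, zyg)
    ins = _rand_seq(rng, length, config.gc_content)
    return VariantRecord(chrom, pos, anchor, anchor + ins, zyg)


def _make_sv(rng, seq: str, chrom: str, pos: int, config: SimConfig):
    zyg = "het" if rng.random() < config.het_fraction else "hom"
    lo, hi = config.sv_len_range
    length = int(rng.integers(lo, hi + 1))
    kind = rng.choice(3, p=np.asarray(config.sv_class_probs) / sum(config.sv_class_probs))
    anchor = seq[pos - 1]
    if kind == 0:  # INS
        return VariantRecord(chrom, pos, anchor, anchor + _rand_seq(rng, length, config.gc_content), zyg)
    if kind == 1 and pos + length <= len(seq):  # DEL
        return VariantRecord(chrom, pos, seq[pos - 1 : pos + length], anchor, zyg)
    return VariantRecord(chrom, pos, anchor, "<INV>", zyg, sv_len=length)


def _draw_snp_alt(rng, ref: str, ts_bias: float) -> str:
    if rng.random() < ts_bias:
        return TRANSITION[ref]
    tv = TRANSVERSIONS[ref]
    return tv[int(rng.integers(0, 2))]


def _apply_variants(seq: str, variants: Sequence[VariantRecord]) -> str:
    """Apply sorted non-overlapping homozygous variants to a sequence."""
    parts: list[str] = []
    cur = 0  # 0-based cursor into seq
    for v in variants:
        if v.vclass == "SNP":
            parts.append(seq[cur : v.pos - 1])
            parts.append(v.alt)
            cur = v.pos
        elif v.vclass == "INV":
            end = v.pos + v.sv_len  # inverted segment [pos+1 .. pos+sv_len]
            parts.append(seq[cur : v.pos])
            seg = seq[v.pos : end]
            parts.append(seg.translate(COMPLEMENT)[::-1])
            cur = end
        else:  # INS / DEL share the anchored-allele convention
            parts.append(seq[cur : v.pos - 1])
            parts.append(v.alt)
            cur = v.pos - 1 + len(v.ref)
    parts.append(seq[cur:])
    return "".join(parts)


def _place_causal(genome, genes: Sequence[GeneModel], spec: CausalSpec):
    """Plant a missense G→A (coding strand) mutation near the requested spot."""
    cands = [g for g in genes if g.chrom == spec.chrom]
    if not cands:
        raise PlacementError(f"no genes on {spec.chrom}")
    cands.sort(key=lambda g: abs((g.tx_start + g.tx_end) // 2 - spec.pos))
    seq = genome[spec.chrom]
    for gene in cands[:5]:
        positions = []
        for s, e in gene.cds:
            positions.extend(range(s, e + 1))
        positions.sort(key=lambda p: abs(p - spec.pos))
        want_ref = "G" if gene.strand == "+" else "C"
        alt = "A" if gene.strand == "+" else "T"
        for pos in positions:
            if seq[pos - 1] != want_ref:
                continue
            v = VariantRecord(spec.chrom, pos, want_ref, alt, "hom")
            ann = classify_cds_effect(v, gene, genome)
            if ann.effect == "missense":
                return v, gene.gene_id
    raise PlacementError(
        f"no coding-strand G with a missense G→A near {spec.chrom}:{spec.pos}"
    )


def _ems_background(rng, genome, config: SimConfig, exclude: VariantRecord | None):
    """Non-causal EMS mutations private to the mutagenized parent."""
    out: list[VariantRecord] = []
    for chrom in config.chrom_names():
        seq = genome[chrom]
        n = rng.binomial(len(seq), config.ems_rate)
        for pos in sorted(int(p) for p in rng.integers(2, len(seq), size=n)):
            if exclude is not None and chrom == exclude.chrom and pos == exclude.pos:
                continue
            ref = seq[pos - 1]
            if ref == "G":
                out.append(VariantRecord(chrom, pos, "G", "A", "hom"))
            elif ref == "C":
                out.append(VariantRecord(chrom, pos, "C", "T", "hom"))
    return out


# ---------------------------------------------------------------------------
# accession genotype panel


def generate_panel(loci: Sequence[VariantRecord], config: SimConfig) -> pd.DataFrame:
    """Simulate inbred-accession genotypes at the given loci.

    Each accession carries a single allele per locus (index 0 = reference,
    1 = the resequenced accession's allele, 2+ = additional length alleles
    seen only in the wider panel), drawn from a per-locus allele-frequency
    prior: the number of alleles follows ``panel_allele_weights`` and the
    frequencies a symmetric Dirichlet. With ``panel_fixed_freq`` set, every
    locus is biallelic with that reference-allele frequency.
    """
    if config.panel_size < 2:
        raise ValueError("panel_size must be >= 2")
    rng = config.rng(_S_PANEL)
    cols = {}
    for v in loci:
        if config.panel_fixed_freq is not None:
            freqs = np.array([config.panel_fixed_freq, 1.0 - config.panel_fixed_freq])
        else:
            k = 2 + rng.choice(3, p=np.asarray(config.panel_allele_weights))
            freqs = rng.dirichlet([config.panel_dirichlet_alpha] * k)
        cols[f"{v.chrom}:{v.pos}"] = rng.choice(len(freqs), size=config.panel_size, p=freqs)
    index = [f"acc{i + 1:04d}" for i in range(config.panel_size)]
    return pd.DataFrame(cols, index=index, dtype=np.int16)


# ---------------------------------------------------------------------------
# F2 population


class F2Population:
    """A simulated F2 from (mutant line × divergent accession).

    Genotype codes per marker: ``A`` = homozygous mutant-parent, ``B`` =
    homozygous mapping-parent, ``H`` = heterozygous. Phenotype is ``mutant``
    iff the individual is homozygous for the causal allele.
    """

    def __init__(self, ids, phenotype, genotypes, gametes, marker_pos, causal_pos):
        self.ids = list(ids)
        self.phenotype = pd.Series(phenotype, index=self.ids, name="phenotype")
        self.genotypes = genotypes  # DataFrame individuals × markers
        self._gametes = gametes  # chrom -> (starts (n,2), xo (n,2,kmax) padded with +inf)
        self.marker_pos = marker_pos  # marker_id -> (chrom, pos)
        self.causal_pos = causal_pos  # (chrom, pos) or None

    def __len__(self) -> int:
        return len(self.ids)

    def origin_matrix(self, chrom: str, pos: int) -> np.ndarray:
        """Parental origin (0 = mutant parent, 1 = mapping parent) of both
        haplotypes of every individual at a genomic position."""
        starts, xo = self._gametes[chrom]
        crossed = (xo <= pos).sum(axis=2) & 1
        return starts ^ crossed

    def genotype_at(self, chrom: str, pos: int) -> np.ndarray:
        org = self.origin_matrix(chrom, pos).sum(axis=1)
        return np.array(["A", "H", "B"])[org]

    def add_markers(self, markers: Sequence) -> None:
        """Genotype the population at additional markers in place.

        Only possible on freshly simulated populations, which retain their
        gamete-level recombination structure; emulates developing new
        markers for an already-grown population.
        """
        if not self._gametes:
            raise ValueError("population has no gamete structure to genotype from")
        for m in markers:
            mid, chrom, pos = _marker_tuple(m)
            self.marker_pos[mid] = (chrom, pos)
            self.genotypes[mid] = self.genotype_at(chrom, pos)

    @property
    def recessives(self) -> list[str]:
        return [i for i in self.ids if self.phenotype[i] == "mutant"]

    def subset(self, ids: Sequence[str]) -> "F2Population":
        idx = [self.ids.index(i) for i in ids]
        sub_gam = {
            c: (starts[idx], xo[idx]) for c, (starts, xo) in self._gametes.items()
        }
        return F2Population(
            ids,
            self.phenotype.loc[list(ids)].to_numpy(),
            self.genotypes.loc[list(ids)],
            sub_gam,
            self.marker_pos,
            self.causal_pos,
        )


def generate_f2(
    truth: SimTruth,
    markers: Sequence,
    config: SimConfig,
    mean_extra_crossovers: float = 1.0,
) -> F2Population:
    """Simulate the F2 of (mutagenized line × divergent accession).

    Each gamete receives one obligate crossover per chromosome plus a
    Poisson(``mean_extra_crossovers``) number of extras, at uniform
    positions. ``markers`` is any sequence with ``marker_id``, ``chrom`` and
    ``pos`` attributes (or ``(marker_id, chrom, pos)`` tuples).
    """
    if truth.causal_variant is None:
        raise ValueError("truth has no causal variant")
    config.validate()
    rng = config.rng(_S_F2)
    marker_list = [_marker_tuple(m) for m in markers]
    chroms = list(truth.chrom_lengths)
    marker_chroms = {c for _, c, _ in marker_list}
    causal = truth.causal_variant
    if causal.chrom not in marker_chroms:
        raise ValueError(f"no markers on causal chromosome {causal.chrom}")

    n = config.f2_size
    gametes = {}
    for chrom in chroms:
        L = truth.chrom_lengths[chrom]
        k = 1 + rng.poisson(mean_extra_crossovers, size=(n, 2))
        kmax = int(k.max())
        xo = np.full((n, 2, kmax), np.inf)
        u = rng.integers(1, L, size=(n, 2, kmax)).astype(float)
        mask = np.arange(kmax) < k[..., None]
        xo[mask] = u[mask]
        xo.sort(axis=2)
        starts = rng.integers(0, 2, size=(n, 2))
        gametes[chrom] = (starts, xo)

    ids = [f"f2_{i + 1:04d}" for i in range(n)]
    pop = F2Population(ids, [""] * n, None, gametes, {}, (causal.chrom, causal.pos))
    hom_causal = pop.origin_matrix(causal.chrom, causal.pos).sum(axis=1) == 0
    phenotype = np.where(hom_causal, "mutant", "wild")
    geno = {}
    marker_pos = {}
    for mid, chrom, pos in marker_list:
        marker_pos[mid] = (chrom, pos)
        geno[mid] = pop.genotype_at(chrom, pos)
    genotypes = pd.DataFrame(geno, index=ids)
    return F2Population(ids, phenotype, genotypes, gametes, marker_pos, (causal.chrom, causal.pos))


def _marker_tuple(m):
    if isinstance(m, tuple):
        return m
    variant = getattr(m, "variant", None)
    if variant is not None:
        return (m.marker_id, variant.chrom, variant.pos)
    return (m.marker_id, m.chrom, m.pos)


# ---------------------------------------------------------------------------
# pooled resequencing of phenotype bulks


def simulate_pool_freqs(
    pop: F2Population,
    variants: Sequence[VariantRecord],
    carrier: Mapping[tuple[str, int], str],
    config: SimConfig,
    n_mutant: int = 100,
    n_wild: int = 100,
    depth: int = 200,
) -> pd.DataFrame:
    """Allele frequencies of phenotype-contrasted bulks at the given variants.

    ``carrier`` says which parent carries the ALT allele of each variant
    (``"A"`` = mutant line, ``"B"`` = mapping parent). Pool frequencies are
    the true pooled allele fractions resampled binomially at the given read
    depth, emulating pooled whole-genome resequencing.
    """
    rng = config.rng(_S_POOL)
    pheno = pop.phenotype.to_numpy()
    mut_idx = np.flatnonzero(pheno == "mutant")
    wild_idx = np.flatnonzero(pheno == "wild")
    if len(mut_idx) < n_mutant or len(wild_idx) < n_wild:
        raise ValueError("not enough individuals for the requested pools")
    mut_pool = rng.choice(mut_idx, size=n_mutant, replace=False)
    wild_pool = rng.choice(wild_idx, size=n_wild, replace=False)
    rows = []
    for v in variants:
        side = carrier[(v.chrom, v.pos)]
        org = pop.origin_matrix(v.chrom, v.pos)
        alt_org = 0 if side == "A" else 1
        f_mut = (org[mut_pool] == alt_org).sum() / (2 * n_mutant)
        f_wild = (org[wild_pool] == alt_org).sum() / (2 * n_wild)
        rows.append(
            {
                "chrom": v.chrom,
                "pos": v.pos,
                "ref": v.ref,
                "alt": v.alt,
                "af_mutant_pool": rng.binomial(depth, f_mut) / depth,
                "af_wild_pool": rng.binomial(depth, f_wild) / depth,
            }
        )
    return pd.DataFrame(rows)
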