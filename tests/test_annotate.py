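"""Region assignment and coding-effect classification."""

import numpy as np
import pytest

from bsamap import annotate
from bsamap.annotate import EffectAnnotation, GeneModel, ReferenceMismatchError
from bsamap.catalog import VariantRecord

from conftest import CODON_TABLE, oracle_translate

COMP = str.maketrans("ACGT", "TGCA")


def revcomp(s):
    return s.translate(COMP)[::-1]


def make_plus_gene(chrom="chr1", offset=20_000):
    """Hand-built plus-strand gene: UTR5 100 bp, CDS split over two exons by
    a 200-bp intron, UTR3 150 bp."""
    utr5 = (offset + 1, offset + 100)
    cds1 = (offset + 101, offset + 400)  # 300 bp
    intron = (offset + 401, offset + 600)
    cds2 = (offset + 601, offset + 900)  # 300 bp
    utr3 = (offset + 901, offset + 1050)
    return GeneModel(
        gene_id="g_plus",
        chrom=chrom,
        strand="+",
        tx_start=utr5[0],
        tx_end=utr3[1],
        exons=[(utr5[0], cds1[1]), (cds2[0], utr3[1])],
        cds=[cds1, cds2],
        utr5=[utr5],
        utr3=[utr3],
    )


def gene_genome(gene, cds_codons=None, length=40_000, seed=0):
    """Embed a clean CDS for ``gene`` into a random background sequence."""
    rng = np.random.default_rng(seed)
    seq = list("".join(rng.choice(list("ACGT"), size=length)))
    if cds_codons is None:
        non_stop = [c for c, aa in CODON_TABLE.items() if aa != "*"]
        n = gene.cds_length // 3 - 2
        cds_codons = "ATG" + "".join(rng.choice(non_stop, size=n)) + "TAA"
    i = 0
    coding = cds_codons if gene.strand == "+" else revcomp(cds_codons)
    for s, e in gene.cds:
        seg = coding[i : i + e - s + 1]
        seq[s - 1 : e] = list(seg)
        i += e - s + 1
    return {gene.chrom: "".join(seq)}


@pytest.fixture(scope="module")
def gene():
    return make_plus_gene()


class TestAssignRegion:
    @pytest.mark.parametrize("pos_offset,expected", [
        (150, "cds"),            # inside first CDS exon
        (401, "splice_region"),  # intron donor base 1
        (402, "splice_region"),  # intron donor base 2
        (403, "intron"),
        (599, "splice_region"),  # acceptor
        (50, "utr5"),
        (950, "utr3"),
        (0, "upstream5kb"),      # 1 bp before tx_start
        (-4999, "upstream5kb"),
        (1051 + 4999, "downstream5kb"),
        (-5001, "intergenic"),
    ])
    def test_precedence_cases(self, gene, pos_offset, expected):
        pos = 20_000 + pos_offset  # offset relative to gene start (1-based at +1)
        v = VariantRecord("chr1", pos, "A", "G", "hom")
        assert annotate.assign_region(v, [gene]).region == expected

    def test_minus_strand_upstream(self):
        """4,999 bp 5' of a minus-strand gene (i.e. beyond its tx_end) is
        upstream, not downstream."""
        g = make_plus_gene()
        g.strand = "-"
        v = VariantRecord("chr1", g.tx_end + 4_999, "A", "G", "hom")
        assert annotate.assign_region(v, [g]).region == "upstream5kb"
        v2 = VariantRecord("chr1", g.tx_start - 1_000, "A", "G", "hom")
        assert annotate.assign_region(v2, [g]).region == "downstream5kb"

    def test_nearer_gene_wins_in_overlapping_flanks(self):
        g1 = make_plus_gene(offset=20_000)
        g2 = make_plus_gene(offset=25_000)
        g2.gene_id = "g2"
        # position 1,000 bp after g1's end and ~2,950 bp before g2's start
        v = VariantRecord("chr1", g1.tx_end + 1_000, "A", "G", "hom")
        ann = annotate.assign_region(v, [g1, g2])
        assert (ann.region, ann.gene_id) == ("downstream5kb", "g_plus")

    def test_deletion_uses_first_deleted_base(self):
        g = make_plus_gene()
        # anchor base just before the transcript, first deleted base inside UTR5
        v = VariantRecord("chr1", g.tx_start - 1, "AT", "A", "hom")
        assert annotate.assign_region(v, [g]).region == "utr5"


class TestCdsEffects:
    def test_glycine_to_glutamate_missense(self):
        """A G→A at codon position 2 of GGA turns Gly into Glu."""
        gene = make_plus_gene()
        codons = "ATG" + "GGA" * 198 + "TAA"
        genome = gene_genome(gene, cds_codons=codons)
        pos = gene.cds[0][0] + 4  # codon 2, position 2
        v = VariantRecord("chr1", pos, "G", "A", "hom")
        ann = annotate.classify_cds_effect(v, gene, genome)
        assert ann.effect == "missense"
        assert ann.aa_change == ("G", 2, "E")

    def test_frameshift_and_inframe(self):
        gene = make_plus_gene()
        genome = gene_genome(gene)
        pos = gene.cds[0][0] + 10
        ref = genome["chr1"][pos - 1 : pos + 1]
        fs = annotate.classify_cds_effect(
            VariantRecord("chr1", pos, ref, ref[0], "hom"), gene, genome
        )
        assert fs.effect == "frameshift" and fs.large_effect
        ref3 = genome["chr1"][pos - 1 : pos + 3]
        inf = annotate.classify_cds_effect(
            VariantRecord("chr1", pos, ref3, ref3[0], "hom"), gene, genome
        )
        assert inf.effect == "inframe_indel" and not inf.large_effect

    def test_reference_mismatch_detected(self):
        gene = make_plus_gene()
        genome = gene_genome(gene)
        pos = gene.cds[0][0] + 3
        wrong = "C" if genome["chr1"][pos - 1] != "C" else "T"
        with pytest.raises(ReferenceMismatchError):
            annotate.classify_cds_effect(
                VariantRecord("chr1", pos, wrong, "G" if wrong != "G" else "A", "hom"),
                gene, genome,
            )

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_agrees_with_codon_oracle(self, strand):
        """200 random codons x all 9 substitutions classified identically to
        a brute-force translate-both-codons oracle."""
        rng = np.random.default_rng(42)
        gene = make_plus_gene()
        gene.strand = strand
        non_stop = [c for c, aa in CODON_TABLE.items() if aa != "*"]
        body = "".join(rng.choice(non_stop, size=198))
        codons = "ATG" + body + "TAA"
        genome = gene_genome(gene, cds_codons=codons)

        checked = 0
        for ci in range(200):
            codon = codons[3 * ci : 3 * ci + 3]
            for within in range(3):
                cds_off = 3 * ci + within
                pos = _genomic_pos(gene, cds_off)
                ref_coding = codon[within]
                for alt_coding in "ACGT".replace(ref_coding, ""):
                    ref = ref_coding if strand == "+" else revcomp(ref_coding)
                    alt = alt_coding if strand == "+" else revcomp(alt_coding)
                    v = VariantRecord(gene.chrom, pos, ref, alt, "hom")
                    got = annotate.classify_cds_effect(v, gene, genome).effect
                    mutated = codon[:within] + alt_coding + codon[within + 1 :]
                    expected = _oracle_effect(ci, codon, mutated)
                    assert got == expected, (ci, within, codon, mutated)
                    checked += 1
        assert checked == 200 * 9

    def test_strand_flip_invariance(self, small_study):
        """Reverse-complementing the genome and flipping coordinates leaves
        every coding-effect call unchanged."""
        genome = small_study["genome"]
        genes = small_study["genes"]
        variants = [
            v for v in small_study["truth"].variants
            if v.zygosity == "hom" and v.vclass == "SNP"
        ][:400]
        anns = annotate.annotate_variants(variants, genes, genome)

        L = {c: len(s) for c, s in genome.items()}
        flipped_genome = {c: revcomp(s) for c, s in genome.items()}
        flip_iv = lambda c, iv: (L[c] - iv[1] + 1, L[c] - iv[0] + 1)
        flipped_genes = [
            GeneModel(
                gene_id=g.gene_id,
                chrom=g.chrom,
                strand="-" if g.strand == "+" else "+",
                tx_start=L[g.chrom] - g.tx_end + 1,
                tx_end=L[g.chrom] - g.tx_start + 1,
                exons=[flip_iv(g.chrom, iv) for iv in g.exons],
                cds=[flip_iv(g.chrom, iv) for iv in g.cds],
                utr5=[flip_iv(g.chrom, iv) for iv in g.utr5],
                utr3=[flip_iv(g.chrom, iv) for iv in g.utr3],
            )
            for g in genes
        ]
        flipped_variants = [
            VariantRecord(v.chrom, L[v.chrom] - v.pos + 1,
                          revcomp(v.ref), revcomp(v.alt), v.zygosity)
            for v in variants
        ]
        flipped_anns = annotate.annotate_variants(
            flipped_variants, flipped_genes, flipped_genome
        )
        for a, b in zip(anns, flipped_anns):
            assert (a.region, a.effect) == (b.region, b.effect)


def _genomic_pos(gene, cds_offset):
    if gene.strand == "+":
        run = 0
        for s, e in gene.cds:
            if cds_offset < run + e - s + 1:
                return s + cds_offset - run
            run += e - s + 1
    else:
        run = 0
        for s, e in reversed(gene.cds):
            if cds_offset < run + e - s + 1:
                return e - (cds_offset - run)
            run += e - s + 1
    raise AssertionError("offset outside CDS")


def _oracle_effect(codon_index, ref_codon, alt_codon):
    ref_aa, alt_aa = CODON_TABLE[ref_codon], CODON_TABLE[alt_codon]
    if codon_index == 0 and ref_codon == "ATG" and alt_codon != "ATG":
        return "start_loss"
    if ref_aa == alt_aa:
        return "synonymous"
    if ref_aa == "*":
        return "stop_loss"
    if alt_aa == "*":
        return "stop_gain"
    return "missense"


class TestAnnotationSummary:
    def test_published_ratios(self):
        assert annotate.ns_s_ratio(15_224, 12_894) == pytest.approx(1.18, abs=0.005)
        assert annotate.proportion_pct(51_514, 97_833) == pytest.approx(52.66, abs=0.005)
        assert annotate.proportion_pct(3_418, 51_514) == pytest.approx(6.64, abs=0.005)
        assert annotate.ns_s_ratio(5, 0) is None

    def test_regions_partition(self, small_study):
        homs = [v for v in small_study["truth"].variants if v.zygosity == "hom"]
        anns = annotate.annotate_variants(homs, small_study["genes"], small_study["genome"])
        summary = annotate.annotation_summary(anns)
        assert sum(summary["region_counts"].values()) == len(homs)
        assert sum(summary["region_pct"].values()) == pytest.approx(100.0)
        genic = sum(summary["region_counts"][r] for r in annotate.GENIC_REGIONS)
        assert summary["n_genic"] == genic

    def test_large_effect_definition(self):
        anns = [
            EffectAnnotation(region="cds", effect="frameshift"),
            EffectAnnotation(region="splice_region", effect="splice_change"),
            EffectAnnotation(region="cds", effect="missense"),
        ]
        assert [a.large_effect for a in anns] == [True, True, False]
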