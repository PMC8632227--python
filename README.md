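# bsamap

Marker development and map-based cloning toolkit for forward genetics in
inbred crops.

When a recessive mutant is crossed to a genetically divergent accession,
the mutation can be located by classical positional cloning: catalogue the
DNA polymorphisms between the two parental genomes, turn large
insertions/deletions (InDels) into cheap agarose-gel PCR markers, and use an
F2 population segregating the mutant phenotype to walk from a chromosome-scale
bulked-segregant signal down to a single candidate nucleotide. `bsamap`
implements that computational workflow end to end for people building or
teaching such pipelines — and ships a synthetic-data generator so every stage
runs and is testable without any sequencing data.

## What it computes

**Variant catalogue** (`bsamap.catalog`). From a VCF of SNPs, InDels and
structural variants between two accessions: zygosity breakdown, transition/
transversion ratio Ts/Tv (transitions are A↔G and C↔T), InDel length classes
(1 bp / 2–20 bp / >20 bp), per-chromosome and per-window densities, and mean
variant spacing (10⁶ / density per Mb).

**Effect annotation** (`bsamap.annotate`). Each homozygous variant is placed
in exactly one region with precedence CDS > splice region > UTR > intron >
5-kb upstream > 5-kb downstream > intergenic, and CDS variants are classified
through the standard nuclear code as synonymous, missense, stop gain/loss,
start loss, frameshift or in-frame InDel. Frameshifts, splice-site changes,
start losses and stop gains/losses are flagged as large-effect.

**InDel marker design** (`bsamap.markers`). Homozygous InDels of 20–200 bp
with clean flanks are scored across a multi-accession genotype panel by
polymorphism information content,

    PIC = 1 − Σᵢ pᵢ² − Σᵢ<ⱼ 2 pᵢ² pⱼ²,

kept when PIC > 0.5, and equipped with PCR assays under a fixed constraint
envelope (product 200–350 bp, primer 18–29 nt, nearest-neighbor Tm 55–64 °C,
GC 35–65 %), with predicted product sizes for both parental alleles and an
exact-match in-silico PCR check.

**BSA mapping** (`bsamap.bsa`). A chi-square test of 3:1 phenotypic
segregation; a pooled-recessive bulk genotyped at genome-wide markers, with a
Bonferroni-guarded binomial test against the 50:50 null, to find the carrier
chromosome; recombinant counting at region markers over all phenotyped
recessives to delimit the interval; and BSA-seq candidate nomination — an SNP
inside the interval is nominated when it is near-fixed in the mutant pool,
segregates at an intermediate frequency in the wild pool (a recessive causal
allele sits at 1/3 among phenotypically wild F2 plants), looks EMS-induced
(G→A or C→T) and changes the protein.

**Simulation** (`bsamap.simulate`). Reference genome with multi-exon gene
models; a divergent accession with transition-biased SNPs (defaults echo a
deep two-accession resequencing comparison: ≈2720 SNPs/Mb, ≈486 InDels/Mb,
Ts/Tv ≈ 2.73, ≈48 % single-base InDels), an accession genotype panel, and an
F2 population carrying one planted recessive G→A missense mutation, with
gamete-level recombination (one obligate crossover per chromosome plus
Poisson(1) extras).

## Worked example

`bsamap all` runs the whole pipeline on a simulated study from one YAML
config:

```yaml
# small.yaml
seed: 5
n_chromosomes: 2
chrom_length: 300000
n_genes: 60
panel_size: 300
f2_size: 300
n_recessive_fine: 60
causal: {chrom: chr2, pos: 220000}
```

```text
$ bsamap all -c small.yaml -o out
bsamap pipeline summary
=======================
seed: 5
genome: 2 x 300,000 bp

variant catalogue
  SNPs: 1,637  InDels: 240  SVs: 17
  heterozygosity ratio: 18.43%
  Ts/Tv: 2.70
  densities: 2728.3 SNPs/Mb, 400.0 InDels/Mb
  mean spacing: one SNP per 367 bp, one InDel per 2500 bp

annotation (homozygous variants)
  genic: 13.72%  (intron 5.76%, cds 5.11%)
  NS/S ratio: 2.24
  large-effect variants: 15

markers
  candidates 20-200 bp: 25  PIC>0.5: 9  primary set: 10

mapping
  3:1 segregation chi2: 1.778 (consistent)
  coarse hit: ('chr2', 'In2-13')
  fine interval: chr2:187,332-274,277 (86.94 kb, 10 genes)
  top BSA-seq candidate: chr2:223265 C>T (missense; mutant pool 1.00, wild pool 0.34)
  candidate recovers planted mutation: True
```

Reading the output: the two synthetic parents differ by ~1,600 SNPs at a
transition-biased Ts/Tv of 2.70; 9 of the 25 screenable InDels are
informative enough (PIC > 0.5) across the 300-accession panel; the F2
segregates 3:1 (χ² = 1.78, n.s.); the 30-recessive bulk flags marker In2-13
on chr2; recombinant counting narrows the region to 87 kb containing 10
genes; and the pooled-resequencing scan nominates exactly one SNP — the
planted C→T (G→A on the coding strand) missense mutation at chr2:223,265,
fixed in the mutant pool and at frequency 0.34 in the wild pool.

The same stages are available individually (`bsamap simulate / catalog /
annotate / markers / bsa`) on FASTA/GFF3/VCF/TSV files, and as library
functions.

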