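# Methods

This note documents the models, conventions and design choices behind
`bsamap`, in the order the pipeline runs them.

## Synthetic study design

The generator (`bsamap.simulate`) produces a complete scaled-down forward
genetics study: two inbred parental genomes, gene models, a genotype panel of
inbred accessions, and an F2 population from (mutagenized line × divergent
accession) segregating one recessive causal mutation 3:1.

**Genome and gene models.** Chromosome sequences are i.i.d. nucleotides at a
configurable GC content (default 0.46, inside the 0.30–0.60 band typical of
grass genomes). Genes are placed non-overlapping on alternating strands, one
per evenly sized slot, each with a 60–200 bp 5′ UTR, 2–5 exons, a CDS of
240–900 bp (start ATG, one stop, no internal stop, total length divisible by
3), GT…AG introns of 80–400 bp and a 100–300 bp 3′ UTR. The default of 900
genes over 9 × 1 Mb gives one gene per ~10 kb, a plant-like gene density.

**Inter-accession variants.** SNPs arise at 2.72 × 10⁻³ per bp and InDels at
4.86 × 10⁻⁴ per bp — the genome-wide densities observed in the deep
two-accession resequencing comparison whose statistics the defaults emulate.
A SNP is a transition with probability 0.732 (Ts/Tv ≈ 2.73). InDel lengths
follow the observed class mixture (48.5 % single-base, 44.7 % 2–20 bp, 6.8 %
21–200 bp, renormalized from the published rounded percentages). Structural
variants (insertions, deletions, inversions of 100–600 bp) occur at
4 × 10⁻⁶ per bp with class weights ≈ 0.24/0.75/0.01. Events are spaced so
their reference spans never overlap. Although both parents are fully inbred,
a fraction of variant *calls* (default 0.2) is emitted heterozygous to mimic
the residual heterozygosity that short-read calling reports on inbred
material; only homozygous variants are applied to the alternate genome and
carried into annotation and marker design.

**The causal mutation.** One G→A substitution on the coding strand (C→T in
forward-strand VCF terms when the gene is on the minus strand) is planted in
the CDS of the gene nearest the requested position, at the closest coding G
whose substitution is missense. It is private to the mutagenized line — it
appears in neither the inter-accession VCF nor the divergent genome. A
background of non-causal EMS-type mutations (G→A/C→T at 5 × 10⁻⁶ per bp,
the order of magnitude of a typical EMS population) is likewise private to
the mutant parent, so the BSA-seq filters are exercised against realistic
linked decoys.

**Accession panel.** Each panel accession is inbred and carries one allele
per locus, drawn from a per-locus prior: 2/3/4 alleles with weights
0.50/0.30/0.20 and symmetric Dirichlet(1.6) frequencies. Multi-allelic loci
are essential, not decorative: under the heterozygosity-corrected PIC used
here a biallelic locus cannot exceed 0.375, so a PIC > 0.5 screen is only
passable when InDel loci segregate additional length alleles across a broad
panel — which is what a real multi-hundred-accession panel shows. Under this
prior roughly a quarter to a third of candidate markers pass the screen and
the mean PIC of the survivors is ≈ 0.58, consistent with published marker
surveys; the survivor mean is a structural consequence of truncating a
smooth PIC distribution at 0.5.

**F2 recombination.** Each gamete receives one obligate crossover per
chromosome plus a Poisson(1) extra count, at uniform positions; an F2
individual is two independent gametes, and its phenotype is mutant iff both
carry the mutant-parent haplotype at the causal position. This yields ≈ 200
cM per chromosome regardless of physical length, so on the 1 Mb scaled
chromosomes the map is ~80× hotter per bp than a real 40-Mb grass
chromosome. Relative genetics (marker informativeness, bulk skews,
recombinant fractions between markers at matched map distances) scale
correctly; absolute physical interval sizes do not, and are read
accordingly below. Populations keep their gamete structure, so new markers
can be genotyped post hoc (`F2Population.add_markers`) exactly as a stored
DNA plate would be re-genotyped with a newly designed assay.

**Pooled resequencing.** Bulk allele frequencies are the true pooled
fractions of the sampled individuals, resampled binomially at fixed read
depth. Defaults: 100 mutant + 100 wild individuals at 200× — bulk sizes and
depth at the generous end of standard BSA-seq recommendations, giving the
wild-pool frequency a standard error of ≈ 0.047 around its expectation of
1/3.

**Determinism.** Every generator draws from its own substream of
`numpy.random.default_rng([seed, stream])`; a fixed seed reproduces every
output byte-for-byte, and output headers record the seed.

## Catalogue conventions

Densities divide by the full declared chromosome lengths (no gap
exclusion). Windows are half-open `[k·w, (k+1)·w)` with the last window
truncated; window density is scaled to per-Mb of the truncated size. Mean
spacing is 10⁶/(density per Mb). InDels use the VCF anchored-base
convention, with length excluding the anchor; insertions/deletions of
≥100 bp are treated as structural variants and counted in the open-ended
length class, and inversions require the symbolic `<INV>` allele with an
`END` tag. Ts/Tv is reported as undefined (not infinite) when there are no
transversions. One caveat on the published worked example the arithmetic
reproduces: the printed transition and transversion counts sum to more than
the printed SNP total, an internal inconsistency of the source table; the
ratio is computed from the printed pair as-is, without guessing which count
is wrong.

## Annotation rules

Precedence when several categories apply: cds > splice_region > utr5/utr3 >
intron > upstream5kb > downstream5kb > intergenic, so the categories
partition the variants and percentages sum to 100. The splice region is the
first/last 2 bp of each intron (canonical donor/acceptor; configurable).
Flanks extend 5,000 bp from the transcript boundaries, strand-aware; when a
variant sits in two genes' flanks the nearer gene wins, and an exact tie
goes to upstream. An InDel is assigned by its leftmost changed base (the
first deleted base for deletions, the anchor for insertions). One transcript
per gene is assumed. CDS SNPs are classified by translating the affected
codon on the coding strand; a variant whose REF disagrees with the reference
sequence raises a reference-mismatch error rather than annotating silently.
Start loss is any change to the initiator ATG; stop gain/loss compare
ref/alt codons against the stop set; InDels are frameshifts unless their
length is a multiple of 3. NS/S is reported as undefined when no synonymous
SNP exists.

## Marker design

Candidates are homozygous InDels of 20–200 bp whose ±350 bp flanks contain
no other InDel ≥ 5 bp (a second length polymorphism inside the amplicon
would confound band-size genotyping; the cleanliness radius matches the
maximum product size). Names follow `In{chromosome}-{rank}` with rank by
position. PIC uses the heterozygosity-corrected form
`1 − Σpᵢ² − Σᵢ<ⱼ 2pᵢ²pⱼ²` (the marker-literature standard); `1 − Σpᵢ²` is
available as `method="expected_het"`. The screen keeps PIC strictly greater
than 0.5; candidates absent from the panel are dropped with a warning.

Primer design enumerates every window of 18–29 nt in the 400 bp flanks,
rejects windows overlapping any other known variant (so both parental
templates amplify), and filters on GC 35–65 %, homopolymers ≤ 4, 3′ G/C runs
≤ 3 and nearest-neighbor Tm 55–64 °C (Biopython `Tm_NN`, 50 mM monovalent
cation, 50 nM oligo — Primer3-like conditions). Pairs must give a reference
product of 200–350 bp; the best pair minimizes Σ|Tm − 59.5 °C| with ties to
the leftmost forward primer, making design deterministic. Infeasible loci
return an explicit design-failure record — real marker sets also contain
non-amplifying assays. In-silico PCR is exact substring matching in both
orientations; by construction a designed pair yields one product per
parental genome with sizes differing by exactly the InDel length.

## BSA and fine mapping

The recessive bulk's mutant-parent allele fraction at a marker is
`(2·#A + #H)/(2·n)` over the sampled individuals; bulk calls use 0.9/0.1
thresholds. The coarse scan tests each marker's allele count against
Binomial(n, 0.5) one-sided with Bonferroni correction across markers
(conservative and appropriate for a few dozen tests) and returns the most
skewed significant marker; with no significant marker it returns no call.
The primary marker set takes the best-PIC screened marker nearest each of
six bin centres per chromosome; a bin with no screened marker falls back to
the best-PIC unscreened candidate, because even genome coverage — the point
of a primary panel — outranks panel-wide informativeness on a compressed
genome where the screened set can leave a chromosome arm empty.

The candidate window is bracketed by the coarse hit's neighbouring primary
markers (or the chromosome end), and eight region markers are taken at grid
points spanning it edge to edge. Fine mapping counts, per marker, the
recessive individuals not homozygous for the mutant-parent allele. The
interval runs between the nearest flanking markers (with ≥1 recombinant) of
the zero-recombinant core; when no marker is recombinant-free — the usual
case here, since on the hot scaled map a zero-recombinant marker among 237
recessives must lie within ~1 kb of the causal site — the widest bracket is
returned with a warning, which with edge-to-edge grid markers equals the
candidate window. The acceptance property is therefore containment of the
causal variant, not interval width; typical intervals span a few hundred kb
of the scaled genome and list tens of candidate genes.

BSA-seq nomination inside the interval requires mutant-pool frequency
≥ 0.9, wild-pool frequency in [0.2, 0.45] (centred on the 1/3 expectation
for a recessive causal allele among phenotypically wild F2 plants),
an EMS-type substitution (G→A or C→T), and a protein-changing effect
(missense or any large-effect class). All thresholds are configurable
(`BsaSeqThresholds`). Candidates sort by descending mutant-pool frequency
with position as tie-break. Divergent-accession variants near the causal
locus fail the mutant-pool filter (the mutant bulk is homozygous for the
mutagenized-line haplotype there), and linked background EMS mutations are
mostly removed by the effect and wild-pool filters.

## Degenerate inputs and numerical choices

Empty variant lists, zero transversions, zero synonymous SNPs and empty
marker tables are reported as explicit undefined/empty results, never as
infinities or silent omissions. Bulk sizes are clamped to the available
individuals (with a log line) so small simulated studies run unchanged.
Frequency vectors must sum to 1 within 10⁻⁹; PIC brute-force equality is
tested to 10⁻¹². The 3:1 test uses Pearson's chi-square with df = 1 and an
α = 0.05 consistency flag.

## Problem sizes used in the tests

Unit and property tests run on a shared 2 × 300 kb study (60 genes, ~1,900
variants); the end-to-end recovery suite and the acceptance script use the
full study scale — 9 chromosomes, 982 F2 individuals, a 30-recessive bulk
over the genome-wide primary set, 237 recessives over 8 region markers —
across 50 independent seeds, with the genome scaled to 9 × 1 Mb so the
whole sweep completes in about a minute on one CPU.

## Known limitations

The generator does not simulate reads, sequencing error, alignment or
variant-calling artifacts beyond the flat heterozygous-call fraction; panel
accessions carry no linkage disequilibrium or population structure; genes
have a single transcript and no nested or overlapping loci; the uniform
recombination model has no interference, centromere suppression or map/
physical calibration. Passing tests therefore demonstrate correctness of
the statistics and of the mapping logic under clean Mendelian segregation,
not robustness to misgenotyping, phenotyping error or segregation
distortion — all of which real F2 data can contain. Physical interval sizes
from the scaled simulations should not be compared directly with real
studies; map-distance-relative quantities should.
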