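"""Bulked segregant analysis and recombinant fine mapping of a recessive locus.

The workflow mirrors classical map-based cloning of a recessive mutant in an
F2 cross: a chi-square test of 3:1 phenotypic segregation, a pooled-recessive
bulk genotyped at genome-wide markers to find the carrier chromosome (coarse
BSA), recombinant counting at region markers over all phenotyped recessives
(fine mapping), and nomination of the causal SNP inside the fine interval
from pooled-resequencing allele frequencies (BSA-seq).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotate import EffectAnnotation, GeneModel
from .catalog import VariantRecord
from .simulate import F2Population


@dataclass
class PoolResult:
    marker_id: str
    pool_call: str  # "A-like" | "B-like" | "H-like"
    a_allele_fraction: float
    n_a_alleles: int
    n_alleles: int


@dataclass
class MappingInterval:
    chrom: str
    left_marker: str
    right_marker: str
    left_pos: int
    right_pos: int
    candidate_gene_ids: list[str] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.right_pos - self.left_pos

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.left_pos <= pos <= self.right_pos


@dataclass
class SegregationTest:
    n_dominant: int
    n_recessive: int
    expected_ratio: tuple[float, float]
    chi2: float
    df: int
    p_value: float

    @property
    def consistent(self) -> bool:
        """Observed counts compatible with the expected ratio at alpha=0.05."""
        return self.p_value >= 0.05


@dataclass
class BsaSeqCandidate:
    chrom: str
    pos: int
    ref: str
    alt: str
    mutant_pool_alt_freq: float
    wild_pool_alt_freq: float
    is_ems_type: bool
    effect: EffectAnnotation


@dataclass(frozen=True)
class BsaSeqThresholds:
    """Nomination filter for BSA-seq candidate SNPs.

    A candidate must be near-fixed in the mutant pool, segregate at an
    intermediate frequency in the wild pool (a recessive causal allele sits
    at 1/3 among phenotypically wild F2 plants), look EMS-induced (G→A or
    C→T), and change the protein.
    """

    mutant_min_freq: float = 0.9
    wild_freq_range: tuple[float, float] = (0.2, 0.45)
    require_ems_type: bool = True
    effects: frozenset = frozenset(
        {"missense", "frameshift", "splice_change", "start_loss", "stop_gain", "stop_loss"}
    )


def is_ems_type(ref: str, alt: str) -> bool:
    """EMS alkylation produces G→A transitions (C→T on the other strand)."""
    return (ref, alt) in (("G", "A"), ("C", "T"))


def pool_recessives(
    pop: F2Population, n_pool: int, marker_id: str, seed: int | np.random.Generator = 0
) -> PoolResult:
    """Genotype a bulk of ``n_pool`` recessive individuals at one marker.

    The bulk's mutant-parent (A) allele fraction is computed by allele
    counting over the sampled individuals: ``(2·#A + #H) / (2·n_pool)``.
    Calls: A-like at fraction >= 0.9, B-like at <= 0.1, H-like otherwise.
    """
    if n_pool <= 0:
        raise ValueError("n_pool must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rec = pop.recessives
    if len(rec) < n_pool:
        raise ValueError(f"only {len(rec)} recessive individuals, need {n_pool}")
    sample = rng.choice(len(rec), size=n_pool, replace=False)
    genos = pop.genotypes.loc[[rec[i] for i in sample], marker_id]
    n_a = 2 * int((genos == "A").sum()) + int((genos == "H").sum())
    n_total = 2 * int((genos != "missing").sum())
    if n_total == 0:
        raise ValueError(f"all genotypes missing at {marker_id}")
    frac = n_a / n_total
    call = "A-like" if frac >= 0.9 else ("B-like" if frac <= 0.1 else "H-like")
    return PoolResult(marker_id, call, frac, n_a, n_total)


def coarse_map(
    pool_results: Sequence[PoolResult],
    marker_positions: Mapping[str, tuple[str, int]],
    alpha: float = 0.05,
) -> tuple[str, str] | None:
    """Locate the carrier chromosome from genome-wide bulk genotypes.

    Under no linkage a recessive bulk draws parental alleles 50:50, so each
    marker's A-allele count is tested against Binomial(n, 0.5) (one-sided),
    Bonferroni-corrected across markers. Returns ``(chrom, marker_id)`` of
    the marker with the highest A-allele fraction, or ``None`` when no
    marker is significant. The result does not depend on input order.
    """
    results = sorted(pool_results, key=lambda r: r.marker_id)
    if not results:
        raise ValueError("no pool results")
    cutoff = alpha / len(results)
    best = None
    for r in results:
        p = stats.binomtest(r.n_a_alleles, r.n_alleles, 0.5, alternative="greater").pvalue
        if p <= cutoff:
            key = (-r.a_allele_fraction, r.marker_id)
            if best is None or key < best[0]:
                best = (key, r)
    if best is None:
        return None
    chrom = marker_positions[best[1].marker_id][0]
    return chrom, best[1].marker_id


def recombinant_counts(
    recessives: F2Population, marker_ids: Sequence[str]
) -> pd.Series:
    """Recombinant count per marker among phenotyped recessives.

    A recessive individual is recombinant at a marker when it is not
    homozygous for the mutant-parent allele there; missing genotypes do not
    count as recombinants.
    """
    counts = {}
    for mid in marker_ids:
        g = recessives.genotypes[mid]
        counts[mid] = int(((g == "B") | (g == "H")).sum())
    return pd.Series(counts)


def fine_map(
    recessives: F2Population,
    region_markers: Sequence[str],
    genes: Sequence[GeneModel] | None = None,
) -> MappingInterval:
    """Delimit the causal interval by recombinant counting.

    ``region_markers`` must be ordered by position on one chromosome and the
    population restricted to recessive individuals. The interval runs
    between the nearest markers flanking the zero-recombinant core that show
    at least one recombinant. When no marker is recombinant-free the widest
    bracket (first to last marker) is returned with a warning.
    """
    if any(recessives.phenotype != "mutant"):
        raise ValueError("fine mapping expects a recessive-only population")
    pos = [recessives.marker_pos[m] for m in region_markers]
    chroms = {c for c, _ in pos}
    if len(chroms) != 1:
        raise ValueError("region markers must lie on a single chromosome")
    chrom = chroms.pop()
    order = [p for _, p in pos]
    if order != sorted(order):
        raise ValueError("region markers must be sorted by position")
    rec = recombinant_counts(recessives, region_markers)
    zero = [i for i, m in enumerate(region_markers) if rec[m] == 0]
    if not zero:
        warnings.warn("no zero-recombinant marker; returning the widest bracket")
        left_i, right_i = 0, len(region_markers) - 1
    else:
        left_i = max((i for i in range(zero[0]) if rec[region_markers[i]] > 0), default=0)
        right_i = min(
            (i for i in range(zero[-1] + 1, len(region_markers)) if rec[region_markers[i]] > 0),
            default=len(region_markers) - 1,
        )
    interval = MappingInterval(
        chrom=chrom,
        left_marker=region_markers[left_i],
        right_marker=region_markers[right_i],
        left_pos=order[left_i],
        right_pos=order[right_i],
    )
    if genes is not None:
        interval.candidate_gene_ids = [
            g.gene_id
            for g in genes
            if g.chrom == chrom and g.tx_end >= interval.left_pos and g.tx_start <= interval.right_pos
        ]
    return interval


def segregation_chisq(
    n_dominant: int, n_recessive: int, ratio: tuple[float, float] = (3.0, 1.0)
) -> SegregationTest:
    """Chi-square goodness-of-fit of phenotype counts to a Mendelian ratio."""
    if n_dominant < 0 or n_recessive < 0 or n_dominant + n_recessive == 0:
        raise ValueError("counts must be non-negative and not both zero")
    total = n_dominant + n_recessive
    w = ratio[0] + ratio[1]
    expected = [total * ratio[0] / w, total * ratio[1] / w]
    chi2, p = stats.chisquare([n_dominant, n_recessive], f_exp=expected)
    return SegregationTest(
        n_dominant=n_dominant,
        n_recessive=n_recessive,
        expected_ratio=ratio,
        chi2=float(chi2),
        df=1,
        p_value=float(p),
    )


def bsa_seq_scan(
    pool_freqs: pd.DataFrame,
    interval: MappingInterval,
    annotations: Mapping[tuple[str, int], EffectAnnotation],
    thresholds: BsaSeqThresholds = BsaSeqThresholds(),
) -> list[BsaSeqCandidate]:
    """Nominate causal-SNP candidates inside the fine-mapping interval.

    ``pool_freqs`` needs columns chrom, pos, ref, alt, af_mutant_pool,
    af_wild_pool. Candidates passing every filter are returned sorted by
    descending mutant-pool frequency (ties toward position).
    """
    inside = pool_freqs[
        (pool_freqs["chrom"] == interval.chrom)
        & (pool_freqs["pos"] >= interval.left_pos)
        & (pool_freqs["pos"] <= interval.right_pos)
    ]
    if inside.empty:
        warnings.warn("no pool-frequency records inside the interval")
        return []
    out = []
    lo, hi = thresholds.wild_freq_range
    for row in inside.itertuples(index=False):
        ems = is_ems_type(row.ref, row.alt)
        if row.af_mutant_pool < thresholds.mutant_min_freq:
            continue
        if not (lo <= row.af_wild_pool <= hi):
            continue
        if thresholds.require_ems_type and not ems:
            continue
        ann = annotations.get((row.chrom, row.pos))
        if ann is None or ann.effect not in thresholds.effects:
            continue
        out.append(
            BsaSeqCandidate(
                chrom=row.chrom,
                pos=row.pos,
                ref=row.ref,
                alt=row.alt,
                mutant_pool_alt_freq=row.af_mutant_pool,
                wild_pool_alt_freq=row.af_wild_pool,
                is_ems_type=ems,
                effect=ann,
            )
        )
    out.sort(key=lambda c: (-c.mutant_pool_alt_freq, c.pos))
    return out
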