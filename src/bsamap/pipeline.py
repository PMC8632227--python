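"""End-to-end positional-cloning pipeline on simulated data.

Chains the stages into one reproducible run: simulate the two parental
genomes and the F2 cross, design and screen InDel markers, locate the
carrier chromosome with a recessive bulk, delimit the interval by
recombinant fine mapping, and nominate the causal SNP from pooled
resequencing. Used by the command-line interface and by the validation
scripts; every step is also callable on its own.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import annotate, bsa, catalog, markers, simulate

log = logging.getLogger("bsamap")


@dataclass
class CloningResult:
    config: simulate.SimConfig
    truth: simulate.SimTruth
    n_candidates: int
    n_screened: int
    coarse_markers: list[markers.MarkerCandidate]
    region_marker_ids: list[str]
    segregation: bsa.SegregationTest
    coarse_hit: tuple[str, str] | None
    interval: bsa.MappingInterval | None
    candidates: list[bsa.BsaSeqCandidate] = field(default_factory=list)

    @property
    def interval_contains_causal(self) -> bool:
        cv = self.truth.causal_variant
        return bool(self.interval and cv and self.interval.contains(cv.chrom, cv.pos))

    @property
    def top_candidate_is_causal(self) -> bool:
        cv = self.truth.causal_variant
        return bool(
            self.candidates
            and cv
            and self.candidates[0].chrom == cv.chrom
            and self.candidates[0].pos == cv.pos
        )


def select_coarse_markers(
    screened: list[markers.MarkerCandidate],
    all_candidates: list[markers.MarkerCandidate],
    chrom_lengths: dict[str, int],
    per_chrom: int = 6,
) -> list[markers.MarkerCandidate]:
    """Pick an evenly spaced genome-wide primary-mapping marker set.

    Each chromosome is cut into ``per_chrom`` bins and the highest-PIC
    screened marker nearest each bin centre is taken from within the bin.
    Even genome coverage is the point of a primary-mapping panel, so a bin
    that holds no screened marker falls back to the best-PIC unscreened
    candidate in the bin (every candidate is polymorphic between the two
    mapping parents regardless of its panel-wide PIC); a bin with no
    candidate at all is skipped.
    """
    out = []
    screened_ids = {m.marker_id for m in screened}
    for chrom, length in chrom_lengths.items():
        scr = [m for m in screened if m.chrom == chrom]
        cand = [m for m in all_candidates if m.chrom == chrom]
        chosen: dict[str, markers.MarkerCandidate] = {}
        for k in range(per_chrom):
            lo, hi = k * length / per_chrom, (k + 1) * length / per_chrom
            centre = (lo + hi) / 2
            in_bin = [m for m in scr if lo <= m.pos < hi]
            if not in_bin:
                in_bin = [m for m in cand if lo <= m.pos < hi]
            if not in_bin:
                continue
            best = min(in_bin, key=lambda m: abs(m.pos - centre))
            chosen[best.marker_id] = best
        out.extend(sorted(chosen.values(), key=lambda m: m.pos))
    return out


def candidate_window(
    coarse_set: list[markers.MarkerCandidate],
    best_marker_id: str,
    chrom_lengths: dict[str, int],
) -> tuple[str, int, int]:
    """Candidate region implied by a coarse BSA hit.

    The causal locus lies between the primary markers adjacent to the most
    skewed one, so the window runs from the preceding to the following
    coarse marker on the same chromosome (extended to the chromosome end
    when the hit is terminal).
    """
    best = next(m for m in coarse_set if m.marker_id == best_marker_id)
    on_chrom = sorted(
        (m for m in coarse_set if m.chrom == best.chrom), key=lambda m: m.pos
    )
    i = [m.marker_id for m in on_chrom].index(best_marker_id)
    lo = on_chrom[i - 1].pos if i > 0 else 1
    hi = on_chrom[i + 1].pos if i + 1 < len(on_chrom) else chrom_lengths[best.chrom]
    return best.chrom, lo, hi


def select_region_markers(
    variants: list[catalog.VariantRecord],
    chrom: str,
    window: tuple[int, int],
    n_markers: int = 8,
) -> list[markers.MarkerCandidate]:
    """Develop fine-mapping markers across a candidate window.

    Takes the homozygous variant nearest each of ``n_markers`` grid points
    spanning the window edge to edge (so the outermost markers bracket the
    whole candidate region), ordered by position — the scaled-down analogue
    of developing new InDel/SNP markers inside the region a coarse BSA scan
    points to.
    """
    lo, hi = window
    homs = [
        v
        for v in variants
        if v.chrom == chrom and v.zygosity == "hom" and not v.is_sv
    ]
    if not homs:
        return []
    picked: dict[int, catalog.VariantRecord] = {}
    for k in range(n_markers):
        target = lo + k * (hi - lo) / max(1, n_markers - 1)
        v = min(homs, key=lambda v: abs(v.pos - target))
        picked[v.pos] = v
    ordered = [picked[p] for p in sorted(picked)]
    return [markers.MarkerCandidate(f"fm{i + 1}", v) for i, v in enumerate(ordered)]


def run_positional_cloning(
    config: simulate.SimConfig,
    n_pool: int = 30,
    coarse_per_chrom: int = 6,
    n_region_markers: int = 8,
    n_recessive_fine: int = 237,
    pic_threshold: float = 0.5,
    n_mutant_pool: int = 100,
    n_wild_pool: int = 100,
    pool_depth: int = 200,
    thresholds: bsa.BsaSeqThresholds = bsa.BsaSeqThresholds(),
) -> CloningResult:
    """Run the whole map-based cloning workflow on one simulated study.

    Defaults follow the study design the package models: a 982-individual
    F2, a 30-recessive bulk over ~54 genome-wide InDel markers (six per
    chromosome), fine mapping of 237 recessives over 8 region markers, and
    BSA-seq pools resequenced at a fixed depth.
    """
    genome, genes = simulate.generate_reference(config)
    log.info("reference: %d chromosomes, %d genes", config.n_chromosomes, len(genes))
    _, variants, truth = simulate.mutate_accession(genome, genes, config)
    log.info("variants: %d between the accessions", len(variants))

    candidates = markers.select_candidates(variants)
    panel = simulate.generate_panel([c.variant for c in candidates], config)
    screened = markers.screen_by_pic(candidates, panel, threshold=pic_threshold)
    log.info(
        "markers: %d candidates in, %d pass PIC > %.2f (%d rejected)",
        len(candidates), len(screened), pic_threshold, len(candidates) - len(screened),
    )
    coarse_set = select_coarse_markers(
        screened, candidates, truth.chrom_lengths, coarse_per_chrom
    )

    cv = truth.causal_variant
    if cv is None:
        raise ValueError("study config has no causal mutation to map")
    pop = simulate.generate_f2(truth, coarse_set, config)

    n_rec = len(pop.recessives)
    seg = bsa.segregation_chisq(len(pop) - n_rec, n_rec)
    log.info("F2: %d individuals, %d recessives, chi2(3:1)=%.3f", len(pop), n_rec, seg.chi2)

    pool_seed = np.random.default_rng([config.seed, 29]).integers(2**31)
    pools = [
        bsa.pool_recessives(pop, n_pool, m.marker_id, seed=int(pool_seed))
        for m in coarse_set
    ]
    coarse_hit = bsa.coarse_map(pools, {m.marker_id: (m.chrom, m.pos) for m in coarse_set})
    log.info("coarse BSA: %s", coarse_hit)

    interval = None
    region_set: list[markers.MarkerCandidate] = []
    scan: list[bsa.BsaSeqCandidate] = []
    if coarse_hit is not None:
        chrom, lo, hi = candidate_window(coarse_set, coarse_hit[1], truth.chrom_lengths)
        log.info("candidate window: %s:%d-%d", chrom, lo, hi)
        region_set = select_region_markers(variants, chrom, (lo, hi), n_region_markers)
        pop.add_markers(region_set)
        rec_ids = pop.recessives[:n_recessive_fine]
        recessives = pop.subset(rec_ids)
        region_ids = [m.marker_id for m in region_set]
        interval = bsa.fine_map(recessives, region_ids, genes=genes)
        log.info(
            "fine interval: %s:%d-%d (%.2f kb, %d genes)",
            interval.chrom, interval.left_pos, interval.right_pos,
            interval.length / 1000, len(interval.candidate_gene_ids),
        )
        n_mut = min(n_mutant_pool, n_rec)
        n_wild = min(n_wild_pool, len(pop) - n_rec)
        if (n_mut, n_wild) != (n_mutant_pool, n_wild_pool):
            log.info("BSA-seq pools clamped to %d mutant / %d wild", n_mut, n_wild)
        scan = _scan_interval(
            pop, truth, interval, genes, genome, config,
            n_mut, n_wild, pool_depth, thresholds,
        )
        log.info("BSA-seq: %d candidate SNPs nominated", len(scan))

    return CloningResult(
        config=config,
        truth=truth,
        n_candidates=len(candidates),
        n_screened=len(screened),
        coarse_markers=coarse_set,
        region_marker_ids=[m.marker_id for m in region_set],
        segregation=seg,
        coarse_hit=coarse_hit,
        interval=interval,
        candidates=scan,
    )


def _scan_interval(
    pop, truth, interval, genes, genome, config,
    n_mutant_pool, n_wild_pool, pool_depth, thresholds,
):
    """Pool-resequencing scan of every variant segregating in the interval."""
    in_iv = lambda v: interval.contains(v.chrom, v.pos)
    background = [v for v in truth.variants if v.zygosity == "hom" and in_iv(v) and not v.is_sv]
    private = [v for v in truth.ems_variants if in_iv(v)]
    cv = truth.causal_variant
    scan_vars = background + private + ([cv] if cv and in_iv(cv) else [])
    if not scan_vars:
        return []
    carrier = {(v.chrom, v.pos): "B" for v in background}
    carrier.update({(v.chrom, v.pos): "A" for v in private})
    if cv:
        carrier[(cv.chrom, cv.pos)] = "A"
    freqs = simulate.simulate_pool_freqs(
        pop, scan_vars, carrier, config,
        n_mutant=n_mutant_pool, n_wild=n_wild_pool, depth=pool_depth,
    )
    anns = annotate.annotate_variants(scan_vars, genes, genome)
    ann_map = {(v.chrom, v.pos): a for v, a in zip(scan_vars, anns)}
    return bsa.bsa_seq_scan(freqs, interval, ann_map, thresholds)


def recovery_rates(
    base_seed: int, n_runs: int = 50, config_kwargs: dict | None = None, **run_kwargs
) -> pd.DataFrame:
    """Repeat the full cloning workflow over seeded runs.

    Returns one row per run with the interval-containment and top-candidate
    outcomes, for measuring recovery rates of the planted mutation.
    """
    rows = []
    for i in range(n_runs):
        cfg = simulate.SimConfig(seed=base_seed + i, **(config_kwargs or {}))
        res = run_positional_cloning(cfg, **run_kwargs)
        rows.append(
            {
                "seed": cfg.seed,
                "n_screened": res.n_screened,
                "coarse_chrom": res.coarse_hit[0] if res.coarse_hit else "",
                "interval_kb": res.interval.length / 1000 if res.interval else np.nan,
                "contains_causal": res.interval_contains_causal,
                "top_is_causal": res.top_candidate_is_causal,
            }
        )
    return pd.DataFrame(rows)
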