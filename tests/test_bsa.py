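"""Bulked segregant analysis, fine mapping and BSA-seq nomination."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from bsamap import bsa, simulate
from bsamap.annotate import EffectAnnotation
from bsamap.bsa import BsaSeqThresholds, MappingInterval
from bsamap.simulate import SimConfig

from conftest import make_light_truth

LENGTHS = {f"chr{i + 1}": 1_000_000 for i in range(9)}
CAUSAL = ("chr5", 770_000)


def grid_markers(per_chrom=6):
    out = []
    for chrom, L in LENGTHS.items():
        for k in range(per_chrom):
            out.append((f"In{chrom[3:]}-{k + 1}", chrom, int((k + 0.5) * L / per_chrom)))
    return out


def make_pop(seed, f2_size=982, markers=None):
    truth = make_light_truth(LENGTHS, *CAUSAL)
    cfg = SimConfig(seed=seed, n_chromosomes=9, chrom_length=1_000_000,
                    f2_size=f2_size, causal=None)
    return simulate.generate_f2(truth, markers or grid_markers(), cfg)


class TestPoolRecessives:
    def test_fully_linked_marker_fraction_one(self):
        pop = make_pop(seed=1, markers=grid_markers() + [("m_causal", *CAUSAL)])
        res = bsa.pool_recessives(pop, 30, "m_causal", seed=0)
        assert res.a_allele_fraction == 1.0
        assert res.pool_call == "A-like"

    def test_zero_pool_rejected(self):
        pop = make_pop(seed=1)
        with pytest.raises(ValueError):
            bsa.pool_recessives(pop, 0, "In1-1")

    def test_unlinked_marker_fraction_band(self):
        """At an unlinked marker a 30-recessive bulk stays near 0.5: inside
        [0.32, 0.68] in at least 95% of seeds (binomial, 60 alleles)."""
        inside = 0
        n_seeds = 200
        for seed in range(n_seeds):
            pop = make_pop(seed=seed, f2_size=200)
            res = bsa.pool_recessives(pop, 30, "In1-3", seed=seed)
            inside += 0.32 <= res.a_allele_fraction <= 0.68
        assert inside >= 0.95 * n_seeds - 5


class TestCoarseMap:
    def _pools(self, pop, seed=0):
        return [bsa.pool_recessives(pop, 30, m, seed=seed)
                for m in pop.genotypes.columns]

    def test_single_linked_marker_wins(self):
        pop = make_pop(seed=3, markers=grid_markers() + [("m_causal", *CAUSAL)])
        hit = bsa.coarse_map(self._pools(pop),
                             {m: (c, p) for m, c, p in grid_markers() + [("m_causal", *CAUSAL)]})
        assert hit == ("chr5", "m_causal")

    def test_input_order_invariance(self):
        pop = make_pop(seed=4)
        pools = self._pools(pop)
        positions = {m: (c, p) for m, c, p in grid_markers()}
        hit_fwd = bsa.coarse_map(pools, positions)
        hit_rev = bsa.coarse_map(list(reversed(pools)), positions)
        assert hit_fwd == hit_rev

    def test_nearest_marker_wins_across_seeds(self):
        """The marker nearest the causal locus has the strongest bulk skew
        in at least 95% of seeds."""
        nearest = min(grid_markers(), key=lambda m: abs(m[2] - CAUSAL[1])
                      if m[1] == CAUSAL[0] else 10**9)[0]
        wins = 0
        n_seeds = 50
        for seed in range(n_seeds):
            pop = make_pop(seed=1000 + seed)
            hit = bsa.coarse_map(self._pools(pop, seed=seed),
                                 {m: (c, p) for m, c, p in grid_markers()})
            wins += hit is not None and hit[1] == nearest
        assert wins >= 0.95 * n_seeds - 1

    def test_permuted_phenotypes_give_no_call(self):
        """With phenotype labels shuffled there is no linkage anywhere, so
        the Bonferroni-guarded scan stays silent in ≥90% of seeds."""
        silent = 0
        n_seeds = 50
        for seed in range(n_seeds):
            pop = make_pop(seed=2000 + seed, f2_size=400)
            rng = np.random.default_rng(seed)
            perm = rng.permutation(pop.phenotype.to_numpy())
            pop.phenotype = pd.Series(perm, index=pop.ids, name="phenotype")
            hit = bsa.coarse_map(self._pools(pop, seed=seed),
                                 {m: (c, p) for m, c, p in grid_markers()})
            silent += hit is None
        assert silent >= 0.90 * n_seeds - 1


class TestFineMap:
    def region(self, offsets):
        return [(f"fm{i + 1}", CAUSAL[0], CAUSAL[1] + off)
                for i, off in enumerate(sorted(offsets))]

    def test_marker_at_causal_has_zero_recombinants(self):
        region = self.region([-40_000, -15_000, 0, 15_000, 40_000])
        pop = make_pop(seed=6, markers=grid_markers() + region)
        rec = pop.subset(pop.recessives)
        counts = bsa.recombinant_counts(rec, [m for m, _, _ in region])
        assert counts["fm3"] == 0

    def test_interval_brackets_causal(self):
        region = self.region([-40_000, -15_000, 0, 15_000, 40_000])
        pop = make_pop(seed=6, markers=grid_markers() + region)
        rec = pop.subset(pop.recessives[:237])
        iv = bsa.fine_map(rec, [m for m, _, _ in region])
        assert iv.contains(*CAUSAL)
        assert iv.left_pos >= CAUSAL[1] - 40_000
        assert iv.right_pos <= CAUSAL[1] + 40_000

    def test_recombinants_increase_with_distance(self):
        """Spearman correlation of recombinant count vs distance to the
        causal locus is positive across seeds."""
        offsets = [-120_000, -60_000, -30_000, -10_000, 10_000, 30_000, 60_000, 120_000]
        region = self.region(offsets)
        rhos = []
        for seed in (7, 8, 9, 10, 11):
            pop = make_pop(seed=seed, markers=grid_markers() + region)
            rec = pop.subset(pop.recessives)
            counts = bsa.recombinant_counts(rec, [m for m, _, _ in region])
            dist = [abs(off) for off in sorted(offsets)]
            rho, _ = stats.spearmanr(dist, counts.to_numpy())
            rhos.append(rho)
        assert all(r > 0 for r in rhos)

    def test_fallback_warns_without_zero_recombinant_core(self):
        region = self.region([-200_000, -100_000, 100_000, 200_000])
        pop = make_pop(seed=12, markers=grid_markers() + region)
        rec = pop.subset(pop.recessives)
        with pytest.warns(UserWarning, match="widest bracket"):
            iv = bsa.fine_map(rec, [m for m, _, _ in region])
        assert (iv.left_pos, iv.right_pos) == (CAUSAL[1] - 200_000, CAUSAL[1] + 200_000)

    def test_added_inner_marker_never_widens_interval(self):
        base = [-40_000, -15_000, 0, 15_000, 40_000]
        extra = base + [5_000]
        pop = make_pop(seed=13, markers=grid_markers() + self.region(extra))
        rec = pop.subset(pop.recessives)
        ids = lambda offs: [f"fm{sorted(extra).index(o) + 1}" for o in sorted(offs)]
        iv_base = bsa.fine_map(rec, ids(base))
        iv_more = bsa.fine_map(rec, ids(extra))
        assert iv_more.left_pos >= iv_base.left_pos
        assert iv_more.right_pos <= iv_base.right_pos

    def test_rejects_non_recessive_input(self):
        region = self.region([-10_000, 0, 10_000])
        pop = make_pop(seed=14, markers=grid_markers() + region)
        with pytest.raises(ValueError, match="recessive-only"):
            bsa.fine_map(pop, [m for m, _, _ in region])


class TestSegregation:
    def test_exact_ratio_gives_zero(self):
        assert bsa.segregation_chisq(750, 250).chi2 == pytest.approx(0.0)

    def test_published_counts(self):
        t = bsa.segregation_chisq(745, 237)
        assert t.chi2 == pytest.approx(0.392, abs=0.005)
        assert t.df == 1
        assert t.consistent  # not significant at alpha = 0.05

    def test_all_dominant_flagged(self):
        t = bsa.segregation_chisq(982, 0)
        assert t.chi2 == pytest.approx(982 / 3, rel=1e-6)
        assert not t.consistent

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            bsa.segregation_chisq(0, 0)


class TestBsaSeqScan:
    INTERVAL = MappingInterval("chr5", "fmL", "fmR", 750_000, 790_000)

    def _table(self, rows):
        return pd.DataFrame(
            rows, columns=["chrom", "pos", "ref", "alt", "af_mutant_pool", "af_wild_pool"]
        )

    def test_planted_causal_nominated(self):
        table = self._table([("chr5", 770_000, "G", "A", 1.0, 0.33)])
        anns = {("chr5", 770_000): EffectAnnotation(region="cds", effect="missense")}
        out = bsa.bsa_seq_scan(table, self.INTERVAL, anns)
        assert len(out) == 1 and out[0].is_ems_type

    def test_non_ems_substitution_rejected(self):
        table = self._table([("chr5", 770_000, "A", "C", 1.0, 0.33)])
        anns = {("chr5", 770_000): EffectAnnotation(region="cds", effect="missense")}
        assert bsa.bsa_seq_scan(table, self.INTERVAL, anns) == []

    def test_outside_interval_ignored_and_empty_warns(self):
        table = self._table([("chr5", 700_000, "G", "A", 1.0, 0.33)])
        with pytest.warns(UserWarning, match="inside the interval"):
            assert bsa.bsa_seq_scan(table, self.INTERVAL, {}) == []

    def test_background_snps_filtered_in_simulation(self):
        """Four-pool simulation with 50 background SNPs in the interval:
        only the causal SNP survives the filters in ≥90% of seeds."""
        rng = np.random.default_rng(0)
        positions = sorted(rng.choice(np.arange(750_001, 790_000), 50, replace=False))
        background = [
            simulate.VariantRecord("chr5", int(p), "G", "A", "hom") for p in positions
        ]
        causal = simulate.VariantRecord("chr5", 770_000, "G", "A", "hom")
        carrier = {(v.chrom, v.pos): "B" for v in background}
        carrier[("chr5", 770_000)] = "A"
        anns = {
            (v.chrom, v.pos): EffectAnnotation(region="cds", effect="missense")
            for v in background + [causal]
        }
        exact = 0
        n_seeds = 50
        for seed in range(n_seeds):
            cfg = SimConfig(seed=3000 + seed, n_chromosomes=9,
                            chrom_length=1_000_000, f2_size=982, causal=None)
            truth = make_light_truth(LENGTHS, *CAUSAL)
            pop = simulate.generate_f2(truth, grid_markers(), cfg)
            freqs = simulate.simulate_pool_freqs(
                pop, background + [causal], carrier, cfg,
                n_mutant=100, n_wild=100, depth=200,
            )
            out = bsa.bsa_seq_scan(freqs, self.INTERVAL, anns)
            exact += len(out) == 1 and out[0].pos == 770_000
        assert exact >= 0.90 * n_seeds - 1
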