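"""Shared fixtures: one small simulated study reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from bsamap import markers, simulate


@pytest.fixture(scope="session")
def small_config() -> simulate.SimConfig:
    return simulate.SimConfig(
        seed=5,
        n_chromosomes=2,
        chrom_length=300_000,
        n_genes=60,
        panel_size=300,
        f2_size=400,
        causal=simulate.CausalSpec("chr2", 220_000),
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    """Reference + divergent genome, gene models, variants and truth."""
    genome, genes = simulate.generate_reference(small_config)
    alt_genome, variants, truth = simulate.mutate_accession(genome, genes, small_config)
    return {
        "config": small_config,
        "genome": genome,
        "genes": genes,
        "alt_genome": alt_genome,
        "variants": variants,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def small_candidates(small_study):
    return markers.select_candidates(small_study["variants"])


def make_light_truth(
    chrom_lengths: dict[str, int], causal_chrom: str, causal_pos: int
) -> simulate.SimTruth:
    """Minimal truth object for F2/BSA tests that need no genome."""
    causal = simulate.VariantRecord(causal_chrom, causal_pos, "G", "A", "hom")
    return simulate.SimTruth(
        variants=[],
        region_labels={},
        causal_variant=causal,
        causal_gene_id="gene_x",
        ems_variants=[],
        chrom_lengths=chrom_lengths,
    )


CODON_TABLE = {
    # independent standard-code lookup used as the translation oracle;
    # written out by hand, not derived from the implementation
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def oracle_translate(cds: str) -> str:
    return "".join(CODON_TABLE[cds[i : i + 3]] for i in range(0, len(cds), 3))
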