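"""Catalogue statistics for variants segregating between two inbred accessions.

Given a VCF of SNPs, InDels and structural variants called between a
resequenced accession and the reference accession, this module computes the
descriptive statistics a resequencing survey reports: zygosity breakdown,
transition/transversion ratio, InDel length-class spectrum, structural-variant
classes, per-chromosome and per-window variant densities, and mean spacing
between variants.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

PURINES = {"A", "G"}
PYRIMIDINES = {"C", "T"}
DNA = {"A", "C", "G", "T"}

SV_MIN_LEN = 100  # INS/DEL at or above this length are treated as SVs


class VcfParseError(ValueError):
    """Raised for malformed or unsorted VCF input."""


@dataclass(frozen=True)
class VariantRecord:
    """One variant between two accessions, in VCF coordinates.

    ``pos`` is 1-based; InDels use the anchored-base convention (first base of
    ``ref`` and ``alt`` is the shared anchor), so ``indel_len`` excludes the
    anchor. Inversions carry the symbolic alt ``<INV>`` and an explicit
    ``sv_len``.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    zygosity: str  # "hom" | "het"
    vclass: str = field(default="")  # "SNP" | "INS" | "DEL" | "INV"
    indel_len: int = 0
    sv_len: int = 0

    def __post_init__(self):
        if not self.vclass:
            vclass, ilen, svlen = _classify_alleles(self.ref, self.alt, self.sv_len)
            object.__setattr__(self, "vclass", vclass)
            object.__setattr__(self, "indel_len", ilen)
            object.__setattr__(self, "sv_len", svlen)
        if self.zygosity not in ("hom", "het"):
            raise ValueError(f"bad zygosity {self.zygosity!r}")

    @property
    def is_sv(self) -> bool:
        return self.vclass == "INV" or (
            self.vclass in ("INS", "DEL") and self.indel_len >= SV_MIN_LEN
        )

    @property
    def is_snp(self) -> bool:
        return self.vclass == "SNP"

    @property
    def is_indel(self) -> bool:
        return self.vclass in ("INS", "DEL") and not self.is_sv


def _classify_alleles(ref: str, alt: str, sv_len: int = 0):
    if alt == "<INV>":
        return "INV", 0, sv_len
    if len(ref) == 1 and len(alt) == 1:
        if ref == alt:
            raise ValueError("ref == alt is not a variant")
        return "SNP", 0, 0
    if len(alt) > len(ref):
        ln = len(alt) - len(ref)
        return "INS", ln, ln if ln >= SV_MIN_LEN else 0
    if len(ref) > len(alt):
        ln = len(ref) - len(alt)
        return "DEL", ln, ln if ln >= SV_MIN_LEN else 0
    raise ValueError(f"cannot classify alleles {ref!r}>{alt!r}")


def classify_substitution(ref: str, alt: str) -> str:
    """Classify a single-base substitution as ``transition`` or ``transversion``.

    Transitions are the purine↔purine and pyrimidine↔pyrimidine exchanges
    (A↔G, C↔T); the other eight ordered base pairs are transversions.
    """
    ref, alt = ref.upper(), alt.upper()
    if ref not in DNA or alt not in DNA:
        raise ValueError(f"non-ACGT base in substitution {ref}>{alt}")
    if ref == alt:
        raise ValueError("identical bases do not form a substitution")
    if {ref, alt} <= PURINES or {ref, alt} <= PYRIMIDINES:
        return "transition"
    return "transversion"


def read_vcf(path) -> list[VariantRecord]:
    """Read a VCF v4.2 file into :class:`VariantRecord` objects.

    Multi-allelic sites are split into one record per alternate allele
    carried by the genotype. Records without a GT call, records out of
    coordinate order, and malformed records raise :class:`VcfParseError`
    naming the offending record.
    """
    from cyvcf2 import VCF

    records: list[VariantRecord] = []
    last: dict[str, int] = {}
    seen_chroms: list[str] = []
    try:
        vcf = VCF(str(path), gts012=False)
    except Exception as exc:  # pragma: no cover - cyvcf2 error text varies
        raise VcfParseError(f"cannot open VCF {path}: {exc}") from exc
    for i, v in enumerate(vcf, start=1):
        where = f"{path} record {i} ({v.CHROM}:{v.POS})"
        if v.CHROM in last:
            if v.POS < last[v.CHROM] or seen_chroms[-1] != v.CHROM:
                raise VcfParseError(f"unsorted VCF at {where}")
        else:
            seen_chroms.append(v.CHROM)
        last[v.CHROM] = v.POS
        gts = v.genotypes
        if not gts or gts[0] is None or len(gts[0]) < 2 or gts[0][0] < 0:
            raise VcfParseError(f"record lacks a GT call at {where}")
        alleles = [a for a in gts[0][:-1] if a is not None]
        for alt_index, alt in enumerate(v.ALT, start=1):
            n_alt = sum(a == alt_index for a in alleles)
            if n_alt == 0:
                continue
            zyg = "hom" if n_alt == len(alleles) else "het"
            sv_len = 0
            if alt == "<INV>":
                end = v.INFO.get("END")
                if end is None:
                    raise VcfParseError(f"<INV> without END at {where}")
                sv_len = int(end) - v.POS + 1
            try:
                records.append(
                    VariantRecord(v.CHROM, v.POS, v.REF, alt, zyg, sv_len=sv_len)
                )
            except ValueError as exc:
                raise VcfParseError(f"bad alleles at {where}: {exc}") from exc
    return records


# ---------------------------------------------------------------------------
# summary statistics


@dataclass
class CatalogSummary:
    n_snp: int
    n_indel: int
    n_sv: int
    n_hom: int
    n_het: int
    het_ratio: float
    n_ts: int
    n_tv: int
    tstv: float | None
    indel_len_classes: dict  # {"1": n, "2-20": n, ">20": n}
    snp_density_per_mb: float
    indel_density_per_mb: float
    mean_snp_spacing: float | None
    mean_indel_spacing: float | None
    sv_len_median: float | None

    def as_series(self) -> pd.Series:
        d = self.__dict__.copy()
        classes = d.pop("indel_len_classes")
        for k, v in classes.items():
            d[f"indel_len_{k}"] = v
        return pd.Series(d)


def het_ratio(n_het: int, n_total: int) -> float:
    """Heterozygous fraction of a variant set, as a proportion in [0, 1]."""
    if n_total <= 0:
        raise ValueError("empty variant set")
    return n_het / n_total


def tstv_ratio(n_ts: int, n_tv: int) -> float | None:
    """Transition/transversion ratio; ``None`` when no transversions."""
    if n_tv == 0:
        return None
    return n_ts / n_tv


def mean_spacing_from_density(density_per_mb: float) -> float | None:
    """Mean bp between adjacent variants given a per-Mb density."""
    if density_per_mb <= 0:
        return None
    return 1_000_000 / density_per_mb


def indel_length_class(indel_len: int) -> str:
    if indel_len == 1:
        return "1"
    if 2 <= indel_len <= 20:
        return "2-20"
    if indel_len > 20:
        return ">20"
    raise ValueError(f"indel_len must be >= 1, got {indel_len}")


def summarize(
    variants: Sequence[VariantRecord], chrom_lengths: Mapping[str, int]
) -> CatalogSummary:
    """Compute the catalogue summary over a variant list.

    Densities are per Mb of the full declared chromosome lengths (assembly
    gaps are not excluded), and mean spacing is the reciprocal of density.
    """
    if not variants:
        raise ValueError("empty variant list")
    total_len = sum(chrom_lengths.values())
    if total_len <= 0:
        raise ValueError("chromosome lengths must be positive")
    mb = total_len / 1_000_000

    snps = [v for v in variants if v.is_snp]
    indels = [v for v in variants if v.is_indel]
    svs = [v for v in variants if v.is_sv]
    n_het = sum(v.zygosity == "het" for v in variants)
    n_hom = len(variants) - n_het

    n_ts = n_tv = 0
    for v in snps:
        if classify_substitution(v.ref, v.alt) == "transition":
            n_ts += 1
        else:
            n_tv += 1

    classes = {"1": 0, "2-20": 0, ">20": 0}
    for v in indels:
        classes[indel_length_class(v.indel_len)] += 1
    # SV-sized INS/DEL belong in the open-ended class of the length spectrum
    for v in svs:
        if v.vclass in ("INS", "DEL"):
            classes[">20"] += 1

    snp_density = len(snps) / mb
    indel_density = len(indels) / mb
    sv_lens = [v.sv_len for v in svs]
    return CatalogSummary(
        n_snp=len(snps),
        n_indel=len(indels),
        n_sv=len(svs),
        n_hom=n_hom,
        n_het=n_het,
        het_ratio=het_ratio(n_het, len(variants)),
        n_ts=n_ts,
        n_tv=n_tv,
        tstv=tstv_ratio(n_ts, n_tv),
        indel_len_classes=classes,
        snp_density_per_mb=snp_density,
        indel_density_per_mb=indel_density,
        mean_snp_spacing=mean_spacing_from_density(snp_density),
        mean_indel_spacing=mean_spacing_from_density(indel_density),
        sv_len_median=float(np.median(sv_lens)) if sv_lens else None,
    )


@dataclass(frozen=True)
class WindowDensity:
    chrom: str
    window_start: int  # 0-based, half-open
    window_size: int
    n_snp: int
    n_indel: int
    density: float  # variants per Mb


def window_densities(
    variants: Iterable[VariantRecord],
    chrom_lengths: Mapping[str, int],
    window_size: int = 1_000_000,
) -> list[WindowDensity]:
    """Bin variants into half-open windows ``[k·w, (k+1)·w)`` per chromosome.

    The last window on each chromosome is truncated at the declared length;
    density is scaled to variants per Mb of the (possibly truncated) window.
    """
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    snp_counts: dict[str, np.ndarray] = {}
    indel_counts: dict[str, np.ndarray] = {}
    for chrom, length in chrom_lengths.items():
        n_win = max(1, math.ceil(length / window_size))
        snp_counts[chrom] = np.zeros(n_win, dtype=int)
        indel_counts[chrom] = np.zeros(n_win, dtype=int)
    for v in variants:
        if v.chrom not in snp_counts:
            raise ValueError(f"variant on undeclared chromosome {v.chrom}")
        if v.pos > chrom_lengths[v.chrom]:
            raise ValueError(
                f"variant at {v.chrom}:{v.pos} beyond declared length "
                f"{chrom_lengths[v.chrom]}"
            )
        w = (v.pos - 1) // window_size
        if v.is_snp:
            snp_counts[v.chrom][w] += 1
        elif v.is_indel:
            indel_counts[v.chrom][w] += 1
    out = []
    for chrom, length in chrom_lengths.items():
        for w in range(len(snp_counts[chrom])):
            start = w * window_size
            size = min(window_size, length - start)
            n_snp = int(snp_counts[chrom][w])
            n_indel = int(indel_counts[chrom][w])
            out.append(
                WindowDensity(
                    chrom, start, size, n_snp, n_indel,
                    (n_snp + n_indel) * 1_000_000 / size,
                )
            )
    return out


def windowed_gc(genome: Mapping[str, str], window_size: int = 1_000_000) -> pd.DataFrame:
    """GC fraction per half-open window; companion track for density plots."""
    rows = []
    for chrom, seq in genome.items():
        for start in range(0, len(seq), window_size):
            chunk = seq[start : start + window_size]
            gc = (chunk.count("G") + chunk.count("C")) / len(chunk)
            rows.append((chrom, start, len(chunk), gc))
    return pd.DataFrame(rows, columns=["chrom", "window_start", "window_size", "gc"])


def density_table(windows: Sequence[WindowDensity]) -> pd.DataFrame:
    return pd.DataFrame([w.__dict__ for w in windows])
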