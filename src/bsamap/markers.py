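"""Agarose-resolvable InDel marker design.

Homozygous InDels of 20–200 bp are screened into PCR markers: a flank
cleanliness filter, polymorphism information content (PIC) across an
accession panel, a PIC threshold, and primer design under a fixed constraint
envelope (product 200–350 bp, primer 18–29 nt, Tm 55–64 °C, GC 35–65 %) with
per-parent predicted product sizes so alleles separate on a 3 % agarose gel.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.SeqUtils import MeltingTemp

from .catalog import VariantRecord

COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(COMPLEMENT)[::-1]


@dataclass
class MarkerCandidate:
    """A screened InDel with (optionally) its panel frequencies and PIC."""

    marker_id: str
    variant: VariantRecord
    panel_freqs: np.ndarray | None = None
    pic: float | None = None

    @property
    def chrom(self) -> str:
        return self.variant.chrom

    @property
    def pos(self) -> int:
        return self.variant.pos

    @property
    def locus(self) -> str:
        return f"{self.variant.chrom}:{self.variant.pos}"


@dataclass(frozen=True)
class PrimerConstraints:
    product_range: tuple[int, int] = (200, 350)
    primer_len: tuple[int, int] = (18, 29)
    tm_range: tuple[float, float] = (55.0, 64.0)
    gc_range: tuple[float, float] = (0.35, 0.65)
    max_homopolymer: int = 4
    max_3prime_gc_run: int = 3
    opt_tm: float = 59.5
    flank: int = 400  # sequence searched on each side of the InDel


@dataclass
class PrimerPair:
    fwd_seq: str
    rev_seq: str
    fwd_tm: float
    rev_tm: float
    fwd_gc: float
    rev_gc: float
    product_size_ref: int
    product_size_alt: int
    fwd_start: int  # 1-based genomic start of the forward primer
    rev_end: int  # 1-based genomic end (3' on the reference) of the amplicon


@dataclass
class PrimerDesignFailure:
    marker_id: str
    reason: str


def select_candidates(
    variants: Sequence[VariantRecord],
    min_len: int = 20,
    max_len: int = 200,
    flank_clean_bp: int = 350,
    min_neighbor_indel: int = 5,
) -> list[MarkerCandidate]:
    """Screen variants into raw marker candidates.

    Keeps homozygous insertions/deletions with ``min_len <= length <=
    max_len`` whose flanks (``flank_clean_bp`` each side) contain no other
    InDel of ``min_neighbor_indel`` bp or more — a second length polymorphism
    inside the amplicon would confound band-size genotyping. Marker ids
    follow the ``In{chromosome}-{rank}`` convention, ranked by position.
    """
    indels = sorted(
        (v for v in variants if v.vclass in ("INS", "DEL")),
        key=lambda v: (v.chrom, v.pos),
    )
    big_by_chrom: dict[str, list[int]] = {}
    for v in indels:
        if v.indel_len >= min_neighbor_indel:
            big_by_chrom.setdefault(v.chrom, []).append(v.pos)
    out: list[MarkerCandidate] = []
    rank: dict[str, int] = {}
    for v in indels:
        if v.zygosity != "hom" or not (min_len <= v.indel_len <= max_len):
            continue
        import bisect

        big = big_by_chrom.get(v.chrom, [])
        lo = bisect.bisect_left(big, v.pos - flank_clean_bp)
        hi = bisect.bisect_right(big, v.pos + flank_clean_bp)
        neighbors = [p for p in big[lo:hi] if p != v.pos]
        if neighbors:
            continue
        rank[v.chrom] = rank.get(v.chrom, 0) + 1
        num = re.sub(r"\D", "", v.chrom) or v.chrom
        out.append(MarkerCandidate(f"In{num}-{rank[v.chrom]}", v))
    return out


def compute_pic(freqs: Sequence[float], method: str = "botstein") -> float:
    """Polymorphism information content of a locus from allele frequencies.

    The default is Botstein's heterozygosity-corrected form::

        PIC = 1 - sum(p_i^2) - sum_{i<j} 2 p_i^2 p_j^2

    ``method="expected_het"`` gives the simpler ``1 - sum(p_i^2)``.
    """
    p = np.asarray(freqs, dtype=float)
    if p.ndim != 1 or p.size < 1:
        raise ValueError("freqs must be a non-empty 1-D sequence")
    if (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("allele frequencies must be >= 0 and sum to 1")
    sq = p**2
    he = 1.0 - sq.sum()
    if method == "expected_het":
        return float(he)
    if method != "botstein":
        raise ValueError(f"unknown PIC method {method!r}")
    cross = sq.sum() ** 2 - (sq**2).sum()  # = sum_{i != j} p_i^2 p_j^2
    return float(he - cross)


def panel_frequencies(panel: pd.DataFrame, locus: str) -> np.ndarray:
    """Allele frequencies of one locus column of an accession panel table."""
    counts = panel[locus].value_counts().sort_index()
    return (counts / counts.sum()).to_numpy()


def screen_by_pic(
    candidates: Sequence[MarkerCandidate],
    panel: pd.DataFrame,
    threshold: float = 0.5,
    method: str = "botstein",
) -> list[MarkerCandidate]:
    """Retain candidates whose panel PIC is strictly above ``threshold``.

    Candidates whose locus is missing from the panel are dropped with a
    warning. PIC and panel frequencies are attached in place to every scored
    candidate, passing or not, so callers can inspect the full spectrum.
    """
    kept = []
    for c in candidates:
        if c.locus not in panel.columns:
            warnings.warn(f"marker {c.marker_id} locus {c.locus} absent from panel")
            continue
        freqs = panel_frequencies(panel, c.locus)
        c.panel_freqs = freqs
        c.pic = compute_pic(freqs, method=method)
        if c.pic > threshold:
            kept.append(c)
    return kept


def pic_report(markers: Sequence[MarkerCandidate]) -> pd.DataFrame:
    """Per-chromosome marker counts and mean PIC."""
    df = pd.DataFrame(
        {"chrom": [m.chrom for m in markers], "pic": [m.pic for m in markers]}
    )
    if df.empty:
        return pd.DataFrame(columns=["chrom", "n_markers", "mean_pic"])
    g = df.groupby("chrom")["pic"].agg(["count", "mean"]).reset_index()
    return g.rename(columns={"count": "n_markers", "mean": "mean_pic"})


# ---------------------------------------------------------------------------
# primer design


def primer_tm(seq: str) -> float:
    """Nearest-neighbor melting temperature, 50 mM monovalent cation and
    50 nM oligo (Primer3-like conditions)."""
    return float(MeltingTemp.Tm_NN(seq, Na=50, dnac1=50, dnac2=0))


def gc_fraction(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq)


def _max_homopolymer(seq: str) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def _3prime_gc_run(seq: str) -> int:
    n = 0
    for b in reversed(seq):
        if b in "GC":
            n += 1
        else:
            break
    return n


def primer_ok(seq: str, c: PrimerConstraints) -> bool:
    if not (c.primer_len[0] <= len(seq) <= c.primer_len[1]):
        return False
    if not (c.gc_range[0] <= gc_fraction(seq) <= c.gc_range[1]):
        return False
    if _max_homopolymer(seq) > c.max_homopolymer:
        return False
    if _3prime_gc_run(seq) > c.max_3prime_gc_run:
        return False
    tm = primer_tm(seq)
    return c.tm_range[0] <= tm <= c.tm_range[1]


def _enumerate_primers(flank: str, c: PrimerConstraints, reverse: bool, blocked=None):
    """Yield (offset, length, seq, tm, gc) for valid primers in a flank.

    Offsets are 0-based into ``flank``; for the reverse primer the sequence
    is the reverse complement of the flank window. Windows touching a
    ``blocked`` position (a known polymorphism that would compromise primer
    binding in one parent) are skipped.
    """
    if blocked is None:
        blocked = np.zeros(len(flank), dtype=bool)
    cum = np.concatenate([[0], np.cumsum(blocked)])
    out = []
    for start in range(0, len(flank) - c.primer_len[0] + 1):
        for ln in range(c.primer_len[0], c.primer_len[1] + 1):
            if start + ln > len(flank):
                break
            if cum[start + ln] - cum[start] > 0:
                continue
            window = flank[start : start + ln]
            seq = _revcomp(window) if reverse else window
            gc = gc_fraction(seq)
            if not (c.gc_range[0] <= gc <= c.gc_range[1]):
                continue
            if _max_homopolymer(seq) > c.max_homopolymer:
                continue
            if _3prime_gc_run(seq) > c.max_3prime_gc_run:
                continue
            tm = primer_tm(seq)
            if not (c.tm_range[0] <= tm <= c.tm_range[1]):
                continue
            out.append((start, ln, seq, tm, gc))
    return out


def design_primers(
    candidate: MarkerCandidate,
    genome: Mapping[str, str],
    constraints: PrimerConstraints = PrimerConstraints(),
    avoid_variants: Sequence[VariantRecord] | None = None,
) -> PrimerPair | PrimerDesignFailure:
    """Design the best primer pair for an InDel marker.

    Candidate primers are enumerated exhaustively in the two reference
    flanks, filtered on length, Tm, GC, homopolymer runs and 3'-GC clamps,
    and paired under the product-size window (measured on the reference
    allele). Flank positions carrying any other known variant
    (``avoid_variants``) are excluded so both parental templates amplify.
    The best pair minimizes total deviation from the optimum Tm; ties break
    toward the leftmost forward primer. Returns a
    :class:`PrimerDesignFailure` when no pair satisfies every constraint.
    """
    v = candidate.variant
    seq = genome[v.chrom]
    c = constraints
    # reference span covered by the InDel allele (anchor + deleted bases)
    ref_end = v.pos + len(v.ref) - 1
    left_lo = max(0, v.pos - 1 - c.flank)
    left = seq[left_lo : v.pos]  # includes the anchor base
    right = seq[ref_end : ref_end + c.flank]
    blocked_left = np.zeros(len(left), dtype=bool)
    blocked_right = np.zeros(len(right), dtype=bool)
    for o in avoid_variants or ():
        if o.chrom != v.chrom or o.pos == v.pos:
            continue
        span = max(len(o.ref), o.sv_len if o.vclass == "INV" else 0)
        for p in range(o.pos, o.pos + span):  # 1-based genomic
            if left_lo + 1 <= p <= v.pos:
                blocked_left[p - left_lo - 1] = True
            elif ref_end + 1 <= p <= ref_end + len(right):
                blocked_right[p - ref_end - 1] = True
    fwd = _enumerate_primers(left, c, reverse=False, blocked=blocked_left)
    rev = _enumerate_primers(right, c, reverse=True, blocked=blocked_right)
    if not fwd or not rev:
        return PrimerDesignFailure(candidate.marker_id, "no valid primer in flank")
    best = None
    for fs, fl, fseq, ftm, fgc in fwd:
        # product on the reference from fwd start to rev 3' end
        base = (len(left) - fs) + (ref_end - v.pos)
        for rs, rl, rseq, rtm, rgc in rev:
            product_ref = base + rs + rl
            if not (c.product_range[0] <= product_ref <= c.product_range[1]):
                continue
            score = (abs(ftm - c.opt_tm) + abs(rtm - c.opt_tm), left_lo + fs)
            if best is None or score < best[0]:
                product_alt = product_ref - v.indel_len if v.vclass == "DEL" else product_ref + v.indel_len
                best = (
                    score,
                    PrimerPair(
                        fwd_seq=fseq,
                        rev_seq=rseq,
                        fwd_tm=ftm,
                        rev_tm=rtm,
                        fwd_gc=fgc,
                        rev_gc=rgc,
                        product_size_ref=product_ref,
                        product_size_alt=product_alt,
                        fwd_start=left_lo + fs + 1,
                        rev_end=ref_end + rs + rl,
                    ),
                )
    if best is None:
        return PrimerDesignFailure(candidate.marker_id, "no pair in product-size window")
    return best[1]


def in_silico_pcr(
    genome: Mapping[str, str], fwd: str, rev: str, max_size: int = 5000
) -> list[tuple[str, int, int, int]]:
    """Exact-match in-silico PCR.

    Returns ``(chrom, start, end, size)`` (1-based inclusive) for every
    amplicon up to ``max_size`` bp, in either orientation of the pair.
    """
    products = []
    for chrom, seq in genome.items():
        for a, b in ((fwd, rev), (rev, fwd)):
            plus = _find_all(seq, a)
            minus = _find_all(seq, _revcomp(b))
            for s in plus:
                for m in minus:
                    end = m + len(b)
                    size = end - s
                    if 0 < size <= max_size:
                        products.append((chrom, s + 1, end, size))
    return sorted(set(products))


def _find_all(seq: str, sub: str) -> list[int]:
    out, i = [], seq.find(sub)
    while i != -1:
        out.append(i)
        i = seq.find(sub, i + 1)
    return out


MARKER_TABLE_COLUMNS = [
    "marker_id", "chrom", "pos", "vclass", "indel_len", "pic",
    "fwd_seq", "rev_seq", "fwd_tm", "rev_tm", "fwd_gc", "rev_gc",
    "product_size_ref", "product_size_alt", "design_status",
]


def marker_table(
    markers: Sequence[MarkerCandidate],
    primers: Mapping[str, PrimerPair | PrimerDesignFailure] | None = None,
) -> pd.DataFrame:
    """Fixed-column marker report: id, locus, InDel length, PIC and assay."""
    rows = []
    for m in markers:
        row = {
            "marker_id": m.marker_id,
            "chrom": m.chrom,
            "pos": m.pos,
            "vclass": m.variant.vclass,
            "indel_len": m.variant.indel_len,
            "pic": m.pic if m.pic is not None else np.nan,
            "fwd_seq": "",
            "rev_seq": "",
            "fwd_tm": np.nan,
            "rev_tm": np.nan,
            "fwd_gc": np.nan,
            "rev_gc": np.nan,
            "product_size_ref": -1,
            "product_size_alt": -1,
            "design_status": "not_attempted",
        }
        if primers and m.marker_id in primers:
            p = primers[m.marker_id]
            if isinstance(p, PrimerPair):
                row.update(
                    fwd_seq=p.fwd_seq,
                    rev_seq=p.rev_seq,
                    fwd_tm=round(p.fwd_tm, 2),
                    rev_tm=round(p.rev_tm, 2),
                    fwd_gc=round(p.fwd_gc, 3),
                    rev_gc=round(p.rev_gc, 3),
                    product_size_ref=p.product_size_ref,
                    product_size_alt=p.product_size_alt,
                    design_status="ok",
                )
            else:
                row["design_status"] = f"failed: {p.reason}"
        rows.append(row)
    return pd.DataFrame(rows, columns=MARKER_TABLE_COLUMNS)
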