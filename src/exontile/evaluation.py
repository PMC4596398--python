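"""Evaluation of assembled genes against reference transcript models.

Reference models play the role of experimentally derived full-length cDNA
structures: assembled genes overlapping a reference by more than 90% of
their sequence are matched to it, structural disagreements are classified
into seven categories (extra/missing exon, extra/missing intron, missing
junction, gap, or multiple discrepancies), and transcript-end offsets are
summarized. The module also carries the sampling arithmetic used to audit
discrepant genes: a finite-population minimum sample size and the
extrapolation from a manually classified sample back to the full set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from statistics import mean
from typing import Sequence

from .io_formats import GeneModel

__all__ = [
    "DiscrepancyReport",
    "SampleSizeParams",
    "OffsetSummary",
    "match_references",
    "classify_discrepancy",
    "tss_tts_offsets",
    "sample_size",
    "extrapolate_rates",
    "CATEGORIES",
]

CATEGORIES = (
    "match", "extra_exon", "missing_exon", "extra_intron",
    "missing_intron", "missing_junction", "gap", "multiple",
)


@dataclass
class DiscrepancyReport:
    """Classification of assembled gene(s) against one reference model."""

    gene_id: str
    ref_id: str
    category: str
    n_discrepancies: int


# ---------------------------------------------------------------------------
# matching
# ---------------------------------------------------------------------------


def _footprint_overlap(a: Sequence[tuple[int, int]],
                       b: Sequence[tuple[int, int]]) -> int:
    return sum(
        max(0, min(e1, e2) - max(s1, s2))
        for s1, e1 in a for s2, e2 in b
    )


def match_references(
    genes: Sequence[GeneModel],
    refs: Sequence[GeneModel],
    min_overlap: float = 0.90,
) -> list[tuple[GeneModel, GeneModel]]:
    """Pair assembled genes with reference models they overlap > ``min_overlap``.

    Overlap is exonic: shared footprint / gene footprint. When several
    reference variants qualify for one gene, a variant with the same exon
    count is preferred; otherwise the best-overlapping variant is taken.
    """
    pairs: list[tuple[GeneModel, GeneModel]] = []
    for g in genes:
        candidates: list[tuple[float, GeneModel]] = []
        for r in refs:
            if r.chrom != g.chrom or r.end <= g.start or g.end <= r.start:
                continue
            frac = _footprint_overlap(g.exons, r.exons) / g.footprint_nt
            if frac > min_overlap:
                candidates.append((frac, r))
        if not candidates:
            continue
        same_n = [c for c in candidates if c[1].n_exons == g.n_exons]
        chosen = max(same_n or candidates, key=lambda c: c[0])
        pairs.append((g, chosen[1]))
    return pairs


# ---------------------------------------------------------------------------
# discrepancy classification
# ---------------------------------------------------------------------------


def _introns(exons: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    return [(e1, s2) for (_, e1), (s2, _) in zip(exons, exons[1:])]


def _inside_any(iv: tuple[int, int], exons: Sequence[tuple[int, int]]) -> bool:
    return any(s < iv[0] and iv[1] < e for s, e in exons)


def _overlaps_none(iv: tuple[int, int], exons: Sequence[tuple[int, int]]) -> bool:
    return all(min(iv[1], e) <= max(iv[0], s) for s, e in exons)


def classify_discrepancy(
    genes: GeneModel | Sequence[GeneModel], ref: GeneModel
) -> DiscrepancyReport:
    """Classify the structural disagreement between assembly and reference.

    ``genes`` is the assembled gene matched to the reference, or a list of
    assembled genes when the reference locus was reported in pieces.
    Elementary discrepancies:

    - *extra exon* — an assembled exon overlapping no reference exon;
    - *missing exon* — a reference exon overlapping no assembled exon;
    - *extra intron* — an assembled intron strictly inside one reference
      exon (the assembly split an exon in two);
    - *missing intron* — a reference intron strictly inside one assembled
      exon (the assembly fused two exons);
    - *missing junction* — a break between two assembled genes where the
      reference has an intron (the join was missed for lack of junction
      evidence);
    - *gap* — a break between two assembled genes inside one reference
      exon, i.e. a coverage hole with no junction support.

    Zero discrepancies is a *match*; one names its category; two or more
    are *multiple*. Every pair receives exactly one category.
    """
    gene_list = [genes] if isinstance(genes, GeneModel) else sorted(
        genes, key=lambda g: g.start)
    if not gene_list:
        raise ValueError("no assembled genes to classify")
    asm_exons = sorted(e for g in gene_list for e in g.exons)
    ref_exons = list(ref.exons)
    ref_introns = _introns(ref_exons)

    found: list[str] = []
    # within-gene intron comparisons
    for g in gene_list:
        for intr in _introns(g.exons):
            if intr in ref_introns:
                continue
            if _inside_any(intr, ref_exons):
                found.append("extra_intron")
    for intr in ref_introns:
        for g in gene_list:
            if _inside_any(intr, g.exons):
                found.append("missing_intron")
    # exon presence
    for ex in asm_exons:
        if _overlaps_none(ex, ref_exons):
            found.append("extra_exon")
    for ex in ref_exons:
        if _overlaps_none(ex, asm_exons):
            found.append("missing_exon")
    # breaks between assembled pieces of one reference locus
    for g1, g2 in zip(gene_list, gene_list[1:]):
        break_iv = (g1.end, g2.start)
        if any(d < break_iv[1] and a > break_iv[0] for d, a in ref_introns):
            found.append("missing_junction")
        elif _inside_any(break_iv, ref_exons):
            found.append("gap")

    gene_id = ",".join(g.gene_id or "?" for g in gene_list)
    if not found:
        return DiscrepancyReport(gene_id, ref.gene_id, "match", 0)
    if len(found) == 1:
        return DiscrepancyReport(gene_id, ref.gene_id, found[0], 1)
    return DiscrepancyReport(gene_id, ref.gene_id, "multiple", len(found))


# ---------------------------------------------------------------------------
# transcript-end offsets
# ---------------------------------------------------------------------------


@dataclass
class OffsetSummary:
    """Start/termination offsets of assembled genes vs references, in nt.

    Sign convention: positive means the assembled gene is longer than the
    reference (start further upstream / end further downstream), negative
    means shorter.
    """

    start_offsets: list[int]
    end_offsets: list[int]

    @property
    def mean_start(self) -> float:
        return mean(self.start_offsets)

    @property
    def mean_end(self) -> float:
        return mean(self.end_offsets)

    def fraction_within(self, limit: int = 100) -> tuple[float, float]:
        fs = sum(1 for o in self.start_offsets if abs(o) <= limit) / len(self.start_offsets)
        fe = sum(1 for o in self.end_offsets if abs(o) <= limit) / len(self.end_offsets)
        return fs, fe


def tss_tts_offsets(pairs: Sequence[tuple[GeneModel, GeneModel]]) -> OffsetSummary:
    """Per-pair transcription start/termination offsets.

    Start offset = ref.start - gene.start (an assembled start 30 nt
    upstream of the reference gives +30); end offset = gene.end - ref.end.
    """
    if not pairs:
        raise ValueError("no matched pairs")
    starts = [r.start - g.start for g, r in pairs]
    ends = [g.end - r.end for g, r in pairs]
    return OffsetSummary(starts, ends)


# ---------------------------------------------------------------------------
# sampling arithmetic
# ---------------------------------------------------------------------------


@dataclass
class SampleSizeParams:
    """Inputs of the finite-population minimum-sample-size formula.

    ``N`` population size, ``E`` margin of error (fraction), ``zc``
    critical value of the confidence level, ``r`` expected rate in percent.
    """

    N: int
    E: float = 0.05
    zc: float = 1.96
    r: float = 60.0

    def __post_init__(self) -> None:
        if not (0 < self.E < 1):
            raise ValueError("E must be a fraction in (0,1)")
        if not (0 <= self.r <= 100):
            raise ValueError("r is a percentage")
        if self.N < 1:
            raise ValueError("N must be >= 1")


def sample_size(p: SampleSizeParams) -> int:
    """Minimum sample size with finite-population correction, rounded up.

    n = N*x / ((N-1)*E^2 + x) with x = zc^2 * r*(100-r) / 100^2.
    Degenerate rates (r = 0 or 100) give x = 0 and hence n = 0.
    """
    x = p.zc ** 2 * p.r * (100.0 - p.r) / 100.0 ** 2
    n = p.N * x / ((p.N - 1) * p.E ** 2 + x)
    return math.ceil(n)


@dataclass
class ExtrapolationResult:
    expected_alt_splice: int
    residual: int
    residual_pct_of_matched: float
    accuracy_bound_pct: float


def extrapolate_rates(
    total_discrepant: int, sampled_rate: float, matched_total: int
) -> ExtrapolationResult:
    """Extrapolate a sampled alternative-splicing rate to all discrepant genes.

    ``sampled_rate`` (fraction) of ``total_discrepant`` genes are expected
    to be explained by alternative splicing; the residual, as a percentage
    of all ``matched_total`` reference-matched genes (1 decimal place),
    bounds the assembler's structural error, and 100 minus it bounds its
    accuracy.
    """
    if not (0 <= sampled_rate <= 1):
        raise ValueError("sampled_rate is a fraction")
    expected = round(total_discrepant * sampled_rate)
    residual = total_discrepant - expected
    residual_pct = round(100.0 * residual / matched_total, 1)
    return ExtrapolationResult(
        expected_alt_splice=expected,
        residual=residual,
        residual_pct_of_matched=residual_pct,
        accuracy_bound_pct=round(100.0 - residual_pct, 1),
    )
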