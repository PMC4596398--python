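"""Novel-gene discovery: annotation-overlap classes and the filter cascade.

Assembled genes are classified by how much of their exonic footprint an
existing annotation explains: well-annotated (>= 75% overlap), intermediate
(possible unannotated splice forms), or novel (< 5%). Candidate novel
genes then pass a cascade of pure-predicate filters — containment
deduplication, minimum footprint, minimum expression, and a genome
self-similarity screen that rejects multi-mapping artefacts — before being
reported, optionally merged with a second assembler's calls into a
high-confidence union with exclusive/shared accounting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from intervaltree import IntervalTree

from .io_formats import AnnotationGene, GeneModel

__all__ = [
    "OverlapClass",
    "SimilarityResult",
    "NovelGeneReport",
    "classify_overlap",
    "dedupe_contained",
    "filter_expression",
    "similarity_screen",
    "novel_gene_cascade",
    "combine_and_report",
    "SIMILARITY_BINS",
]

SIMILARITY_BINS = ((0, 25), (25, 50), (50, 75), (75, 101))


@dataclass
class OverlapClass:
    """A gene's best annotation overlap and the class it implies."""

    gene: GeneModel
    best_overlap_fraction: float
    category: str  # annotated | intermediate | novel


@dataclass
class SimilarityResult:
    """Fraction of a gene's sequence that aligns elsewhere in the genome."""

    gene: GeneModel
    percent_similarity: float
    method: str = "internal"


def _footprint_overlap_with_span(gene: GeneModel, span: tuple[int, int]) -> int:
    s0, e0 = span
    return sum(max(0, min(e, e0) - max(s, s0)) for s, e in gene.exons)


def classify_overlap(
    genes: Sequence[GeneModel],
    annotation: Sequence[AnnotationGene],
    hi: float = 0.75,
    lo: float = 0.05,
) -> list[OverlapClass]:
    """Classify each gene by the largest fraction of its footprint that any
    single annotated gene span overlaps.

    >= ``hi`` (default 75%) means the assembly rediscovered an annotated
    gene; < ``lo`` (default 5%) marks a potential novel gene; in between
    lies the intermediate class, plausibly unannotated splice variants of
    known genes. Overlap is computed against annotated spans (start to
    termination), not exon-resolved structure.
    """
    trees: dict[str, IntervalTree] = {}
    for a in annotation:
        trees.setdefault(a.chrom, IntervalTree()).addi(a.start, a.end, a)
    out: list[OverlapClass] = []
    for g in genes:
        tree = trees.get(g.chrom)
        best = 0.0
        if tree is not None:
            hits = {id(iv.data): iv.data
                    for s, e in g.exons for iv in tree.overlap(s, e)}
            for a in hits.values():
                frac = _footprint_overlap_with_span(g, (a.start, a.end)) / g.footprint_nt
                best = max(best, frac)
        category = ("annotated" if best >= hi
                    else "novel" if best < lo
                    else "intermediate")
        out.append(OverlapClass(g, best, category))
    return out


def dedupe_contained(transcripts: Sequence[GeneModel]) -> list[GeneModel]:
    """Drop transcripts completely contained within another transcript.

    Containment is exonic: every exonic base of the dropped transcript lies
    within the other's exons (same chromosome). Identical footprints keep
    the first by sort order.
    """
    order = sorted(
        range(len(transcripts)),
        key=lambda i: (transcripts[i].chrom, -transcripts[i].footprint_nt,
                       transcripts[i].start, i),
    )
    kept: list[int] = []
    for i in order:
        g = transcripts[i]
        contained = any(
            _covered_by(g, transcripts[k]) for k in kept
            if transcripts[k].chrom == g.chrom
        )
        if not contained:
            kept.append(i)
    return [transcripts[i] for i in sorted(kept)]


def _covered_by(inner: GeneModel, outer: GeneModel) -> bool:
    covered = 0
    for s, e in inner.exons:
        for s2, e2 in outer.exons:
            covered += max(0, min(e, e2) - max(s, s2))
    return covered >= inner.footprint_nt


def filter_expression(genes: Sequence[GeneModel], min_rpke: float = 100.0) -> list[GeneModel]:
    """Keep genes expressed at or above ``min_rpke`` (default 100 RPKE,
    the depth at which benchmark titration shows reliable identification)."""
    return [g for g in genes if g.rpke >= min_rpke]


# ---------------------------------------------------------------------------
# genome self-similarity screen
# ---------------------------------------------------------------------------

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _spliced_seq(gene: GeneModel, genome: Mapping[str, str]) -> str:
    try:
        chrom_seq = genome[gene.chrom]
    except KeyError as exc:
        raise KeyError(f"gene locus chromosome {gene.chrom!r} not in genome") from exc
    if gene.end > len(chrom_seq):
        raise ValueError(f"gene {gene.gene_id} extends past end of {gene.chrom}")
    return "".join(chrom_seq[s:e] for s, e in gene.exons).upper()


def _kmer_index(genome: Mapping[str, str], k: int) -> dict[str, list[tuple[str, int]]]:
    index: dict[str, list[tuple[str, int]]] = {}
    for chrom, seq in genome.items():
        s = seq.upper()
        for i in range(len(s) - k + 1):
            index.setdefault(s[i:i + k], []).append((chrom, i))
    return index


def _extend_hit(query: str, qpos: int, target: str, tpos: int, k: int,
                min_identity: float) -> tuple[int, int]:
    """Ungapped extension of an exact seed; returns query interval covered.

    Extends in both directions while the running identity of the whole
    alignment stays at or above ``min_identity``, stopping a direction
    after 5 consecutive mismatches; trailing mismatch runs are trimmed.
    """
    MAX_RUN = 5
    # right extension
    qi, ti = qpos + k, tpos + k
    matches, length, run, best_right = k, k, 0, k
    while qi < len(query) and ti < len(target) and run < MAX_RUN:
        matches += query[qi] == target[ti]
        length += 1
        run = 0 if query[qi] == target[ti] else run + 1
        if query[qi] == target[ti] and matches / length >= min_identity:
            best_right = qi - qpos + 1
        qi += 1
        ti += 1
    # left extension
    qi, ti = qpos - 1, tpos - 1
    run, best_left = 0, 0
    left_matches, left_len = 0, 0
    while qi >= 0 and ti >= 0 and run < MAX_RUN:
        hit = query[qi] == target[ti]
        left_matches += hit
        left_len += 1
        run = 0 if hit else run + 1
        if hit and (matches + left_matches) / (best_right + left_len) >= min_identity:
            best_left = qpos - qi
        qi -= 1
        ti -= 1
    return qpos - best_left, qpos + best_right


def similarity_screen(
    genes: Sequence[GeneModel],
    genome: Mapping[str, str],
    max_percent: float = 25.0,
    word_size: int = 16,
    min_identity: float = 0.9,
    external: Mapping[str, float] | None = None,
) -> list[SimilarityResult]:
    """Measure each gene's sequence similarity to the rest of the genome.

    Internal method: exact ``word_size``-mer seeds of the spliced gene
    sequence (both strands) against the genome, excluding hits overlapping
    the gene's own locus, extended ungapped at >= ``min_identity``;
    percent similarity = 100 x (gene bases covered by any such alignment)
    / footprint. Reads randomly assigned among near-identical loci inflate
    apparent expression there, so genes above ``max_percent`` (default 25)
    are treated as probable multi-mapping artefacts downstream.

    ``external`` substitutes precomputed percent-similarity values (e.g.
    parsed from a tabular alignment report), keyed by gene_id.
    """
    if external is not None:
        return [
            SimilarityResult(g, float(external.get(g.gene_id, 0.0)), "external")
            for g in genes
        ]
    index = _kmer_index(genome, word_size)
    results: list[SimilarityResult] = []
    for g in genes:
        seq = _spliced_seq(g, genome)
        covered = [False] * len(seq)
        own = (g.chrom, g.start, g.end)
        for strand_seq, flip in ((seq, False), (_revcomp(seq), True)):
            n = len(strand_seq)
            for qpos in range(0, n - word_size + 1):
                word = strand_seq[qpos:qpos + word_size]
                for chrom, tpos in index.get(word, ()):
                    if (chrom == own[0]
                            and tpos < own[2] and tpos + word_size > own[1]):
                        continue  # the gene's own locus
                    q0, q1 = _extend_hit(strand_seq, qpos, genome[chrom].upper(),
                                         tpos, word_size, min_identity)
                    if flip:
                        q0, q1 = n - q1, n - q0
                    for p in range(q0, q1):
                        covered[p] = True
        pct = 100.0 * sum(covered) / len(seq)
        results.append(SimilarityResult(g, pct, "internal"))
    return results


# ---------------------------------------------------------------------------
# cascade + two-source report
# ---------------------------------------------------------------------------


@dataclass
class CascadeCounts:
    """Per-stage survivor counts of the novel-gene cascade."""

    input: int = 0
    novel_class: int = 0
    after_dedupe: int = 0
    after_footprint: int = 0
    after_expression: int = 0
    after_similarity: int = 0
    similarity_bins: dict[tuple[int, int], int] = field(default_factory=dict)


def novel_gene_cascade(
    genes: Sequence[GeneModel],
    annotation: Sequence[AnnotationGene],
    genome: Mapping[str, str] | None,
    lo: float = 0.05,
    hi: float = 0.75,
    min_footprint: int = 140,
    min_rpke: float = 100.0,
    max_similarity: float = 25.0,
    word_size: int = 16,
    min_identity: float = 0.9,
    external_similarity: Mapping[str, float] | None = None,
) -> tuple[list[GeneModel], CascadeCounts]:
    """Run the full novel-gene filter cascade on one assembly.

    Stages: novel annotation-overlap class (< ``lo``), containment
    deduplication, minimum footprint, minimum expression, and genome
    similarity below ``max_similarity`` percent. Each stage is a pure
    predicate, so the surviving set is order-independent; the counts
    record survivors per stage in the order above, plus a histogram of
    percent-similarity bins over the expression-filtered set.
    """
    counts = CascadeCounts(input=len(genes))
    novel = [oc.gene for oc in classify_overlap(genes, annotation, hi, lo)
             if oc.category == "novel"]
    counts.novel_class = len(novel)
    deduped = dedupe_contained(novel)
    counts.after_dedupe = len(deduped)
    sized = [g for g in deduped if g.footprint_nt >= min_footprint]
    counts.after_footprint = len(sized)
    expressed = filter_expression(sized, min_rpke)
    counts.after_expression = len(expressed)
    if genome is None and external_similarity is None:
        counts.after_similarity = len(expressed)
        return expressed, counts
    sims = similarity_screen(expressed, genome or {}, max_similarity,
                             word_size, min_identity, external_similarity)
    for b in SIMILARITY_BINS:
        counts.similarity_bins[b] = sum(
            1 for r in sims if b[0] <= r.percent_similarity < b[1]
        )
    final = [r.gene for r in sims if r.percent_similarity < max_similarity]
    counts.after_similarity = len(final)
    return final, counts


@dataclass
class NovelGeneReport:
    """Two-source novel-gene accounting and the high-confidence union."""

    exclusive_a: int
    exclusive_b: int
    shared: int
    union: list[GeneModel]
    counts_a: CascadeCounts
    counts_b: CascadeCounts

    @property
    def n_union(self) -> int:
        return len(self.union)


def _overlaps_any(g: GeneModel, others: Sequence[GeneModel]) -> bool:
    return any(
        o.chrom == g.chrom and g.start < o.end and o.start < g.end
        for o in others
    )


def combine_and_report(
    ta_genes: Sequence[GeneModel],
    other_genes: Sequence[GeneModel],
    annotation: Sequence[AnnotationGene],
    genome: Mapping[str, str] | None,
    **cascade_kwargs,
) -> NovelGeneReport:
    """Run the cascade on two assemblies and report exclusive/shared counts.

    Cross-source matching uses any same-chromosome span overlap (>= 1 nt).
    A pair of overlapping calls counts once toward ``shared``; the union is
    the first source's survivors plus the second source's exclusives, so
    exclusive_a + exclusive_b + shared == len(union) always holds.
    """
    a, counts_a = novel_gene_cascade(ta_genes, annotation, genome, **cascade_kwargs)
    b, counts_b = novel_gene_cascade(other_genes, annotation, genome, **cascade_kwargs)
    shared_a = [g for g in a if _overlaps_any(g, b)]
    exclusive_a = len(a) - len(shared_a)
    b_exclusive = [g for g in b if not _overlaps_any(g, a)]
    union = list(a) + b_exclusive
    return NovelGeneReport(
        exclusive_a=exclusive_a,
        exclusive_b=len(b_exclusive),
        shared=len(shared_a),
        union=union,
        counts_a=counts_a,
        counts_b=counts_b,
    )
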