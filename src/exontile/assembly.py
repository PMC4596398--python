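"""Linking exons into single-isoform gene models through junction edges.

Exon fragments become nodes of a splice graph; junctions whose donor and
acceptor coordinates match fragment boundaries become edges. Every
connected component is emitted as exactly one gene model containing all of
the component's exons — the longest possible isoform — rather than an
enumeration of alternative transcripts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

from .exon_detection import (
    CoverageIndex,
    ExonFragment,
    combine_fragments,
    infer_short_exons,
    merge_close_fragments,
    split_at_internal_junctions,
    tile_fragments,
)
from .io_formats import GeneModel, Junction

logger = logging.getLogger(__name__)

__all__ = [
    "SpliceGraph",
    "StageCounts",
    "filter_junctions",
    "build_splice_graph",
    "link_genes",
    "filter_min_footprint",
    "gene_rpke",
    "assemble",
]


def filter_junctions(
    junctions: Sequence[Junction],
    exons: Sequence[ExonFragment],
    max_span: int = 50_000,
    max_skip_span: int = 50_000,
) -> list[Junction]:
    """Drop implausible junctions before graph construction.

    Junctions longer than ``max_span`` are mapping artefacts from sequence
    similarity elsewhere in the genome. Junctions that skip over one or
    more detected exons are additionally capped at ``max_skip_span``
    (both default to 50,000 nt). Comparisons are strict: a junction of
    exactly the cap survives.
    """
    kept: list[Junction] = []
    for j in junctions:
        if j.span > max_span:
            continue
        if j.span > max_skip_span:
            skips = any(
                e.chrom == j.chrom and j.donor_end <= e.start and e.end <= j.acceptor_start
                for e in exons
            )
            if skips:
                continue
        kept.append(j)
    return kept


@dataclass
class SpliceGraph:
    """Exon fragments (nodes) joined by boundary-matched junctions (edges)."""

    nodes: list[ExonFragment]
    edges: list[tuple[int, int, Junction]] = field(default_factory=list)


def build_splice_graph(
    exons: Sequence[ExonFragment],
    junctions: Sequence[Junction],
    tolerance: int = 0,
    fallback_tolerance: int = 5,
) -> SpliceGraph:
    """Match junction coordinates to fragment boundaries.

    After trimming, fragment ends should equal junction donor/acceptor
    coordinates exactly; a small ``fallback_tolerance`` (default +/-5 nt)
    catches off-by-ones in inputs that bypassed trimming. The nearest
    boundary within tolerance wins.
    """
    nodes = sorted(exons, key=lambda f: (f.chrom, f.start, f.end))
    graph = SpliceGraph(nodes=list(nodes))
    by_chrom: dict[str, list[int]] = {}
    for i, f in enumerate(nodes):
        by_chrom.setdefault(f.chrom, []).append(i)

    def _best(indices: list[int], coord: int, side: str) -> int | None:
        for tol in (tolerance, fallback_tolerance):
            cands = [
                i for i in indices
                if abs((nodes[i].end if side == "end" else nodes[i].start) - coord) <= tol
            ]
            if cands:
                return min(
                    cands,
                    key=lambda i: abs(
                        (nodes[i].end if side == "end" else nodes[i].start) - coord
                    ),
                )
        return None

    for j in junctions:
        idxs = by_chrom.get(j.chrom, [])
        u = _best(idxs, j.donor_end, "end")
        v = _best(idxs, j.acceptor_start, "start")
        if u is None or v is None or u == v:
            continue
        graph.edges.append((u, v, j))
    return graph


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, a: int) -> int:
        while self.parent[a] != a:
            self.parent[a] = self.parent[self.parent[a]]
            a = self.parent[a]
        return a

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def link_genes(graph: SpliceGraph) -> list[GeneModel]:
    """Emit one gene model per connected component of the splice graph.

    All of a component's exons enter the model in coordinate order (single
    longest isoform); edgeless fragments become single-exon genes. Exons
    that interleave on the genome without a connecting junction stay in
    separate genes.
    """
    uf = _UnionFind(len(graph.nodes))
    for u, v, _ in graph.edges:
        uf.union(u, v)
    comp_exons: dict[int, list[int]] = {}
    for i in range(len(graph.nodes)):
        comp_exons.setdefault(uf.find(i), []).append(i)
    comp_edges: dict[int, list[Junction]] = {}
    for u, v, j in graph.edges:
        comp_edges.setdefault(uf.find(u), []).append(j)

    genes: list[GeneModel] = []
    for root in sorted(
        comp_exons, key=lambda r: (graph.nodes[r].chrom,
                                   min(graph.nodes[i].start for i in comp_exons[r]))
    ):
        members = sorted(comp_exons[root],
                         key=lambda i: (graph.nodes[i].start, graph.nodes[i].end))
        exons = [(graph.nodes[i].start, graph.nodes[i].end) for i in members]
        junctions = sorted(comp_edges.get(root, []),
                           key=lambda j: (j.donor_end, j.acceptor_start))
        gene = GeneModel(
            chrom=graph.nodes[members[0]].chrom,
            exons=exons,
            junctions_used=junctions,
            read_count=sum(graph.nodes[i].read_count for i in members),
        )
        gene.rpke = gene.read_count * 1000.0 / gene.footprint_nt
        genes.append(gene)
    for i, g in enumerate(genes, 1):
        g.gene_id = g.gene_id or f"gene_{i}"
    return genes


def filter_min_footprint(genes: Sequence[GeneModel], min_nt: int = 140) -> list[GeneModel]:
    """Remove gene models with exonic footprint below ``min_nt``.

    Very small high-coverage islands (default < 140 nt) are typically
    multi-mapping pile-ups from repeated sequence, not genes.
    """
    if min_nt < 0:
        raise ValueError("min_nt must be >= 0")
    kept = [g for g in genes if g.footprint_nt >= min_nt]
    removed = len(genes) - len(kept)
    if removed:
        logger.info("footprint filter removed %d gene(s) < %d nt", removed, min_nt)
    return kept


def gene_rpke(gene: GeneModel, cov: CoverageIndex) -> float:
    """Gene-level RPKE: distinct reads overlapping any exon, per kb of footprint.

    A junction-spanning read overlapping two exons counts once.
    """
    n = cov.count_reads_multi(gene.chrom, gene.exons)
    return n * 1000.0 / gene.footprint_nt


@dataclass
class StageCounts:
    """Per-stage accounting of the exon/gene pipeline."""

    tiled: int = 0
    with_inferred: int = 0
    after_merge: int = 0
    after_split: int = 0
    genes_linked: int = 0
    genes_kept: int = 0


def assemble(
    cov: CoverageIndex,
    junctions: Sequence[Junction],
    min_exon_rpke: float = 50.0,
    merge_gap: int = 50,
    read_len: int = 50,
    density_ratio: float = 0.5,
    max_junction_span: int = 50_000,
    max_skip_span: int = 50_000,
    min_footprint: int = 140,
) -> tuple[list[GeneModel], StageCounts]:
    """Run the full pipeline: tile, infer short exons, merge, split, link.

    Returns the assembled gene models (with gene-level read counts and RPKE
    recomputed from coverage) and the per-stage fragment/gene counts.
    """
    counts = StageCounts()
    tiled = tile_fragments(cov, min_rpke=min_exon_rpke)
    counts.tiled = len(tiled)
    inferred = infer_short_exons(junctions, read_len, cov)
    frags = combine_fragments(tiled, inferred)
    counts.with_inferred = len(frags)
    frags = merge_close_fragments(frags, max_gap=merge_gap)
    counts.after_merge = len(frags)
    frags = split_at_internal_junctions(
        frags, junctions, cov, density_ratio=density_ratio,
        flank_window=read_len, read_len=read_len,
    )
    counts.after_split = len(frags)
    usable = filter_junctions(junctions, frags, max_junction_span, max_skip_span)
    graph = build_splice_graph(frags, usable)
    genes = link_genes(graph)
    counts.genes_linked = len(genes)
    for g in genes:
        g.read_count = cov.count_reads_multi(g.chrom, g.exons)
        g.rpke = gene_rpke(g, cov)
    genes = filter_min_footprint(genes, min_footprint)
    counts.genes_kept = len(genes)
    return genes, counts
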