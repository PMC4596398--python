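"""Synthetic-genome benchmark: read-depth titration and false-positive audit.

Single-isoform genes with known exon structure are inserted into a random
test genome (a sequence to which no real read aligns, so any signal is
simulated on purpose). Uniformly distributed reads are simulated over each
gene's spliced transcript at a series of depths, the assembler is run at
each depth, and a *point of first failure* is recorded per gene: the
highest expression level (in RPKE) at which the gene's structure was
misreported. Levels above a gene's point of first failure count as
reliable; accuracy at a level is the fraction of genes whose point of
first failure lies below it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .assembly import assemble
from .exon_detection import CoverageIndex
from .io_formats import GeneModel, Junction, ReadBlock, write_gtf

__all__ = [
    "SimGene",
    "BenchmarkResult",
    "generate_test_genome",
    "simulate_reads",
    "titrate",
    "accuracy_at",
    "run_benchmark",
    "false_positive_audit",
    "DEFAULT_LEVELS",
]

DEFAULT_LEVELS: tuple[int, ...] = (1000, 800, 600, 400, 200, 150, 100, 75, 50)

# Structure priors for simulated genes. Exons are long enough that 50-nt
# reads tile them directly; introns exceed the merge gap so exons never
# coalesce by accident.
EXON_LEN_RANGE = (150, 600)
INTRON_LEN_RANGE = (100, 2000)
GENE_SPACING = 10_000


@dataclass
class SimGene:
    """A simulated single-isoform gene with known exon structure."""

    gene_id: str
    chrom: str
    exons: list[tuple[int, int]]  # genomic, half-open, sorted

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def transcript_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    def to_gene_model(self) -> GeneModel:
        junctions = [
            Junction(self.chrom, e1, s2)
            for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])
        ]
        return GeneModel(chrom=self.chrom, exons=list(self.exons),
                         junctions_used=junctions, gene_id=self.gene_id)


def _random_structure(rng: np.random.Generator, n_exons: int,
                      offset: int) -> list[tuple[int, int]]:
    exons = []
    pos = offset
    for i in range(n_exons):
        if i > 0:
            pos += int(rng.integers(*INTRON_LEN_RANGE, endpoint=True))
        length = int(rng.integers(*EXON_LEN_RANGE, endpoint=True))
        exons.append((pos, pos + length))
        pos += length
    return exons


def generate_test_genome(
    seed: int,
    genes_per_category: int = 20,
    categories: Sequence[int] = (1, 2, 3, 4),
    read_len: int = 50,
    chrom: str = "test1",
) -> tuple[dict[str, str], list[SimGene]]:
    """Create a random genome with inserted single-isoform genes.

    One gene category per exon count (default 1-4 exons, 20 genes each).
    Genes are laid out non-overlapping with >= 10 kb spacing. Deterministic
    under ``seed``: identical seeds give byte-identical genome and truth.
    """
    rng = np.random.default_rng(seed)
    genes: list[SimGene] = []
    pos = GENE_SPACING
    gid = 0
    for n_exons in categories:
        for _ in range(genes_per_category):
            gid += 1
            exons = _random_structure(rng, n_exons, pos)
            genes.append(SimGene(f"sim_{gid:03d}", chrom, exons))
            pos = exons[-1][1] + GENE_SPACING
    genome_len = pos
    seq = "".join(rng.choice(list("ACGT"), size=genome_len))
    return {chrom: seq}, genes


def write_truth_gtf(genes: Sequence[SimGene], path: str | Path) -> None:
    """Write the true gene structures as a GTF for external comparison."""
    write_gtf([g.to_gene_model() for g in genes], path, source="sim_truth")


def _transcript_to_blocks(gene: SimGene, t_start: int,
                          read_len: int) -> list[tuple[int, int]]:
    """Map a transcript interval [t_start, t_start+read_len) to genomic blocks."""
    blocks: list[tuple[int, int]] = []
    remaining = read_len
    t = 0
    for s, e in gene.exons:
        exon_len = e - s
        if t + exon_len <= t_start:
            t += exon_len
            continue
        g_start = s + max(0, t_start - t)
        take = min(e - g_start, remaining)
        blocks.append((g_start, g_start + take))
        remaining -= take
        t += exon_len
        if remaining == 0:
            break
    return blocks


def simulate_reads(
    gene: SimGene,
    n_reads: int,
    read_len: int = 50,
    rng: np.random.Generator | int | None = None,
) -> tuple[list[ReadBlock], list[Junction]]:
    """Simulate uniformly distributed reads over a gene's spliced transcript.

    Read start positions are uniform over the transcript; reads crossing an
    exon boundary are emitted as split blocks and add one supporting read
    to the corresponding junction.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    L = gene.transcript_length
    if read_len > L:
        raise ValueError("read longer than transcript")
    blocks: list[ReadBlock] = []
    support: dict[tuple[int, int], int] = {}
    true_introns = [
        (e1, s2) for (_, e1), (s2, _) in zip(gene.exons, gene.exons[1:])
    ]
    starts = rng.integers(0, L - read_len + 1, size=n_reads)
    for i, t0 in enumerate(sorted(int(x) for x in starts)):
        rid = f"{gene.gene_id}_r{i}"
        segs = _transcript_to_blocks(gene, t0, read_len)
        for s, e in segs:
            blocks.append(ReadBlock(gene.chrom, s, e, rid))
        for (s1, e1), (s2, e2) in zip(segs, segs[1:]):
            support[(e1, s2)] = support.get((e1, s2), 0) + 1
    junctions = [
        Junction(gene.chrom, d, a, n)
        for (d, a), n in sorted(support.items())
        if (d, a) in set(true_introns)
    ]
    return blocks, junctions


def _assembles_correctly(gene: SimGene, blocks: list[ReadBlock],
                         junctions: list[Junction],
                         min_exon_rpke: float, read_len: int) -> bool:
    cov = CoverageIndex(blocks)
    genes, _ = assemble(cov, junctions, min_exon_rpke=min_exon_rpke,
                        read_len=read_len)
    return len(genes) == 1 and genes[0].n_exons == gene.n_exons


def titrate(
    gene: SimGene,
    levels: Sequence[int] = DEFAULT_LEVELS,
    read_len: int = 50,
    min_exon_rpke: float = 50.0,
    rng: np.random.Generator | int | None = None,
) -> float | None:
    """Find a gene's point of first failure over descending read counts.

    At each level a fresh read set is drawn, the assembler is run, and the
    result is a failure unless it is a single gene with the true exon
    count. Returns the highest failing level expressed in RPKE, or ``None``
    if the gene never fails down to the lowest level tested.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    poff: float | None = None
    for n_reads in sorted(levels, reverse=True):
        blocks, junctions = simulate_reads(gene, n_reads, read_len, rng)
        level_rpke = n_reads * 1000.0 / gene.transcript_length
        if not _assembles_correctly(gene, blocks, junctions,
                                    min_exon_rpke, read_len):
            if poff is None or level_rpke > poff:
                poff = level_rpke
    return poff


def accuracy_at(poffs: Sequence[float | None], level_rpke: float) -> float:
    """Fraction of genes whose point of first failure is below ``level_rpke``."""
    if not poffs:
        raise ValueError("no genes")
    ok = sum(1 for p in poffs if p is None or p < level_rpke)
    return ok / len(poffs)


@dataclass
class BenchmarkResult:
    """Per-category accuracy from the depth-titration benchmark."""

    accuracy_at_level: dict[int, float]  # exon-count category -> accuracy
    plateau_accuracy: dict[int, float]  # correctness at the highest level
    level_rpke: float = 100.0
    poffs: dict[int, list[float | None]] = field(default_factory=dict)


def run_benchmark(
    seeds: Sequence[int],
    genes_per_category: int = 20,
    categories: Sequence[int] = (1, 2, 3, 4),
    levels: Sequence[int] = DEFAULT_LEVELS,
    read_len: int = 50,
    min_exon_rpke: float = 50.0,
    level_rpke: float = 100.0,
) -> BenchmarkResult:
    """Run the titration benchmark over several independently seeded genomes.

    Each seed builds a fresh test genome (``genes_per_category`` genes per
    exon-count category); every gene is titrated and scored by point of
    first failure. Accuracy is pooled per category across seeds.
    """
    poffs: dict[int, list[float | None]] = {c: [] for c in categories}
    correct_at_top: dict[int, list[bool]] = {c: [] for c in categories}
    top = max(levels)
    for seed in seeds:
        _, genes = generate_test_genome(seed, genes_per_category, categories,
                                        read_len)
        rng = np.random.default_rng(seed)
        for gene in genes:
            p = titrate(gene, levels, read_len, min_exon_rpke, rng)
            poffs[gene.n_exons].append(p)
            top_rpke = top * 1000.0 / gene.transcript_length
            correct_at_top[gene.n_exons].append(p is None or p < top_rpke)
    return BenchmarkResult(
        accuracy_at_level={c: accuracy_at(poffs[c], level_rpke)
                           for c in categories},
        plateau_accuracy={c: sum(correct_at_top[c]) / len(correct_at_top[c])
                          for c in categories},
        level_rpke=level_rpke,
        poffs=poffs,
    )


@dataclass
class FalsePositiveAudit:
    """Assembled genes not explained one-to-one by a truth locus."""

    n_truth: int
    n_assembled: int
    unmatched_assembled: int  # overlap no truth locus at all
    split_extras: int  # truth loci reported as >1 gene (extras beyond first)

    @property
    def extras(self) -> int:
        return self.unmatched_assembled + self.split_extras


def false_positive_audit(
    truth: Sequence[SimGene], assembled: Sequence[GeneModel]
) -> FalsePositiveAudit:
    """Audit an assembly against the inserted truth loci.

    Counts assembled genes overlapping no truth locus, plus the surplus
    genes where a single truth locus was reported as several.
    """
    per_truth = {g.gene_id: 0 for g in truth}
    unmatched = 0
    for a in assembled:
        hits = [
            t for t in truth
            if t.chrom == a.chrom and a.start < t.span[1] and t.span[0] < a.end
        ]
        if not hits:
            unmatched += 1
        else:
            for t in hits:
                per_truth[t.gene_id] += 1
    split_extras = sum(max(0, n - 1) for n in per_truth.values())
    return FalsePositiveAudit(
        n_truth=len(truth), n_assembled=len(assembled),
        unmatched_assembled=unmatched, split_extras=split_extras,
    )
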