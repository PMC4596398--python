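"""Input/output for alignments, junction files, GTF gene models and annotations.

All coordinates are handled internally as 0-based, half-open intervals.
Conversion to and from the 1-based inclusive convention of GTF happens only
at the file boundary; BED is already 0-based half-open.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

import pysam

logger = logging.getLogger(__name__)

__all__ = [
    "ReadBlock",
    "Junction",
    "GeneModel",
    "AnnotationGene",
    "read_alignments",
    "junctions_from_alignments",
    "read_junctions_bed",
    "write_gtf",
    "read_gtf",
    "read_annotation",
    "load_genome",
]


def load_genome(path: str | Path) -> dict[str, str]:
    """Load a FASTA genome as a chromosome -> sequence mapping."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


@dataclass(frozen=True)
class ReadBlock:
    """One aligned, ungapped block of a read on the genome.

    A spliced read (CIGAR with ``N`` gaps) contributes one block per matched
    segment; blocks from the same read share ``read_id``.
    """

    chrom: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    read_id: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty block {self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Junction:
    """An intron call: the gap an aligner split a read across.

    ``donor_end`` is the 0-based exclusive end of the upstream exonic side;
    ``acceptor_start`` the 0-based inclusive start of the downstream side, so
    the intron occupies ``[donor_end, acceptor_start)``.
    """

    chrom: str
    donor_end: int
    acceptor_start: int
    support: int = 1

    def __post_init__(self) -> None:
        if self.acceptor_start <= self.donor_end:
            raise ValueError(
                f"junction span must be >= 1 nt "
                f"({self.donor_end}..{self.acceptor_start})"
            )
        if self.support < 1:
            raise ValueError("junction support must be >= 1")

    @property
    def span(self) -> int:
        """Intron length in nt."""
        return self.acceptor_start - self.donor_end


@dataclass
class GeneModel:
    """An assembled single-isoform transcript.

    ``exons`` are sorted, non-overlapping half-open intervals; adjacent exons
    are separated exactly by one junction in ``junctions_used``.
    """

    chrom: str
    exons: list[tuple[int, int]]
    junctions_used: list[Junction] = field(default_factory=list)
    read_count: int = 0
    rpke: float = 0.0
    strand: str = "."
    gene_id: str = ""

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def footprint_nt(self) -> int:
        """Total exonic length in nt (not genomic span)."""
        return sum(e - s for s, e in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def validate(self) -> None:
        if not self.exons:
            raise ValueError("gene model has no exons")
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if e1 <= s1 or e2 <= s2 or s2 < e1:
                raise ValueError(f"exons not sorted/disjoint: {self.exons}")


@dataclass
class AnnotationGene:
    """A gene from an existing annotation, reduced to its genomic span."""

    chrom: str
    start: int
    end: int
    gene_id: str
    exons: list[tuple[int, int]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# alignments
# ---------------------------------------------------------------------------


def read_alignments(path: str | Path, min_mapq: int = 0) -> Iterator[ReadBlock]:
    """Stream aligned blocks from a SAM/BAM file.

    Unmapped, secondary and supplementary records are skipped; each retained
    primary alignment is counted once at its reported position. Spliced
    alignments yield one block per CIGAR match segment.
    """
    with pysam.AlignmentFile(str(path), check_sq=False) as af:
        for i, rec in enumerate(af):
            try:
                if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                    continue
                if rec.mapping_quality < min_mapq:
                    continue
                # merge blocks contiguous on the reference (e.g. across
                # insertions): a block boundary means a reference gap
                merged: list[list[int]] = []
                for start, end in rec.get_blocks():
                    if merged and start == merged[-1][1]:
                        merged[-1][1] = end
                    else:
                        merged.append([start, end])
                for start, end in merged:
                    yield ReadBlock(rec.reference_name, start, end, rec.query_name)
            except (ValueError, TypeError) as exc:  # pragma: no cover - defensive
                raise ValueError(f"unparseable alignment record #{i}: {exc}") from exc


def junctions_from_alignments(
    path: str | Path, min_mapq: int = 0
) -> list[Junction]:
    """Derive junctions from N-gaps in spliced alignments.

    Fallback for when no junction file accompanies the alignments; a junction
    file from the aligner is preferred when available.
    """
    support: dict[tuple[str, int, int], int] = {}
    with pysam.AlignmentFile(str(path), check_sq=False) as af:
        for rec in af:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if rec.mapping_quality < min_mapq:
                continue
            blocks = rec.get_blocks()
            for (s1, e1), (s2, e2) in zip(blocks, blocks[1:]):
                if s2 > e1:  # reference gap => intron
                    key = (rec.reference_name, e1, s2)
                    support[key] = support.get(key, 0) + 1
    return [
        Junction(chrom, d, a, n) for (chrom, d, a), n in sorted(support.items())
    ]


# ---------------------------------------------------------------------------
# junction BED (BED12, two blocks per record, score = supporting reads)
# ---------------------------------------------------------------------------


def read_junctions_bed(path: str | Path) -> list[Junction]:
    """Parse a BED12 junction file (``junctions.bed`` dialect).

    Each record has two blocks flanking the intron. The junction's donor end
    is ``chromStart + blockSize1``; its acceptor start is
    ``chromStart + blockStart2``; the score field carries the supporting-read
    count. Records with a block count other than two are skipped with a
    warning; structurally malformed lines are a hard error.
    """
    junctions: list[Junction] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ValueError(f"{path}:{lineno}: expected 12 BED fields")
            try:
                chrom = fields[0]
                chrom_start = int(fields[1])
                score = int(float(fields[3 + 1]))  # score column (5th field)
                block_count = int(fields[9])
                block_sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
                block_starts = [int(x) for x in fields[11].rstrip(",").split(",")]
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed BED line: {exc}") from exc
            if block_count != 2 or len(block_sizes) != 2 or len(block_starts) != 2:
                logger.warning("%s:%d: %d blocks, expected 2; skipped",
                               path, lineno, block_count)
                continue
            donor_end = chrom_start + block_sizes[0]
            acceptor_start = chrom_start + block_starts[1]
            junctions.append(
                Junction(chrom, donor_end, acceptor_start, max(score, 1))
            )
    return junctions


# ---------------------------------------------------------------------------
# GTF gene models
# ---------------------------------------------------------------------------

_ATTR_RE = re.compile(r'(\w+) "([^"]*)";?')


def _format_attrs(**attrs: object) -> str:
    return " ".join(f'{k} "{v}";' for k, v in attrs.items())


def write_gtf(genes: Iterable[GeneModel], path: str | Path,
              source: str = "exontile") -> None:
    """Write gene models as GTF: one ``transcript`` line plus per-exon
    ``exon`` lines, 1-based inclusive coordinates.

    Read count, RPKE and per-intron junction supports are emitted as
    attributes so that :func:`read_gtf` round-trips models losslessly.
    """
    with open(path, "w") as fh:
        for i, gene in enumerate(genes):
            gene.validate()
            gid = gene.gene_id or f"gene_{i + 1}"
            supports = ",".join(str(j.support) for j in gene.junctions_used)
            attrs = _format_attrs(
                gene_id=gid, transcript_id=f"{gid}.1",
                read_count=gene.read_count, rpke=f"{gene.rpke:.17g}",
                junction_supports=supports,
            )
            fh.write("\t".join([
                gene.chrom, source, "transcript",
                str(gene.start + 1), str(gene.end), ".",
                gene.strand if gene.strand in "+-" else ".", ".", attrs,
            ]) + "\n")
            for s, e in gene.exons:
                fh.write("\t".join([
                    gene.chrom, source, "exon", str(s + 1), str(e), ".",
                    gene.strand if gene.strand in "+-" else ".", ".", attrs,
                ]) + "\n")


def read_gtf(path: str | Path) -> list[GeneModel]:
    """Read gene models from GTF, grouping exons by ``transcript_id``.

    Multi-isoform files yield one model per transcript. Junctions are
    reconstructed between adjacent exons; supports come from the
    ``junction_supports`` attribute when present, else default to 1.
    """
    transcripts: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GTF columns")
            chrom, _src, ftype, start, end, _score, strand, _frame, attr_s = fields
            attrs = dict(_ATTR_RE.findall(attr_s))
            tid = attrs.get("transcript_id") or attrs.get("gene_id")
            if tid is None:
                raise ValueError(f"{path}:{lineno}: no transcript_id/gene_id")
            if tid not in transcripts:
                transcripts[tid] = {
                    "chrom": chrom, "strand": strand, "exons": [], "attrs": attrs,
                }
                order.append(tid)
            if ftype == "exon":
                transcripts[tid]["exons"].append((int(start) - 1, int(end)))

    genes: list[GeneModel] = []
    for tid in order:
        t = transcripts[tid]
        exons = sorted(t["exons"])
        if not exons:
            continue
        attrs = t["attrs"]
        supports_s = attrs.get("junction_supports", "")
        supports = [int(x) for x in supports_s.split(",") if x] or None
        junctions = []
        for k, ((_, e1), (s2, _)) in enumerate(zip(exons, exons[1:])):
            sup = supports[k] if supports and k < len(supports) else 1
            junctions.append(Junction(t["chrom"], e1, s2, sup))
        gene = GeneModel(
            chrom=t["chrom"], exons=exons, junctions_used=junctions,
            read_count=int(attrs.get("read_count", 0)),
            rpke=float(attrs.get("rpke", 0.0)),
            strand=t["strand"] if t["strand"] in "+-" else ".",
            gene_id=attrs.get("gene_id", tid),
        )
        gene.validate()
        genes.append(gene)
    return genes


# ---------------------------------------------------------------------------
# annotation (GTF or GFF3), span-level view
# ---------------------------------------------------------------------------


def read_annotation(path: str | Path) -> list[AnnotationGene]:
    """Read an annotation (GFF3 or GTF) as span-level genes.

    Parsed with :mod:`gffutils` (in-memory database). ``gene`` features
    define spans directly; GTF files without explicit gene features get
    gene extents inferred from their transcripts by gffutils. Exon
    intervals are attached when present.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[AnnotationGene] = []
    feature_types = set(db.featuretypes())
    if "gene" in feature_types:
        gene_features = db.features_of_type("gene")
    else:  # fall back to top-level transcripts
        gene_features = (
            f for t in ("mRNA", "transcript") if t in feature_types
            for f in db.features_of_type(t)
        )
    for f in gene_features:
        exons = sorted(
            (c.start - 1, c.end) for c in db.children(f, featuretype="exon")
        )
        genes.append(
            AnnotationGene(f.seqid, f.start - 1, f.end, f.id, exons)
        )
    return genes
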