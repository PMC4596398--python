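"""Longest-ORF analysis of assembled transcripts.

Transcripts are unstranded (assembly uses no strand information), so the
spliced sequence is scanned in all six frames — three on the given
sequence and three on its reverse complement. An ORF runs from an ATG to
the first in-frame stop; its length in codons excludes the stop. ORFs
shorter than ~40 codons are unlikely to be protein-coding (random sequence
rarely stays stop-free beyond ~50 codons), so short calls are labelled
likely non-coding.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from Bio.Seq import Seq

from .io_formats import GeneModel

__all__ = [
    "OrfCall",
    "splice_sequence",
    "longest_orf",
    "classify_coding",
    "orf_histogram",
    "translate_orf",
]

_STOPS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class OrfCall:
    """The longest open reading frame found in a transcript.

    ``start``/``end`` are half-open codon-aligned coordinates on the strand
    the ORF was found on (``+`` = the sequence as given, ``-`` = its
    reverse complement); ``end`` includes the stop codon when present.
    """

    gene_id: str
    strand: str  # '+' or '-'
    frame: int  # 0..2 on the reported strand
    start: int
    end: int
    length_codons: int  # ATG through last sense codon, stop excluded
    has_stop: bool


def splice_sequence(gene: GeneModel, genome: Mapping[str, str]) -> str:
    """Concatenate a gene's exon sequences in genomic order (introns removed).

    Reverse-complementation is left to the six-frame scan.
    """
    if not gene.exons:
        raise ValueError(f"gene {gene.gene_id or '<unnamed>'} has no exons")
    try:
        chrom_seq = genome[gene.chrom]
    except KeyError as exc:
        raise KeyError(f"chromosome {gene.chrom!r} not in genome") from exc
    return "".join(chrom_seq[s:e] for s, e in gene.exons).upper()


def _scan_frame(seq: str, frame: int) -> tuple[int, int, int, bool] | None:
    """Longest ORF in one frame: (start, end, codons, has_stop) or None."""
    best: tuple[int, int, int, bool] | None = None
    open_start: int | None = None
    i = frame
    while i + 3 <= len(seq):
        codon = seq[i:i + 3]
        if open_start is None and codon == "ATG":
            open_start = i
        elif open_start is not None and codon in _STOPS:
            codons = (i - open_start) // 3
            if best is None or codons > best[2]:
                best = (open_start, i + 3, codons, True)
            open_start = None
        i += 3
    if open_start is not None:  # ran off the end without a stop
        codons = (i - open_start) // 3
        if best is None or codons > best[2]:
            best = (open_start, i, codons, False)
    return best


def longest_orf(seq: str, gene_id: str = "") -> OrfCall:
    """Longest ORF over six frames (three per strand).

    Stop-free ORFs reaching the sequence end are allowed but flagged
    ``has_stop=False``. Ties break toward the forward strand, then the
    earliest start coordinate. A sequence with no ATG yields a zero-length
    call.
    """
    if len(seq) < 3:
        raise ValueError("sequence shorter than one codon")
    seq = seq.upper()
    rc = str(Seq(seq).reverse_complement())
    best: OrfCall | None = None
    for strand, s in (("+", seq), ("-", rc)):
        for frame in range(3):
            hit = _scan_frame(s, frame)
            if hit is None:
                continue
            start, end, codons, has_stop = hit
            call = OrfCall(gene_id, strand, frame, start, end, codons, has_stop)
            if best is None or codons > best.length_codons:
                best = call
    if best is None:
        return OrfCall(gene_id, "+", 0, 0, 0, 0, False)
    return best


def translate_orf(seq: str, call: OrfCall) -> str:
    """Peptide for an ORF call (stop not included)."""
    s = seq.upper() if call.strand == "+" else str(Seq(seq.upper()).reverse_complement())
    coding = s[call.start:call.start + 3 * call.length_codons]
    return str(Seq(coding).translate())


def classify_coding(
    calls: Sequence[OrfCall], min_codons: int = 40
) -> list[tuple[OrfCall, str]]:
    """Label calls ``likely coding`` (>= ``min_codons``) or ``likely non-coding``."""
    return [
        (c, "likely coding" if c.length_codons >= min_codons
         else "likely non-coding")
        for c in calls
    ]


def orf_histogram(calls: Sequence[OrfCall], bin_codons: int = 80) -> dict[tuple[int, int], int]:
    """Histogram of ORF lengths in ``bin_codons``-wide bins."""
    hist: dict[tuple[int, int], int] = {}
    for c in calls:
        b = c.length_codons // bin_codons
        key = (b * bin_codons, (b + 1) * bin_codons)
        hist[key] = hist.get(key, 0) + 1
    return dict(sorted(hist.items()))
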