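"""Shared fixtures: tiny SAM/BED/GTF builders and toy gene models."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pytest
from hypothesis import settings

from exontile.io_formats import GeneModel, Junction, ReadBlock

# Property tests must be reproducible run to run.
settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def make_sam(path: Path, records: list[tuple], chroms: dict[str, int]) -> Path:
    """Write a minimal SAM file.

    Each record is (qname, flag, chrom, pos_1based, cigar); mapq fixed at 50
    unless a 6th element overrides it.
    """
    lines = ["@HD\tVN:1.6\tSO:coordinate"]
    for name, length in chroms.items():
        lines.append(f"@SQ\tSN:{name}\tLN:{length}")
    for rec in records:
        qname, flag, chrom, pos, cigar = rec[:5]
        mapq = rec[5] if len(rec) > 5 else 50
        seq_len = _query_length(cigar)
        seq = "A" * seq_len if seq_len else "*"
        lines.append(
            f"{qname}\t{flag}\t{chrom}\t{pos}\t{mapq}\t{cigar}\t*\t0\t0\t{seq}\t*"
        )
    path.write_text("\n".join(lines) + "\n")
    return path


def _query_length(cigar: str) -> int:
    if cigar == "*":
        return 0
    total = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            if ch in "MIS=X":
                total += int(num)
            num = ""
    return total


def make_junction_bed(path: Path, junctions: list[Junction]) -> Path:
    """Write junctions as BED12 records (two blocks flanking the intron)."""
    flank = 20
    lines = []
    for i, j in enumerate(junctions):
        chrom_start = j.donor_end - flank
        chrom_end = j.acceptor_start + flank
        block_starts = f"0,{j.acceptor_start - chrom_start}"
        lines.append("\t".join([
            j.chrom, str(chrom_start), str(chrom_end), f"JUNC{i:05d}",
            str(j.support), "+", str(chrom_start), str(chrom_end), "255,0,0",
            "2", f"{flank},{flank}", block_starts,
        ]))
    path.write_text("\n".join(lines) + "\n")
    return path


def blocks_for_interval(chrom: str, start: int, end: int, n_reads: int,
                        read_len: int = 50, prefix: str = "r") -> list[ReadBlock]:
    """Evenly spaced reads tiling [start, end); the last read is clamped."""
    span = end - start - read_len
    out = []
    for i in range(n_reads):
        s = start + (round(i * span / max(1, n_reads - 1)) if n_reads > 1 else 0)
        out.append(ReadBlock(chrom, s, s + read_len, f"{prefix}{i}"))
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def toy_gene() -> GeneModel:
    g = GeneModel(
        chrom="chr1",
        exons=[(100, 300), (500, 700), (900, 1000)],
        junctions_used=[Junction("chr1", 300, 500, 10),
                        Junction("chr1", 700, 900, 8)],
        read_count=120,
        strand=".",
        gene_id="toy1",
    )
    g.rpke = g.read_count * 1000.0 / g.footprint_nt
    return g
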