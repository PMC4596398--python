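"""Exon pipeline tests: tiling, short-exon inference, merging, splitting.

Each operation is checked against an independent brute-force oracle on
randomized inputs, plus the documented boundary behaviours.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from exontile.exon_detection import (
    CoverageIndex,
    ExonFragment,
    combine_fragments,
    infer_short_exons,
    merge_close_fragments,
    split_at_internal_junctions,
    tile_fragments,
)
from exontile.io_formats import Junction, ReadBlock

from conftest import blocks_for_interval


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------


def brute_force_segmentation(blocks, chrom, genome_len=200_000):
    """Per-base depth array; maximal runs of depth >= 1 with read counts."""
    depth = np.zeros(genome_len, dtype=int)
    for b in blocks:
        if b.chrom == chrom:
            depth[b.start:b.end] += 1
    segs = []
    in_run = False
    for pos in range(genome_len):
        if depth[pos] > 0 and not in_run:
            start, in_run = pos, True
        elif depth[pos] == 0 and in_run:
            segs.append((start, pos))
            in_run = False
    if in_run:
        segs.append((start, genome_len))
    out = []
    for s, e in segs:
        reads = {b.read_id for b in blocks
                 if b.chrom == chrom and b.start < e and b.end > s}
        out.append((s, e, len(reads)))
    return out


def transitive_merge_oracle(intervals, max_gap):
    """Merge any two intervals with gap <= max_gap until fixpoint."""
    items = sorted(intervals)
    changed = True
    while changed:
        changed = False
        for i in range(len(items) - 1):
            s1, e1 = items[i]
            s2, e2 = items[i + 1]
            if s2 - e1 <= max_gap:
                items[i:i + 2] = [(s1, max(e1, e2))]
                changed = True
                break
    return items


# ---------------------------------------------------------------------------
# CoverageIndex
# ---------------------------------------------------------------------------


random_blocks = st.lists(
    st.tuples(st.integers(0, 5_000), st.integers(1, 120)),
    min_size=0, max_size=60,
)


@settings(max_examples=50, deadline=None)
@given(random_blocks)
def test_tiling_matches_per_base_coverage_oracle(spec):
    """Random block sets segment identically to a per-base depth array."""
    blocks = [ReadBlock("c", s, s + l, f"r{i}") for i, (s, l) in enumerate(spec)]
    cov = CoverageIndex(blocks)
    frags = tile_fragments(cov, min_rpke=0.0)
    oracle = brute_force_segmentation(blocks, "c", genome_len=6_000)
    assert [(f.start, f.end, f.read_count) for f in frags] == oracle


def test_depth_mass_conservation(rng):
    blocks = [ReadBlock("c", int(s), int(s) + 50, f"r{i}")
              for i, s in enumerate(rng.integers(0, 10_000, 200))]
    cov = CoverageIndex(blocks)
    assert cov.total_block_nt() == 200 * 50


def test_empty_coverage_gives_no_fragments():
    assert tile_fragments(CoverageIndex([]), min_rpke=50) == []


# ---------------------------------------------------------------------------
# tiling + RPKE threshold
# ---------------------------------------------------------------------------


def test_rpke_definition_at_threshold():
    """50 overlapping 50-nt reads over 1,000 nt give RPKE exactly 50: kept."""
    blocks = blocks_for_interval("c", 1000, 2000, 50)
    frags = tile_fragments(CoverageIndex(blocks), min_rpke=50)
    assert len(frags) == 1
    f = frags[0]
    assert (f.start, f.end, f.read_count) == (1000, 2000, 50)
    assert f.rpke == pytest.approx(50.0)


def test_rpke_below_threshold_dropped():
    """49 reads over the same 1,000 nt fall below the floor and are dropped."""
    blocks = blocks_for_interval("c", 1000, 2000, 49)
    assert tile_fragments(CoverageIndex(blocks), min_rpke=50) == []


def test_rpke_scaling_linear_in_reads_inverse_in_length():
    """RPKE doubles with read count and halves with fragment length."""
    f1 = tile_fragments(CoverageIndex(blocks_for_interval("c", 0, 1000, 100)),
                        min_rpke=0)[0]
    f2 = tile_fragments(CoverageIndex(blocks_for_interval("c", 0, 1000, 200)),
                        min_rpke=0)[0]
    f3 = tile_fragments(CoverageIndex(blocks_for_interval("c", 0, 500, 100)),
                        min_rpke=0)[0]
    assert f2.rpke == pytest.approx(2 * f1.rpke)
    assert f3.rpke == pytest.approx(2 * f1.rpke, rel=0.02)


def test_rpkm_equivalent_screen():
    """With ~151.5M mapped reads, 1.0 RPKM corresponds to ~150 RPKE, so an
    RPKE floor of 150 reproduces an RPKM >= 1.0 screen for that library."""
    library_reads = 151_492_182
    rpkm_floor = 1.0
    rpke_equiv = rpkm_floor * library_reads / 1e6
    assert rpke_equiv == pytest.approx(150, rel=0.02)
    blocks = blocks_for_interval("c", 0, 1000, 155)
    assert tile_fragments(CoverageIndex(blocks), min_rpke=rpke_equiv)
    blocks = blocks_for_interval("c", 0, 1000, 145)
    assert not tile_fragments(CoverageIndex(blocks), min_rpke=rpke_equiv)


# ---------------------------------------------------------------------------
# short exon inference
# ---------------------------------------------------------------------------


def test_short_exon_inferred_between_junction_pair():
    """Junctions ending at 1000 and starting at 1030 flank a 30-nt exon."""
    j1 = Junction("c", 500, 1000, 5)
    j2 = Junction("c", 1030, 1500, 5)
    (frag,) = infer_short_exons([j1, j2], read_len=50, cov=CoverageIndex([]))
    assert (frag.start, frag.end) == (1000, 1030)
    assert frag.origin == "junction_inferred"
    assert frag.read_count == 0  # no direct coverage required


def test_gap_at_read_length_not_inferred():
    """An 80-nt inter-junction stretch >= read length is left to tiling."""
    j1 = Junction("c", 500, 1000, 5)
    j2 = Junction("c", 1080, 1500, 5)
    assert infer_short_exons([j1, j2], read_len=50, cov=CoverageIndex([])) == []


def test_inferred_exon_duplicate_suppressed():
    j1 = Junction("c", 500, 1000, 5)
    j2 = Junction("c", 1030, 1500, 5)
    cov = CoverageIndex(blocks_for_interval("c", 990, 1060, 20))
    tiled = tile_fragments(cov, min_rpke=0)
    inferred = infer_short_exons([j1, j2], read_len=50, cov=cov)
    combined = combine_fragments(tiled, inferred)
    assert combined == tiled  # inferred exon lies inside the tiled fragment


def test_cross_chromosome_junctions_not_paired():
    j1 = Junction("c1", 500, 1000, 5)
    j2 = Junction("c2", 1030, 1500, 5)
    assert infer_short_exons([j1, j2], read_len=50, cov=CoverageIndex([])) == []


# ---------------------------------------------------------------------------
# merging
# ---------------------------------------------------------------------------


def _frag(s, e, n=10, chrom="c"):
    return ExonFragment(chrom, s, e, n, n * 1000.0 / (e - s))


def test_merge_within_gap():
    """Fragments 40 nt apart coalesce into one spanning fragment."""
    merged = merge_close_fragments([_frag(100, 200), _frag(240, 300)], max_gap=50)
    assert [(f.start, f.end) for f in merged] == [(100, 300)]
    assert merged[0].read_count == 20
    assert merged[0].rpke == pytest.approx(20 * 1000 / 200)


def test_merge_boundary_gap_51_stays_split():
    merged = merge_close_fragments([_frag(100, 200), _frag(251, 300)], max_gap=50)
    assert len(merged) == 2


@settings(max_examples=60, deadline=None)
@given(
    st.lists(st.tuples(st.integers(1, 300), st.integers(10, 200)),
             min_size=1, max_size=20),
    st.integers(0, 100),
)
def test_merge_equals_transitive_closure_oracle(spec, max_gap):
    """Randomized disjoint fragment lists merge exactly like the
    repeated-pairwise-union oracle, and merging is idempotent."""
    frags, pos = [], 0
    for gap, length in spec:
        pos += gap
        frags.append(_frag(pos, pos + length, n=5))
        pos += length
    merged = merge_close_fragments(frags, max_gap)
    oracle = transitive_merge_oracle([(f.start, f.end) for f in frags], max_gap)
    assert [(f.start, f.end) for f in merged] == oracle
    assert merge_close_fragments(merged, max_gap) == merged
    # disjointness is preserved
    for a, b in zip(merged, merged[1:]):
        assert b.start > a.end


# ---------------------------------------------------------------------------
# splitting and trimming
# ---------------------------------------------------------------------------


def _retention_scenario(intron_reads: int):
    """One merged fragment (0,500) containing the intron (200,300): dense
    exonic coverage on (0,200) and (300,500), a variable number of
    intron-retention reads bridging the intron."""
    blocks = blocks_for_interval("c", 0, 250, 50, prefix="L", read_len=50)
    blocks = [b for b in blocks if b.start < 200]  # exonic left side only
    right = blocks_for_interval("c", 250, 500, 60, prefix="R", read_len=50)
    blocks += [b for b in right if b.start >= 300]
    blocks += blocks_for_interval("c", 180, 340, intron_reads, prefix="I",
                                  read_len=40)
    cov = CoverageIndex(blocks)
    frag = _frag(0, 500, len(blocks))
    j = Junction("c", 200, 300, 40)
    return frag, j, cov


def test_split_when_intron_density_low():
    """Sparse intronic reads vs dense flanks: the junction wins, the
    fragment is cut into its exonic sides."""
    frag, j, cov = _retention_scenario(intron_reads=3)
    out = split_at_internal_junctions([frag], [j], cov, density_ratio=0.5)
    assert [(f.start, f.end) for f in out] == [(0, 200), (300, 500)]
    assert all(f.origin == "split" for f in out)


def test_no_split_when_intron_retained():
    """Intronic read density comparable to the flanks: the longest
    (intron-retaining) form is kept intact."""
    frag, j, cov = _retention_scenario(intron_reads=40)
    out = split_at_internal_junctions([frag], [j], cov, density_ratio=0.5)
    assert [(f.start, f.end) for f in out] == [(0, 500)]


def test_no_internal_junctions_identity():
    frag = _frag(0, 500)
    cov = CoverageIndex(blocks_for_interval("c", 0, 500, 20))
    j = Junction("c", 600, 900, 5)  # outside the fragment
    out = split_at_internal_junctions([frag], [j], cov)
    assert [(f.start, f.end) for f in out] == [(0, 500)]


def test_half_inside_junction_not_split():
    frag = _frag(100, 500)
    cov = CoverageIndex(blocks_for_interval("c", 100, 500, 20))
    j = Junction("c", 50, 300, 5)  # donor side outside the fragment
    out = split_at_internal_junctions([frag], [j], cov)
    assert [(f.start, f.end) for f in out] == [(100, 500)]


def test_split_is_idempotent():
    frag, j, cov = _retention_scenario(intron_reads=3)
    once = split_at_internal_junctions([frag], [j], cov)
    twice = split_at_internal_junctions(once, [j], cov)
    assert twice == once


def test_trim_snaps_boundary_to_connecting_junction():
    """A fragment end that overshoots a junction donor by < read_len is
    snapped back to the junction edge; the downstream partner's start
    likewise."""
    blocks = blocks_for_interval("c", 0, 210, 40, prefix="L")
    blocks += blocks_for_interval("c", 295, 500, 40, prefix="R")
    cov = CoverageIndex(blocks)
    frags = [_frag(0, 210, 40), _frag(295, 500, 40)]
    j = Junction("c", 200, 300, 25)
    out = split_at_internal_junctions(frags, [j], cov, read_len=50)
    assert [(f.start, f.end) for f in out] == [(0, 200), (300, 500)]


def test_terminal_ends_never_trimmed():
    """With no connecting partner on the far side, a boundary near a
    junction edge stays where the coverage put it."""
    frags = [_frag(0, 210, 40)]
    cov = CoverageIndex(blocks_for_interval("c", 0, 210, 40))
    j = Junction("c", 200, 300, 25)  # nothing downstream to connect to
    out = split_at_internal_junctions(frags, [j], cov, read_len=50)
    assert [(f.start, f.end) for f in out] == [(0, 210)]


def test_fragments_disjoint_after_each_stage(rng):
    """Pipeline stages preserve fragment disjointness on random input."""
    blocks = [ReadBlock("c", int(s), int(s) + 50, f"r{i}")
              for i, s in enumerate(rng.integers(0, 20_000, 400))]
    cov = CoverageIndex(blocks)
    frags = tile_fragments(cov, min_rpke=0)
    junctions = [Junction("c", int(d), int(d) + 200, 5)
                 for d in rng.integers(0, 20_000, 10)]
    for stage in (
        combine_fragments(frags, infer_short_exons(junctions, 50, cov)),
        merge_close_fragments(frags, 50),
        split_at_internal_junctions(frags, junctions, cov),
    ):
        ordered = sorted(stage, key=lambda f: (f.chrom, f.start))
        for a, b in zip(ordered, ordered[1:]):
            assert b.start >= a.end or a.chrom != b.chrom
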