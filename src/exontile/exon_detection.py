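"""Exon detection from read coverage and splice junctions.

Candidate exons are found in four fixed stages:

1. **Tiling** — maximal intervals of overlapping read blocks, kept when
   their expression is at least ``min_rpke`` (reads per kilobase of exon).
2. **Short-exon recovery** — exons shorter than a read rarely accumulate
   direct alignments; they are inferred from pairs of junctions whose
   exonic gap is shorter than the read length.
3. **Merging** — fragments separated by small coverage gaps (low-depth
   artefacts) are coalesced when the gap is at most ``max_gap`` nt.
4. **Split/trim** — fragments containing both sides of a junction are cut
   at the junction boundaries when intronic read density is low relative to
   the flanking exonic density (intron retention and pre-mRNA noise
   adjudication); fragment boundaries near junction edges are snapped to
   them.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .io_formats import Junction, ReadBlock

__all__ = [
    "CoverageIndex",
    "ExonFragment",
    "tile_fragments",
    "infer_short_exons",
    "combine_fragments",
    "merge_close_fragments",
    "split_at_internal_junctions",
]


@dataclass(frozen=True)
class ExonFragment:
    """A candidate exon interval with its read support.

    ``read_count`` is the number of distinct reads overlapping the interval
    by at least one base; ``rpke`` = read_count x 1000 / length.
    """

    chrom: str
    start: int
    end: int
    read_count: int
    rpke: float
    origin: str = "tiling"  # tiling | junction_inferred | merged | split

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty fragment {self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start


def rpke(read_count: int, length_nt: int) -> float:
    """Reads per kilobase of exon."""
    if length_nt <= 0:
        raise ValueError("length must be positive")
    return read_count * 1000.0 / length_nt


class CoverageIndex:
    """Per-chromosome index of aligned read blocks.

    Supports the coverage queries the exon pipeline needs: maximal covered
    intervals, distinct-read counts over an interval, and read-start
    densities (used by the intron-retention density rule).
    """

    def __init__(self, blocks: Iterable[ReadBlock] = ()) -> None:
        per_chrom: dict[str, list[tuple[int, int, str]]] = {}
        for b in blocks:
            per_chrom.setdefault(b.chrom, []).append((b.start, b.end, b.read_id))
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        self._read_idx: dict[str, np.ndarray] = {}
        self._read_ids: dict[str, list[str]] = {}
        self.total_blocks = 0
        for chrom, blk in per_chrom.items():
            blk.sort()
            ids: dict[str, int] = {}
            idx = np.empty(len(blk), dtype=np.int64)
            starts = np.empty(len(blk), dtype=np.int64)
            ends = np.empty(len(blk), dtype=np.int64)
            for i, (s, e, rid) in enumerate(blk):
                starts[i], ends[i] = s, e
                idx[i] = ids.setdefault(rid, len(ids))
            self._starts[chrom] = starts
            self._ends[chrom] = ends
            self._read_idx[chrom] = idx
            self._read_ids[chrom] = list(ids)
            self.total_blocks += len(blk)

    @property
    def chroms(self) -> list[str]:
        return sorted(self._starts)

    def total_block_nt(self) -> int:
        return int(sum((self._ends[c] - self._starts[c]).sum() for c in self._starts))

    def coverage_intervals(self, chrom: str) -> list[tuple[int, int]]:
        """Maximal intervals with depth >= 1, sorted and disjoint."""
        starts = self._starts.get(chrom)
        if starts is None or len(starts) == 0:
            return []
        ends = self._ends[chrom]
        out: list[tuple[int, int]] = []
        cur_s, cur_e = int(starts[0]), int(ends[0])
        for s, e in zip(starts[1:], ends[1:]):
            if s > cur_e:  # blocks sorted by start => gap closes the interval
                out.append((cur_s, cur_e))
                cur_s, cur_e = int(s), int(e)
            else:
                cur_e = max(cur_e, int(e))
        out.append((cur_s, cur_e))
        return out

    def _overlap_mask(self, chrom: str, start: int, end: int) -> np.ndarray:
        starts = self._starts.get(chrom)
        if starts is None:
            return np.zeros(0, dtype=bool)
        return (starts < end) & (self._ends[chrom] > start)

    def count_reads(self, chrom: str, start: int, end: int) -> int:
        """Distinct reads with >= 1 bp overlap with [start, end)."""
        mask = self._overlap_mask(chrom, start, end)
        if not mask.any():
            return 0
        return len(np.unique(self._read_idx[chrom][mask]))

    def count_reads_multi(self, chrom: str,
                          intervals: Sequence[tuple[int, int]]) -> int:
        """Distinct reads overlapping any of the intervals (counted once)."""
        idx = self._read_idx.get(chrom)
        if idx is None:
            return 0
        hit = np.zeros(len(idx), dtype=bool)
        for s, e in intervals:
            hit |= self._overlap_mask(chrom, s, e)
        if not hit.any():
            return 0
        return len(np.unique(idx[hit]))

    def start_density(self, chrom: str, start: int, end: int) -> float:
        """Read-block starts per nt within [start, end)."""
        if end <= start:
            return 0.0
        starts = self._starts.get(chrom)
        if starts is None:
            return 0.0
        n = int(np.searchsorted(starts, end) - np.searchsorted(starts, start))
        return n / (end - start)


# ---------------------------------------------------------------------------
# stage 1: tiling
# ---------------------------------------------------------------------------


def tile_fragments(cov: CoverageIndex, min_rpke: float = 50.0) -> list[ExonFragment]:
    """Detect candidate exons as maximal covered intervals, filtered by RPKE.

    The RPKE floor (default 50) rejects intervals whose read support is in
    the range produced by stray/noise alignments.
    """
    frags: list[ExonFragment] = []
    for chrom in cov.chroms:
        for s, e in cov.coverage_intervals(chrom):
            n = cov.count_reads(chrom, s, e)
            r = rpke(n, e - s)
            if r >= min_rpke:
                frags.append(ExonFragment(chrom, s, e, n, r, origin="tiling"))
    return frags


# ---------------------------------------------------------------------------
# stage 2: short exons from junction pairs
# ---------------------------------------------------------------------------


def infer_short_exons(
    junctions: Sequence[Junction], read_len: int, cov: CoverageIndex
) -> list[ExonFragment]:
    """Infer exons shorter than a read from flanking junction pairs.

    For junctions J1, J2 on the same chromosome with
    ``0 < J2.donor_end - J1.acceptor_start < read_len``, the exonic stretch
    between them is emitted as an inferred exon. Such exons carry whatever
    coverage they happen to have (possibly none) and are exempt from the
    RPKE floor.
    """
    if read_len <= 0:
        raise ValueError("read_len must be positive")
    by_chrom: dict[str, list[Junction]] = {}
    for j in junctions:
        by_chrom.setdefault(j.chrom, []).append(j)
    out: list[ExonFragment] = []
    seen: set[tuple[str, int, int]] = set()
    for chrom, js in sorted(by_chrom.items()):
        acceptors = sorted({j.acceptor_start for j in js})
        donors = sorted({j.donor_end for j in js})
        donors_arr = np.asarray(donors, dtype=np.int64)
        for a in acceptors:
            lo = int(np.searchsorted(donors_arr, a, side="right"))
            hi = int(np.searchsorted(donors_arr, a + read_len, side="left"))
            for d in donors_arr[lo:hi]:
                key = (chrom, a, int(d))
                if key in seen:
                    continue
                seen.add(key)
                n = cov.count_reads(chrom, a, int(d))
                out.append(
                    ExonFragment(chrom, a, int(d), n, rpke(n, int(d) - a),
                                 origin="junction_inferred")
                )
    return out


def combine_fragments(
    tiled: Sequence[ExonFragment], inferred: Sequence[ExonFragment]
) -> list[ExonFragment]:
    """Union of tiled and inferred fragments, suppressing inferred duplicates.

    An inferred exon already contained in (or overlapping) a tiled fragment
    adds no information and is dropped; survivors are interleaved in
    coordinate order. Overlapping survivors never arise because inferred
    exons sit between junction edges, outside covered fragments.
    """
    kept = list(tiled)
    for f in inferred:
        if any(t.chrom == f.chrom and t.start < f.end and f.start < t.end
               for t in tiled):
            continue
        kept.append(f)
    return sorted(kept, key=lambda f: (f.chrom, f.start, f.end))


# ---------------------------------------------------------------------------
# stage 3: merging across small coverage gaps
# ---------------------------------------------------------------------------


def merge_close_fragments(
    frags: Sequence[ExonFragment], max_gap: int = 50
) -> list[ExonFragment]:
    """Coalesce consecutive fragments whose gap is <= ``max_gap`` nt.

    The merged fragment spans the gap (read-through assumption: the gap is
    taken to be a coverage hole inside one real exon). Read counts are
    summed and RPKE recomputed over the merged length. Idempotent.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    ordered = sorted(frags, key=lambda f: (f.chrom, f.start, f.end))
    out: list[ExonFragment] = []
    for f in ordered:
        if out and out[-1].chrom == f.chrom and f.start - out[-1].end <= max_gap:
            prev = out[-1]
            n = prev.read_count + f.read_count
            merged_origin = prev.origin if f.start <= prev.end else "merged"
            out[-1] = ExonFragment(
                f.chrom, prev.start, max(prev.end, f.end), n,
                rpke(n, max(prev.end, f.end) - prev.start), origin=merged_origin,
            )
        else:
            out.append(f)
    return out


# ---------------------------------------------------------------------------
# stage 4: split at internal junctions, trim to junction edges
# ---------------------------------------------------------------------------


def _intronic_density_ratio(
    cov: CoverageIndex, frag: ExonFragment, j: Junction, flank_window: int
) -> float:
    """Read-start density inside the putative intron relative to its flanks.

    Flanks are the up-to-``flank_window``-nt stretches of the fragment
    immediately adjacent to the intron. A ratio below the split threshold
    means the intron is mostly junction-spanned (reads inside it are
    retention/noise); a high ratio means genuine exonic coverage.
    """
    intron = cov.start_density(frag.chrom, j.donor_end, j.acceptor_start)
    left = (max(frag.start, j.donor_end - flank_window), j.donor_end)
    right = (j.acceptor_start, min(frag.end, j.acceptor_start + flank_window))
    widths = (left[1] - left[0]) + (right[1] - right[0])
    if widths <= 0:
        return 0.0 if intron == 0 else float("inf")
    n_starts = (
        cov.start_density(frag.chrom, *left) * (left[1] - left[0])
        + cov.start_density(frag.chrom, *right) * (right[1] - right[0])
    )
    flank = n_starts / widths
    if flank == 0:
        return 0.0 if intron == 0 else float("inf")
    return intron / flank


def _split_one(
    frag: ExonFragment,
    junctions: Sequence[Junction],
    cov: CoverageIndex,
    density_ratio: float,
    flank_window: int,
) -> list[ExonFragment]:
    pieces: list[ExonFragment] = []
    cur = frag
    internal = sorted(
        (j for j in junctions
         if j.chrom == frag.chrom
         and frag.start < j.donor_end and j.acceptor_start < frag.end),
        key=lambda j: j.donor_end,
    )
    for j in internal:
        if not (cur.start < j.donor_end and j.acceptor_start < cur.end):
            continue  # consumed by an earlier cut
        ratio = _intronic_density_ratio(cov, cur, j, flank_window)
        if ratio < density_ratio:
            left_n = cov.count_reads(cur.chrom, cur.start, j.donor_end)
            pieces.append(
                ExonFragment(cur.chrom, cur.start, j.donor_end, left_n,
                             rpke(left_n, j.donor_end - cur.start), origin="split")
            )
            right_n = cov.count_reads(cur.chrom, j.acceptor_start, cur.end)
            cur = ExonFragment(cur.chrom, j.acceptor_start, cur.end, right_n,
                               rpke(right_n, cur.end - j.acceptor_start),
                               origin="split")
    pieces.append(cur)
    return pieces


def _trim_to_junction_edges(
    frags: list[ExonFragment],
    junctions: Sequence[Junction],
    cov: CoverageIndex,
    read_len: int,
) -> list[ExonFragment]:
    """Snap fragment boundaries within ``read_len`` of a junction edge.

    Only junctions that connect two distinct fragments trim; terminal gene
    ends (no connecting junction) are left as read coverage found them,
    since no junction evidence constrains them.
    """
    by_chrom: dict[str, list[int]] = {}
    for i, f in enumerate(frags):
        by_chrom.setdefault(f.chrom, []).append(i)
    bounds: dict[int, list[int]] = {i: [f.start, f.end] for i, f in enumerate(frags)}
    for j in junctions:
        idxs = by_chrom.get(j.chrom, [])
        donor_side = [
            i for i in idxs
            if abs(bounds[i][1] - j.donor_end) <= read_len
            and bounds[i][0] < j.donor_end
        ]
        acceptor_side = [
            i for i in idxs
            if abs(bounds[i][0] - j.acceptor_start) <= read_len
            and bounds[i][1] > j.acceptor_start
        ]
        donor_side = [i for i in donor_side if i not in acceptor_side]
        acceptor_side = [i for i in acceptor_side if i not in donor_side]
        if not donor_side or not acceptor_side:
            continue
        di = min(donor_side, key=lambda i: abs(bounds[i][1] - j.donor_end))
        ai = min(acceptor_side, key=lambda i: abs(bounds[i][0] - j.acceptor_start))
        if di == ai:
            continue

        def _clear(lo: int, hi: int, skip: int) -> bool:
            # an extension must not run into another fragment
            return lo >= hi or not any(
                bounds[k][0] < hi and bounds[k][1] > lo
                for k in idxs if k != skip
            )

        if _clear(bounds[di][1], j.donor_end, di):
            bounds[di][1] = j.donor_end
        if _clear(j.acceptor_start, bounds[ai][0], ai):
            bounds[ai][0] = j.acceptor_start
    out: list[ExonFragment] = []
    for i, f in enumerate(frags):
        s, e = bounds[i]
        if (s, e) == (f.start, f.end):
            out.append(f)
        else:
            n = cov.count_reads(f.chrom, s, e)
            out.append(ExonFragment(f.chrom, s, e, n, rpke(n, e - s),
                                    origin=f.origin))
    return out


def split_at_internal_junctions(
    frags: Sequence[ExonFragment],
    junctions: Sequence[Junction],
    cov: CoverageIndex,
    density_ratio: float = 0.5,
    flank_window: int = 50,
    read_len: int = 50,
) -> list[ExonFragment]:
    """Separate mistakenly merged exons at junction boundaries.

    A junction wholly inside one fragment marks a putative retained intron.
    When the intronic read-start density is below ``density_ratio`` of the
    flanking exonic density, the junction wins: the fragment is split into
    its two exonic sides and the intronic reads are discarded as retention
    or noise. Otherwise the intron-retaining (longest) form is kept.
    Fragment boundaries within ``read_len`` of the edge of a connecting
    junction are then snapped to that edge. Idempotent.
    """
    if not (0 < density_ratio <= 1):
        raise ValueError("density_ratio must be in (0, 1]")
    pieces: list[ExonFragment] = []
    for f in frags:
        pieces.extend(_split_one(f, junctions, cov, density_ratio, flank_window))
    pieces.sort(key=lambda f: (f.chrom, f.start, f.end))
    return _trim_to_junction_edges(pieces, junctions, cov, read_len)
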