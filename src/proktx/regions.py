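"""Strand-specific contiguously transcribed (CT) regions.

A CT region is a maximal strand-specific genomic span covered end to end by
overlapping reads — the unit of work for transcript prediction. Regions are
built by a strand-split interval union over the read intervals, optionally
subdivided wherever coverage drops below a minimum depth, and finally
filtered by the number of reads fully contained in them.

Reads that straddle a subdivision split point cannot be "completely
contained" in either side and are discarded from prediction (counted in
:attr:`SubdivisionResult.n_discarded_reads`). Because discarding reads can
itself lower depth below the cutoff, subdivision iterates to a fixed point.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .io import ReadInterval, RegionRecord

__all__ = [
    "CTRegion",
    "SubdivisionResult",
    "build_ct_regions",
    "subdivide_by_depth",
    "subdivide_all",
    "filter_regions",
    "regions_from_records",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True, slots=True)
class CTRegion:
    """A contiguously transcribed region and the reads fully contained in it."""

    contig: str
    start: int
    end: int
    strand: str
    reads: tuple[ReadInterval, ...]
    region_id: str = field(default="")

    def __post_init__(self) -> None:
        if self.end - self.start < 1:
            raise ValueError("region span must be >= 1")
        for r in self.reads:
            if not (self.start <= r.start and r.end <= self.end):
                raise ValueError(
                    f"read {r.read_id!r} [{r.start},{r.end}) not contained in "
                    f"region [{self.start},{self.end})"
                )
            if r.strand != self.strand:
                raise ValueError(f"read {r.read_id!r} strand mismatch")
        if not self.region_id:
            object.__setattr__(self, "region_id", default_region_id(self))

    @property
    def n_reads(self) -> int:
        return len(self.reads)

    @property
    def length(self) -> int:
        return self.end - self.start


def default_region_id(region: CTRegion) -> str:
    return f"{region.contig}:{region.start}-{region.end}({region.strand})"


def _sorted_reads(reads: Iterable[ReadInterval]) -> list[ReadInterval]:
    return sorted(reads, key=lambda r: (r.contig, r.strand, r.start, r.end, r.read_id))


def build_ct_regions(reads: Iterable[ReadInterval]) -> list[CTRegion]:
    """Partition reads into maximal runs of positive depth per (contig, strand).

    Equivalent to a strand-split interval merge of the read intervals:
    abutting half-open intervals ([0,10) and [10,20)) do not overlap and
    start separate regions. Each read is attached to the unique region that
    contains it. Output is sorted by (contig, start, strand).
    """
    regions: list[CTRegion] = []
    by_key: dict[tuple[str, str], list[ReadInterval]] = {}
    for r in reads:
        by_key.setdefault((r.contig, r.strand), []).append(r)
    for (contig, strand), group in sorted(by_key.items()):
        group = _sorted_reads(group)
        run_start, run_end = group[0].start, group[0].end
        members: list[ReadInterval] = []
        for r in group:
            if r.start < run_end:  # strict overlap; abutting reads split
                run_end = max(run_end, r.end)
                members.append(r)
            else:
                regions.append(CTRegion(contig, run_start, run_end, strand, tuple(members)))
                run_start, run_end = r.start, r.end
                members = [r]
        regions.append(CTRegion(contig, run_start, run_end, strand, tuple(members)))
    regions.sort(key=lambda g: (g.contig, g.start, g.end, g.strand))
    return regions


def _depth_array(region_start: int, region_end: int, reads: Sequence[ReadInterval]) -> np.ndarray:
    depth = np.zeros(region_end - region_start + 1, dtype=np.int64)
    for r in reads:
        depth[r.start - region_start] += 1
        depth[r.end - region_start] -= 1
    return np.cumsum(depth)[:-1]


@dataclass(frozen=True, slots=True)
class SubdivisionResult:
    regions: tuple[CTRegion, ...]
    n_discarded_reads: int


def subdivide_by_depth(region: CTRegion, min_depth: int = 2) -> SubdivisionResult:
    """Split a region at every maximal run of positions with depth < ``min_depth``.

    Reads fully contained in a resulting sub-region follow it; reads spanning
    a split point are discarded. Sub-region boundaries are trimmed to the
    first/last position covered by the retained reads. Discarding can lower
    depth further, so splitting iterates until every surviving sub-region has
    depth >= ``min_depth`` throughout (bounded by region length).
    """
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    discarded = 0
    finished: list[CTRegion] = []
    work = [region]
    while work:
        reg = work.pop()
        if not reg.reads:
            continue
        depth = _depth_array(reg.start, reg.end, reg.reads)
        ok = depth >= min_depth
        if ok.all():
            finished.append(reg)
            continue
        # maximal runs of positions meeting the cutoff
        edges = np.flatnonzero(np.diff(np.concatenate(([False], ok, [False])).astype(np.int8)))
        runs = edges.reshape(-1, 2)  # [run_start, run_end) offsets
        kept_in_any = 0
        for off_start, off_end in runs:
            lo, hi = reg.start + int(off_start), reg.start + int(off_end)
            sub_reads = tuple(r for r in reg.reads if lo <= r.start and r.end <= hi)
            kept_in_any += len(sub_reads)
            if not sub_reads:
                continue
            # trim to coverage of the retained reads
            lo2 = min(r.start for r in sub_reads)
            hi2 = max(r.end for r in sub_reads)
            work.append(CTRegion(reg.contig, lo2, hi2, reg.strand, sub_reads))
        discarded += reg.n_reads - kept_in_any
    finished.sort(key=lambda g: (g.contig, g.start, g.end, g.strand))
    return SubdivisionResult(tuple(finished), discarded)


def subdivide_all(regions: Iterable[CTRegion], min_depth: int = 2) -> SubdivisionResult:
    """Apply :func:`subdivide_by_depth` to every region; aggregate results."""
    out: list[CTRegion] = []
    discarded = 0
    for region in regions:
        res = subdivide_by_depth(region, min_depth)
        out.extend(res.regions)
        discarded += res.n_discarded_reads
    if discarded:
        logger.info("subdivision discarded %d split-spanning reads", discarded)
    out.sort(key=lambda g: (g.contig, g.start, g.end, g.strand))
    return SubdivisionResult(tuple(out), discarded)


def filter_regions(regions: Iterable[CTRegion], min_reads: int) -> list[CTRegion]:
    """Keep regions with at least ``min_reads`` fully contained reads.

    Two conventional settings: 2 (the algorithm-level minimum for a region to
    be considered at all) and 20 (the stricter pipeline-level prefilter used
    for genome-wide predictions).
    """
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    return [g for g in regions if g.n_reads >= min_reads]


def regions_from_records(
    records: Iterable[RegionRecord],
    reads: Iterable[ReadInterval],
    min_record_reads: int = 0,
) -> list[CTRegion]:
    """Build CT regions from a pre-merged region BED used as a mask.

    Each record passing the ``read_count >= min_record_reads`` prefilter
    becomes a region holding the reads fully contained in it on its strand.
    Records that end up with no contained reads are dropped.
    """
    kept = [rec for rec in records if rec.read_count >= min_record_reads]
    by_key: dict[tuple[str, str], list[ReadInterval]] = {}
    for r in reads:
        by_key.setdefault((r.contig, r.strand), []).append(r)
    regions: list[CTRegion] = []
    for rec in kept:
        pool = by_key.get((rec.contig, rec.strand), [])
        members = tuple(
            r for r in _sorted_reads(pool) if rec.start <= r.start and r.end <= rec.end
        )
        if not members:
            logger.info("region mask %s:%d-%d(%s) contains no reads; dropped",
                        rec.contig, rec.start, rec.end, rec.strand)
            continue
        regions.append(CTRegion(rec.contig, rec.start, rec.end, rec.strand, members))
    regions.sort(key=lambda g: (g.contig, g.start, g.end, g.strand))
    return regions
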