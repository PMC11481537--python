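"""Candidate transcript enumeration and the shortest-to-longest ratio filter.

Candidates are the Cartesian product of grouped left and right boundary
sites of a CT region. Two read counts decide which candidates survive:

* ``N_tot`` — reads fully contained in the candidate (a read may count
  toward many candidates);
* ``N_ea`` — reads whose *exclusive* home is the candidate, a read's home
  being the shortest not-yet-discarded candidate that contains it.

Candidates are processed shortest to longest. At each step ``N_ea`` is
recomputed from the live assignment and the candidate is discarded when
``N_ea / N_tot`` falls below the ratio threshold; its reads are immediately
re-homed to their next-shortest surviving container, so that reads from a
rejected short candidate can still support a longer one. ``N_tot`` is fixed
at enumeration time and never recomputed.

Containment allows a configurable slack: grouped boundary sites represent
read ends up to the grouping distance away, so a read may overhang a
candidate boundary by up to ``slack`` bases on each side and still count as
contained. ``slack=0`` restores strict containment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .boundaries import SiteGroup, call_sites, compute_depth, group_sites
from .io import ReadInterval
from .regions import CTRegion

__all__ = [
    "PredictionParams",
    "CandidateTranscript",
    "Transcript",
    "enumerate_candidates",
    "count_containment",
    "assign_exclusive",
    "filter_by_ratio",
    "predict_transcripts",
    "run_prediction",
]

logger = logging.getLogger(__name__)

PENDING = "pending"
RETAINED = "retained"
DISCARDED = "discarded"


@dataclass(frozen=True, slots=True)
class PredictionParams:
    """All tunable parameters of the per-region prediction algorithm."""

    delta_threshold: int = 4
    strict_gt: bool = False
    group_distance: int = 100
    ratio_threshold: float = 0.2
    min_depth: int = 2
    min_region_reads: int = 2
    min_length: int = 50
    containment_slack: int = 100

    def __post_init__(self) -> None:
        if not (0.0 <= self.ratio_threshold <= 1.0):
            raise ValueError("ratio_threshold must be in [0, 1]")
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")
        if self.containment_slack < 0:
            raise ValueError("containment_slack must be >= 0")


@dataclass(slots=True)
class CandidateTranscript:
    region_id: str
    left: int
    right: int
    n_tot: int = 0
    n_ea: int = 0
    status: str = PENDING

    @property
    def length(self) -> int:
        return self.right - self.left

    @property
    def ratio(self) -> float:
        return self.n_ea / self.n_tot if self.n_tot else float("nan")


@dataclass(frozen=True, slots=True)
class Transcript:
    """A retained prediction with its final support counts."""

    contig: str
    start: int
    end: int
    strand: str
    region_id: str
    n_tot: int
    n_ea: int
    ratio: float
    transcript_id: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("transcript interval is empty")

    @property
    def length(self) -> int:
        return self.end - self.start


def enumerate_candidates(
    left_groups: Sequence[SiteGroup],
    right_groups: Sequence[SiteGroup],
    region_id: str,
    min_length: int = 50,
) -> list[CandidateTranscript]:
    """Cartesian product of left x right representatives, shortest first.

    Pairs with ``right - left < min_length`` are excluded. Ordering is
    (length ascending, left ascending) — the processing order of the ratio
    filter and the tie-break order for equal-length containers.
    """
    out = [
        CandidateTranscript(region_id, lg.representative, rg.representative)
        for lg in left_groups
        for rg in right_groups
        if rg.representative - lg.representative >= max(min_length, 1)
    ]
    out.sort(key=lambda c: (c.length, c.left))
    return out


def _containment_lists(
    candidates: Sequence[CandidateTranscript],
    reads: Sequence[ReadInterval],
    slack: int,
) -> list[list[int]]:
    """For each read, the candidate indices containing it, in candidate order."""
    if not candidates or not reads:
        return [[] for _ in reads]
    lefts = np.fromiter((c.left for c in candidates), dtype=np.int64)
    rights = np.fromiter((c.right for c in candidates), dtype=np.int64)
    starts = np.fromiter((r.start for r in reads), dtype=np.int64)
    ends = np.fromiter((r.end for r in reads), dtype=np.int64)
    contained = (starts[:, None] >= lefts[None, :] - slack) & (
        ends[:, None] <= rights[None, :] + slack
    )
    return [list(np.flatnonzero(row)) for row in contained]


def count_containment(
    candidates: Sequence[CandidateTranscript],
    reads: Sequence[ReadInterval],
    slack: int = 100,
) -> None:
    """Fill ``n_tot`` for every candidate (multi-counting allowed), in place."""
    for lst in _containment_lists(candidates, reads, slack):
        for j in lst:
            candidates[j].n_tot += 1


def assign_exclusive(
    candidates: Sequence[CandidateTranscript],
    reads: Sequence[ReadInterval],
    slack: int = 100,
) -> list[int | None]:
    """Home each read at its shortest non-discarded containing candidate.

    Returns one candidate index (or None) per read. Candidates must be in
    enumeration order, which encodes both the shortest-first rule and the
    equal-length tie-break by left coordinate.
    """
    homes: list[int | None] = []
    for lst in _containment_lists(candidates, reads, slack):
        home = next((j for j in lst if candidates[j].status != DISCARDED), None)
        homes.append(home)
    return homes


def filter_by_ratio(
    candidates: Sequence[CandidateTranscript],
    reads: Sequence[ReadInterval],
    slack: int = 100,
    ratio_threshold: float = 0.2,
) -> list[int | None]:
    """Run the sequential shortest-to-longest ratio filter.

    Candidates must arrive in enumeration order with ``n_tot`` already
    counted. Each candidate's ``N_ea`` is recomputed from the live read
    assignment when its turn comes; a candidate with no reads or with
    ``N_ea / N_tot`` below the threshold is discarded and its reads are
    immediately re-homed to their next-shortest surviving container (reads
    with no surviving container become unassigned and support nothing).
    Sets candidate statuses and final ``n_ea`` in place; returns the final
    per-read homes.
    """
    containers = _containment_lists(candidates, reads, slack)
    homes: list[int | None] = [lst[0] if lst else None for lst in containers]
    homed_at: list[list[int]] = [[] for _ in candidates]
    for ridx, home in enumerate(homes):
        if home is not None:
            homed_at[home].append(ridx)

    for i, cand in enumerate(candidates):
        n_ea = len(homed_at[i])
        if cand.n_tot == 0 or n_ea / cand.n_tot < ratio_threshold:
            cand.status = DISCARDED
            for ridx in homed_at[i]:
                lst = containers[ridx]
                nxt = next(
                    (j for j in lst if j > i and candidates[j].status != DISCARDED),
                    None,
                )
                homes[ridx] = nxt
                if nxt is not None:
                    homed_at[nxt].append(ridx)
            homed_at[i] = []
        else:
            cand.status = RETAINED

    for i, cand in enumerate(candidates):
        cand.n_ea = len(homed_at[i]) if cand.status == RETAINED else 0
    return homes


def predict_transcripts(
    region: CTRegion, params: PredictionParams = PredictionParams()
) -> list[Transcript]:
    """Full per-region prediction: depth -> sites -> groups -> candidates -> filter."""
    profile = compute_depth(region)
    sites = call_sites(profile, params.delta_threshold, params.strict_gt)
    groups = group_sites(
        sites, params.group_distance, region_start=region.start, region_end=region.end
    )
    left_groups = [g for g in groups if g.side == "left"]
    right_groups = [g for g in groups if g.side == "right"]
    candidates = enumerate_candidates(
        left_groups, right_groups, region.region_id, params.min_length
    )
    if not candidates:
        logger.info("region %s: no candidate passes min_length", region.region_id)
        return []
    count_containment(candidates, region.reads, params.containment_slack)
    filter_by_ratio(
        candidates, region.reads, params.containment_slack, params.ratio_threshold
    )
    retained = [c for c in candidates if c.status == RETAINED]
    retained.sort(key=lambda c: (c.left, c.right))
    transcripts = [
        Transcript(
            contig=region.contig,
            start=c.left,
            end=c.right,
            strand=region.strand,
            region_id=region.region_id,
            n_tot=c.n_tot,
            n_ea=c.n_ea,
            ratio=c.n_ea / c.n_tot,
            transcript_id=f"{region.region_id}.t{k + 1}",
        )
        for k, c in enumerate(retained)
    ]
    if not transcripts:
        logger.info("region %s: all candidates discarded", region.region_id)
    return transcripts


@dataclass(frozen=True, slots=True)
class PredictionRun:
    """Outcome of a whole-dataset prediction with per-stage accounting."""

    transcripts: tuple[Transcript, ...]
    regions_built: int
    regions_after_subdivision: int
    regions_used: int
    reads_discarded_at_splits: int


def run_prediction(
    reads: Iterable[ReadInterval],
    params: PredictionParams = PredictionParams(),
    min_region_reads: int | None = None,
    region_mask=None,
) -> PredictionRun:
    """Predict transcripts genome-wide from per-read intervals.

    ``min_region_reads`` is the pipeline-level read-support prefilter
    (defaults to ``params.min_region_reads``; genome-scale runs typically use
    20). ``region_mask`` optionally supplies pre-merged region records; their
    read counts are filtered with the same threshold before reads are
    assigned.
    """
    from .regions import (
        build_ct_regions,
        filter_regions,
        regions_from_records,
        subdivide_all,
    )

    threshold = params.min_region_reads if min_region_reads is None else min_region_reads
    reads = list(reads)
    if region_mask is not None:
        initial = regions_from_records(region_mask, reads, min_record_reads=threshold)
    else:
        initial = build_ct_regions(reads)
    sub = subdivide_all(initial, params.min_depth)
    used = filter_regions(sub.regions, threshold)
    transcripts: list[Transcript] = []
    for region in used:
        transcripts.extend(predict_transcripts(region, params))
    transcripts.sort(key=lambda t: (t.contig, t.start, t.end, t.strand))
    return PredictionRun(
        transcripts=tuple(transcripts),
        regions_built=len(initial),
        regions_after_subdivision=len(sub.regions),
        regions_used=len(used),
        reads_discarded_at_splits=sub.n_discarded_reads,
    )
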