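"""Depth profiles, boundary-site calling and proximity grouping.

For a CT region the per-position depth D(n) counts reads covering position n
(every base of a read counts equally — alignment mismatches and indels are
deliberately ignored so that base modifications or reference divergence do
not dent the profile). The discrete derivative

    dD(n) = D(n+1) - D(n),   D == 0 outside the region,

is evaluated for n in [start-1, end): a strongly positive delta marks a pile
of read starts (a candidate transcript left boundary) and a strongly
negative delta a pile of read ends (right boundary). The first and last
positions of the region are always boundary sites, regardless of magnitude.

Long-read end positions jitter by tens of bases, so called sites within a
grouping distance of each other are merged and represented by the
max-magnitude member — the mode of read ends is the best single estimate of
the true boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .regions import CTRegion

__all__ = [
    "DepthProfile",
    "BoundarySite",
    "SiteGroup",
    "compute_depth",
    "call_sites",
    "group_sites",
]

LEFT = "left"
RIGHT = "right"


@dataclass(frozen=True, slots=True)
class DepthProfile:
    """Exact integer depth and delta arrays for one region.

    ``depth[i]`` is the depth at genomic position ``offset + i`` for
    i in [0, L). ``delta[k]`` is dD(offset - 1 + k) for k in [0, L], i.e. the
    step between consecutive positions over the padded range [offset-1,
    offset+L), with depth 0 outside the region. The deltas therefore sum
    to zero.
    """

    region_id: str
    offset: int
    depth: np.ndarray
    delta: np.ndarray


def compute_depth(region: CTRegion) -> DepthProfile:
    """Depth by difference-array accumulation (+1 at start, -1 at end, prefix sum)."""
    if not region.reads:
        raise ValueError(f"region {region.region_id} has no reads")
    L = region.length
    diff = np.zeros(L + 1, dtype=np.int64)
    for r in region.reads:
        diff[r.start - region.start] += 1
        diff[r.end - region.start] -= 1
    depth = np.cumsum(diff)[:-1]
    delta = np.diff(np.concatenate(([0], depth, [0])))
    return DepthProfile(region.region_id, region.start, depth, delta)


@dataclass(frozen=True, slots=True)
class BoundarySite:
    """A candidate transcript boundary.

    ``side`` is genomic: a left site is where depth steps up (read 5' ends on
    the + strand, 3' ends on the - strand), a right site where it steps down.
    Left sites are transcript start coordinates and right sites half-open end
    coordinates. ``forced`` marks the unconditional region-terminus sites.
    """

    position: int
    side: str
    magnitude: int
    forced: bool = False


def call_sites(
    profile: DepthProfile, threshold: int = 4, strict_gt: bool = False
) -> list[BoundarySite]:
    """Call boundary sites where |delta| passes ``threshold``.

    A delta of +m between positions n and n+1 (m >= threshold) yields a left
    site at n+1, the first covered base; a delta of -m yields a right site at
    n+1, directly usable as a half-open end. The region terminus sites are
    always included (``forced=True``) whatever their magnitude. By default a
    delta exactly equal to the threshold counts ("surpasses" read as >=);
    ``strict_gt`` switches the comparison to >.
    """
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    delta = profile.delta
    L = len(profile.depth)
    region_start = profile.offset
    region_end = profile.offset + L

    def passes(mag: int) -> bool:
        return mag > threshold if strict_gt else mag >= threshold

    sites: dict[tuple[int, str], BoundarySite] = {}
    for k in np.flatnonzero(delta != 0):
        d = int(delta[k])
        pos = profile.offset + int(k)  # n + 1 for n = offset - 1 + k
        side = LEFT if d > 0 else RIGHT
        if passes(abs(d)):
            sites[(pos, side)] = BoundarySite(pos, side, abs(d))
    # unconditional terminus sites; merge with a same-position called site
    first = BoundarySite(region_start, LEFT, int(profile.depth[0]), forced=True)
    last = BoundarySite(region_end, RIGHT, int(profile.depth[-1]), forced=True)
    sites[(first.position, LEFT)] = first
    sites[(last.position, RIGHT)] = last
    return sorted(sites.values(), key=lambda s: (s.position, s.side))


@dataclass(frozen=True, slots=True)
class SiteGroup:
    """A chain of nearby same-side sites collapsed to one representative."""

    side: str
    representative: int
    members: tuple[BoundarySite, ...]

    @property
    def total_magnitude(self) -> int:
        return sum(s.magnitude for s in self.members)

    @property
    def positions(self) -> tuple[int, ...]:
        return tuple(s.position for s in self.members)


def _representative(members: Sequence[BoundarySite], terminus: int) -> int:
    """Max-magnitude member; ties broken toward the region terminus when the
    group contains a forced site, else toward the leftmost position."""
    best = max(s.magnitude for s in members)
    candidates = [s.position for s in members if s.magnitude == best]
    if any(s.forced for s in members):
        return min(candidates, key=lambda p: (abs(p - terminus), p))
    return min(candidates)


def group_sites(
    sites: Sequence[BoundarySite],
    distance: int = 100,
    region_start: int | None = None,
    region_end: int | None = None,
) -> list[SiteGroup]:
    """Single-linkage chain same-side sites with pairwise gaps <= ``distance``.

    Left sites never merge with right sites. Forced terminus sites take part
    in grouping like any other member. ``region_start``/``region_end`` locate
    the terminus used for tie-breaking; they default to the extreme site
    positions.
    """
    if distance < 0:
        raise ValueError("distance must be >= 0")
    groups: list[SiteGroup] = []
    for side in (LEFT, RIGHT):
        pool = sorted((s for s in sites if s.side == side), key=lambda s: s.position)
        if not pool:
            continue
        if side == LEFT:
            terminus = region_start if region_start is not None else pool[0].position
        else:
            terminus = region_end if region_end is not None else pool[-1].position
        chain: list[BoundarySite] = [pool[0]]
        for s in pool[1:]:
            if s.position - chain[-1].position <= distance:
                chain.append(s)
            else:
                groups.append(SiteGroup(side, _representative(chain, terminus), tuple(chain)))
                chain = [s]
        groups.append(SiteGroup(side, _representative(chain, terminus), tuple(chain)))
    groups.sort(key=lambda g: (g.representative, g.side))
    return groups
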