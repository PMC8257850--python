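"""Replicate-consensus (hcpeak) calling and cross-condition peak merging.

A high-confidence peak (hcpeak) is a connected component of replicate peak
calls in which peaks from different replicates overlap by at least
``min(min_overlap, shorter peak length)`` bp and which spans at least
``min_support`` distinct replicates.  hcpeaks from all experimental groups
are then merged transitively (>= 1 bp overlap) into the unique peak set
(unipeaks) that every downstream stage annotates and tests.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Tuple

from .genomic_io import GenomicInterval, PeakCall

logger = logging.getLogger("merip_conjoint")


@dataclass(frozen=True)
class HCPeak:
    """Replicate-consensus peak: union interval of its member peak calls."""

    interval: GenomicInterval
    condition: Optional[str]
    replicates: FrozenSet[int]
    members: Tuple[str, ...]

    def __post_init__(self):
        if len(self.replicates) < 2:
            raise ValueError("an hcpeak needs support from >= 2 replicates")


@dataclass(frozen=True)
class UniPeak:
    """A member of the merged unique peak set, with per-group presence flags."""

    peak_id: str
    interval: GenomicInterval
    groups: FrozenSet[str]

    def __post_init__(self):
        if not self.groups:
            raise ValueError("a unipeak must be present in >= 1 group")


def effective_overlap_threshold(min_overlap: int, len_a: int, len_b: int) -> int:
    """The 100 bp overlap rule, relaxed to the shorter feature's length so
    sub-threshold features are not silently unassignable."""
    return min(min_overlap, len_a, len_b)


def _self_merge(peaks: Sequence[PeakCall]) -> List[PeakCall]:
    """Merge overlapping peaks within one replicate (MACS2 can emit them)."""
    merged: List[PeakCall] = []
    n_merges = 0
    for p in sorted(peaks, key=lambda p: (p.interval.chrom, p.interval.start)):
        if (
            merged
            and merged[-1].interval.chrom == p.interval.chrom
            and p.interval.start < merged[-1].interval.end
        ):
            prev = merged[-1]
            merged[-1] = PeakCall(
                interval=GenomicInterval(
                    prev.interval.chrom,
                    prev.interval.start,
                    max(prev.interval.end, p.interval.end),
                    prev.interval.strand,
                ),
                sample=prev.sample,
                name=f"{prev.name},{p.name}",
                score=max(prev.score, p.score),
            )
            n_merges += 1
        else:
            merged.append(p)
    if n_merges:
        logger.warning(
            "self-merged %d overlapping peak(s) within one replicate", n_merges
        )
    return merged


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def find_hcpeaks(
    replicate_peaks: Sequence[Sequence[PeakCall]],
    min_support: int = 2,
    min_overlap: int = 100,
    condition: Optional[str] = None,
) -> List[HCPeak]:
    """Derive hcpeaks from per-replicate peak calls.

    Peaks from *different* replicates are linked when they overlap by at
    least ``min(min_overlap, shorter peak length)``; each connected
    component spanning >= ``min_support`` distinct replicates becomes one
    hcpeak whose interval is the union of its members.
    """
    if len(replicate_peaks) < 2:
        raise ValueError("need >= 2 replicate peak sets")
    if min_overlap <= 0:
        raise ValueError("min_overlap must be positive")
    reps = [_self_merge(peaks) for peaks in replicate_peaks]
    nodes: List[Tuple[int, PeakCall]] = [
        (r, p) for r, peaks in enumerate(reps) for p in peaks
    ]
    uf = _UnionFind(len(nodes))
    # group node ids by chromosome, then pairwise-check across replicates
    by_chrom: Dict[str, List[int]] = {}
    for idx, (_, p) in enumerate(nodes):
        by_chrom.setdefault(p.interval.chrom, []).append(idx)
    for idxs in by_chrom.values():
        idxs.sort(key=lambda i: nodes[i][1].interval.start)
        for a_pos, i in enumerate(idxs):
            ri, pi = nodes[i]
            for j in idxs[a_pos + 1 :]:
                rj, pj = nodes[j]
                if pj.interval.start >= pi.interval.end:
                    break
                if ri == rj:
                    continue
                ov = pi.interval.overlap(pj.interval)
                if ov >= effective_overlap_threshold(
                    min_overlap, pi.interval.length, pj.interval.length
                ):
                    uf.union(i, j)
    components: Dict[int, List[int]] = {}
    for idx in range(len(nodes)):
        components.setdefault(uf.find(idx), []).append(idx)
    out: List[HCPeak] = []
    for member_ids in components.values():
        rep_set = frozenset(nodes[i][0] for i in member_ids)
        if len(rep_set) < min_support:
            continue
        ivs = [nodes[i][1].interval for i in member_ids]
        out.append(
            HCPeak(
                interval=GenomicInterval(
                    ivs[0].chrom,
                    min(iv.start for iv in ivs),
                    max(iv.end for iv in ivs),
                ),
                condition=condition,
                replicates=rep_set,
                members=tuple(sorted(nodes[i][1].name for i in member_ids)),
            )
        )
    out.sort(key=lambda h: (h.interval.chrom, h.interval.start, h.interval.end))
    return out


def merge_conditions(
    hcpeaks_by_group: Mapping[str, Sequence[HCPeak]]
) -> List[UniPeak]:
    """Merge hcpeaks across experimental groups into the unique peak set.

    Intervals overlapping by >= 1 bp are merged transitively; presence flags
    record which groups contributed.  Output is sorted by (chrom, start) and
    pairwise disjoint.
    """
    entries = sorted(
        (
            (h.interval.chrom, h.interval.start, h.interval.end, group)
            for group, peaks in hcpeaks_by_group.items()
            for h in peaks
        ),
    )
    merged: List[Tuple[str, int, int, set]] = []
    for chrom, start, end, group in entries:
        if merged and merged[-1][0] == chrom and start < merged[-1][2]:
            prev = merged[-1]
            merged[-1] = (chrom, prev[1], max(prev[2], end), prev[3] | {group})
        else:
            merged.append((chrom, start, end, {group}))
    return [
        UniPeak(
            peak_id=f"unipeak_{i + 1:05d}",
            interval=GenomicInterval(chrom, start, end),
            groups=frozenset(groups),
        )
        for i, (chrom, start, end, groups) in enumerate(merged)
    ]


@dataclass
class PeakSetComparison:
    """Venn-style comparison of two hcpeak sets (e.g. CK vs Cd)."""

    shared_a: List[HCPeak]
    shared_b: List[HCPeak]
    a_only: List[HCPeak]
    b_only: List[HCPeak]

    @property
    def n_shared(self) -> int:
        return len(self.shared_a)

    def counts(self) -> Dict[str, int]:
        return {
            "shared_a": len(self.shared_a),
            "shared_b": len(self.shared_b),
            "a_only": len(self.a_only),
            "b_only": len(self.b_only),
        }


def compare_peak_sets(
    set_a: Sequence[HCPeak], set_b: Sequence[HCPeak], min_overlap: int = 100
) -> PeakSetComparison:
    """Classify peaks of each set as shared or exclusive.

    A peak is shared iff it overlaps some peak of the other set by
    >= min(min_overlap, shorter peak length).
    """

    def shared_mask(src: Sequence[HCPeak], other: Sequence[HCPeak]) -> List[bool]:
        flags = []
        for p in src:
            hit = any(
                p.interval.overlap(q.interval)
                >= effective_overlap_threshold(
                    min_overlap, p.interval.length, q.interval.length
                )
                for q in other
                if q.interval.chrom == p.interval.chrom
            )
            flags.append(hit)
        return flags

    mask_a = shared_mask(set_a, set_b)
    mask_b = shared_mask(set_b, set_a)
    return PeakSetComparison(
        shared_a=[p for p, f in zip(set_a, mask_a) if f],
        shared_b=[p for p, f in zip(set_b, mask_b) if f],
        a_only=[p for p, f in zip(set_a, mask_a) if not f],
        b_only=[p for p, f in zip(set_b, mask_b) if not f],
    )
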