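"""Sample-level outlier exclusion and cross-sample CNV regions."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import CNVCall

__all__ = ["CNVRegion", "define_regions", "exclude_outlier_samples"]


@dataclass
class CNVRegion:
    """Merged cross-sample region: union of linked calls."""

    chromosome: str
    start: int
    end: int
    members: list[CNVCall] = field(default_factory=list)
    n_carriers: int = 0
    frequency: float = 0.0
    rare: bool = False


def exclude_outlier_samples(
    calls: list[CNVCall], subject_ids: list[str], k_sd: float = 3.0
) -> list[str]:
    """Subjects retained after the one-sided total-call-count screen.

    A subject is excluded iff its total call count exceeds
    ``mean + k_sd * SD`` of the per-subject counts (computed once, not
    iterated). Subjects with zero calls participate in the statistics.
    """
    counts = pd.Series(0, index=list(subject_ids), dtype=float)
    for c in calls:
        counts[c.subject_id] += 1
    mu, sd = counts.mean(), counts.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        return list(subject_ids)
    cutoff = mu + k_sd * sd
    return [s for s in subject_ids if counts[s] <= cutoff]


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


def _linked(a: CNVCall, b: CNVCall, max_gap_markers: int) -> bool:
    if a.chromosome != b.chromosome:
        return False
    if not (a.last < b.first or b.last < a.first):  # marker overlap
        return True
    gap = (b.first - a.last - 1) if a.first <= b.first else (a.first - b.last - 1)
    return gap < max_gap_markers


def define_regions(
    calls: list[CNVCall],
    n_subjects: int,
    max_gap_markers: int = 3,
    rare_frequency: float = 0.01,
) -> list[CNVRegion]:
    """Single-linkage merge of calls into cross-sample regions.

    Two calls (from any samples) link iff their marker spans overlap or
    are apart by fewer than ``max_gap_markers`` markers; regions are
    the transitive closure. Frequency is distinct carriers over
    ``n_subjects``; ``rare`` iff frequency < ``rare_frequency``.
    """
    if n_subjects <= 0:
        raise ValueError("n_subjects must be positive")
    regions: list[CNVRegion] = []
    order = sorted(range(len(calls)), key=lambda i: (calls[i].chromosome, calls[i].first))
    uf = _UnionFind(len(calls))
    # sorted sweep: linking is an interval relation, so comparing each
    # call with its predecessors inside the current linked cluster is enough
    by_chrom: dict[str, list[int]] = {}
    for i in order:
        by_chrom.setdefault(calls[i].chromosome, []).append(i)
    for chrom_calls in by_chrom.values():
        frontier = -(10**12)
        cluster_rep = None
        for i in chrom_calls:
            c = calls[i]
            if cluster_rep is not None and c.first - frontier - 1 < max_gap_markers:
                uf.union(cluster_rep, i)
            else:
                cluster_rep = i
            frontier = max(frontier, c.last)

    groups: dict[int, list[int]] = {}
    for i in range(len(calls)):
        groups.setdefault(uf.find(i), []).append(i)
    for idxs in groups.values():
        members = [calls[i] for i in idxs]
        carriers = {m.subject_id for m in members}
        freq = len(carriers) / n_subjects
        regions.append(
            CNVRegion(
                chromosome=members[0].chromosome,
                start=min(m.start for m in members),
                end=max(m.end for m in members),
                members=members,
                n_carriers=len(carriers),
                frequency=freq,
                rare=freq < rare_frequency,
            )
        )
    regions.sort(key=lambda r: (r.chromosome, r.start))
    return regions
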