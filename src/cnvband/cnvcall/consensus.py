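"""Consensus fusion of CBS and HMM segments, SNR check and
structural (size / telomere / centromere) filters."""

from __future__ import annotations

import numpy as np

from ..synthdata.maps import CytobandMap
from .types import CNVCall, Segment

__all__ = ["consensus_calls", "snr_filter", "structural_filters"]


def _marker_gap(a: Segment, b: Segment) -> int:
    """Number of markers strictly between two disjoint segments."""
    if a.first > b.first:
        a, b = b, a
    return b.first - a.last - 1


def consensus_calls(
    cbs_segments: list[Segment],
    hmm_segments: list[Segment],
    positions: np.ndarray,
    subject_id: str,
    max_gap_markers: int = 3,
    min_markers: int = 3,
    cbs_magnitude: float = 0.1,
) -> list[CNVCall]:
    """Candidate calls supported by both segmentations.

    Only non-neutral HMM segments and CBS segments with
    ``|mean LRR| >= cbs_magnitude`` participate, each spanning at least
    ``min_markers`` markers. A pair matches iff the marker intervals
    overlap or are apart by fewer than ``max_gap_markers`` markers.
    The call takes its copy number from the HMM state; its span is the
    marker intersection when overlapping, else the HMM segment's span
    (recorded in provenance).
    """
    cbs_cand = [s for s in cbs_segments if abs(s.mean_lrr) >= cbs_magnitude and s.n_markers >= min_markers]
    hmm_cand = [s for s in hmm_segments if s.state not in (None, 2) and s.n_markers >= min_markers]
    calls: list[CNVCall] = []
    seen: set[tuple[int, int, int]] = set()
    for h in hmm_cand:
        # the CBS segment must shift in the same direction as the state
        sign = -1 if h.state < 2 else 1
        for c in cbs_cand:
            if np.sign(c.mean_lrr) != sign:
                continue
            overlap = not (c.last < h.first or h.last < c.first)
            if overlap:
                first, last = max(c.first, h.first), min(c.last, h.last)
                matched_by = "overlap"
            elif _marker_gap(c, h) < max_gap_markers:
                first, last = h.first, h.last
                matched_by = "gap"
            else:
                continue
            key = (first, last, h.state)
            if key in seen:
                continue
            seen.add(key)
            calls.append(
                CNVCall(
                    subject_id=subject_id,
                    chromosome=h.chromosome,
                    start=int(positions[first]),
                    end=int(positions[last]),
                    first=first,
                    last=last,
                    copy_number=int(h.state),
                    provenance={
                        "cbs_span": (c.first, c.last),
                        "hmm_span": (h.first, h.last),
                        "matched_by": matched_by,
                    },
                )
            )
    calls.sort(key=lambda c: c.first)
    return calls


def snr_filter(
    candidates: list[CNVCall],
    lrr: np.ndarray,
    flank_markers: int = 50,
    snr_threshold: float = 2.0,
) -> list[CNVCall]:
    """Keep candidates whose segment-vs-flank contrast is strong enough.

    ``snr = |mean(segment) - mean(flank)| / SD(flank)`` with flanks of
    up to ``flank_markers`` markers on each side, truncated at
    chromosome ends and excluding other candidates' spans. A zero
    flank SD with a nonzero contrast counts as infinite SNR (keep).
    The raw mean ratio is recorded per call for audit.
    """
    x = np.asarray(lrr, dtype=float)
    n = len(x)
    in_candidate = np.zeros(n, dtype=bool)
    for c in candidates:
        in_candidate[c.first : c.last + 1] = True

    kept = []
    for c in candidates:
        left = np.arange(max(0, c.first - flank_markers), c.first)
        right = np.arange(c.last + 1, min(n, c.last + 1 + flank_markers))
        flank_idx = np.concatenate([left, right])
        flank_idx = flank_idx[~in_candidate[flank_idx]]
        seg_mean = float(x[c.first : c.last + 1].mean())
        if len(flank_idx) < 2:
            c.snr = float("inf")
            kept.append(c)
            continue
        flank = x[flank_idx]
        flank_mean = float(flank.mean())
        flank_sd = float(flank.std(ddof=1))
        diff = abs(seg_mean - flank_mean)
        c.snr = diff / flank_sd if flank_sd > 0 else (float("inf") if diff > 0 else 0.0)
        c.raw_snr_ratio = seg_mean / flank_mean if flank_mean != 0 else float("inf")
        if c.snr >= snr_threshold:
            kept.append(c)
    return kept


def _overlap_fraction(call: CNVCall, interval: tuple[int, int]) -> float:
    """Fraction of the call's bp length inside a half-open interval."""
    lo, hi = interval  # [lo, hi), 1-based
    ov = min(call.end + 1, hi) - max(call.start, lo)
    return max(ov, 0) / call.length


def structural_filters(
    candidates: list[CNVCall],
    cytoband_map: CytobandMap,
    min_bp: int = 500,
    max_tel_cen_overlap: float = 0.5,
    homozygous_small_exception: bool = False,
) -> list[CNVCall]:
    """Drop calls mostly inside telomeres/centromeres or shorter than
    ``min_bp`` (homozygous deletions may be whitelisted below the size
    floor with ``homozygous_small_exception``)."""
    kept = []
    for c in candidates:
        if c.length < min_bp and not (homozygous_small_exception and c.copy_number == 0):
            continue
        intervals = cytoband_map.tel_cen_intervals(c.chromosome)
        if any(_overlap_fraction(c, iv) > max_tel_cen_overlap for iv in intervals):
            continue
        kept.append(c)
    return kept
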