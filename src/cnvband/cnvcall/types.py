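"""Segment and call records shared across the calling pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["CNVCall", "Segment", "classify_copy_number"]


def classify_copy_number(cn: int) -> str:
    """Deletion for copy number 0/1, insertion for 3+; CN2 is neutral."""
    if cn in (0, 1):
        return "deletion"
    if cn >= 3:
        return "insertion"
    return "neutral"


@dataclass
class Segment:
    """A contiguous marker run from one segmentation algorithm.

    ``first``/``last`` are 0-based marker indices into the chromosome's
    marker vector, inclusive. ``state`` is the HMM copy number; CBS
    segments have ``state=None``.
    """

    chromosome: str
    first: int
    last: int
    start: int  # bp, 1-based inclusive
    end: int  # bp, 1-based inclusive
    mean_lrr: float
    source: str  # "CBS" | "HMM"
    state: int | None = None
    flagged: bool = False

    @property
    def n_markers(self) -> int:
        return self.last - self.first + 1

    def __post_init__(self) -> None:
        if self.last < self.first:
            raise ValueError("segment with last < first")
        if self.end < self.start:
            raise ValueError("segment with end bp < start bp")


@dataclass
class CNVCall:
    """A consensus CNV call for one subject."""

    subject_id: str
    chromosome: str
    start: int  # bp, 1-based inclusive
    end: int  # bp, 1-based inclusive
    first: int  # marker index, inclusive
    last: int
    copy_number: int
    snr: float = float("nan")
    raw_snr_ratio: float = float("nan")  # segment mean / flank mean, recorded for audit
    provenance: dict = field(default_factory=dict)
    low_confidence: bool = False  # insertions are flagged, no algorithmic difference

    @property
    def n_markers(self) -> int:
        return self.last - self.first + 1

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def cnv_class(self) -> str:
        return classify_copy_number(self.copy_number)

    def __post_init__(self) -> None:
        if self.copy_number == 2:
            raise ValueError("neutral segments are not CNV calls")
        if self.cnv_class == "insertion":
            self.low_confidence = True
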