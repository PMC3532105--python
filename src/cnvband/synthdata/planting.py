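"""Planting ground-truth CNV events into a synthetic cohort."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .maps import CytobandMap, MarkerMap

__all__ = ["CNVTruth", "PlantedEvent", "PlantingConfig", "plant_cnvs"]


@dataclass(frozen=True)
class PlantedEvent:
    subject_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    copy_number: int
    band: str

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class PlantingConfig:
    """Rates and shapes for planted events.

    ``background_del_rate``/``background_ins_rate`` are per-subject,
    per-band Bernoulli rates. ``effect_band`` gets a higher deletion
    rate in cases than controls (the "hotspot" scenario); carriers of
    the effect band may carry two deletions with probability
    ``second_event_rate``.
    """

    background_del_rate: float = 0.01
    background_ins_rate: float = 0.008
    effect_band: str | None = None
    effect_case_rate: float = 0.08
    effect_control_rate: float = 0.017
    second_event_rate: float = 0.0
    homozygous_prob: float = 0.05
    cn4_prob: float = 0.1
    min_markers: int = 10
    max_markers: int = 40
    excluded_stains: tuple[str, ...] = ("acen",)

    def rates(self) -> list[float]:
        return [
            self.background_del_rate,
            self.background_ins_rate,
            self.effect_case_rate,
            self.effect_control_rate,
            self.second_event_rate,
            self.homozygous_prob,
            self.cn4_prob,
        ]


@dataclass
class CNVTruth:
    """Planted events plus the planting rates that produced them."""

    events: list[PlantedEvent]
    config: PlantingConfig

    def for_subject(self, subject_id: str) -> list[PlantedEvent]:
        return [e for e in self.events if e.subject_id == subject_id]

    def deletion_load(self, subjects: pd.DataFrame, band: str) -> pd.Series:
        """Per-subject count of planted deletions in ``band``."""
        load = pd.Series(0, index=subjects["subject_id"], dtype=int)
        for e in self.events:
            if e.band == band and e.copy_number < 2 and e.subject_id in load.index:
                load[e.subject_id] += 1
        return load

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "subject_id": e.subject_id,
                    "chrom": e.chrom,
                    "start": e.start,
                    "end": e.end,
                    "copy_number": e.copy_number,
                    "band": e.band,
                }
                for e in self.events
            ],
            columns=["subject_id", "chrom", "start", "end", "copy_number", "band"],
        )


def _place_event(
    rng: np.random.Generator,
    marker_map: MarkerMap,
    chrom: str,
    band_lo: int,
    band_hi: int,
    n_markers: int,
    min_markers: int = 1,
) -> tuple[int, int] | None:
    """Pick a run of ``n_markers`` markers inside a band; bp span covers them."""
    idx = marker_map.markers_in(chrom, band_lo, band_hi - 1)
    if len(idx) < n_markers:
        if len(idx) >= min_markers:
            n_markers = len(idx)  # shrink to what fits
        else:
            return None
    start_at = rng.integers(0, len(idx) - n_markers + 1)
    run = idx[start_at : start_at + n_markers]
    lo = int(marker_map.position[run[0]])
    hi = int(marker_map.position[run[-1]])
    # pad a little on each side without leaving the band
    pad_lo = int(rng.integers(0, 50))
    pad_hi = int(rng.integers(0, 50))
    return max(band_lo, lo - pad_lo), min(band_hi - 1, hi + pad_hi)


def plant_cnvs(
    subjects: pd.DataFrame,
    cytoband_map: CytobandMap,
    marker_map: MarkerMap,
    config: PlantingConfig,
    seed: int,
) -> CNVTruth:
    """Plant CNV events per subject/band according to ``config``.

    Deletions get copy number 1 (0 with probability ``homozygous_prob``)
    and insertions copy number 3 (4 with probability ``cn4_prob``).
    Events are placed uniformly within their band over marker runs of
    ``min_markers``..``max_markers`` markers.
    """
    for r in config.rates():
        if not (0.0 <= r <= 1.0):
            raise ValueError("planting rates must be in [0, 1]")
    rng = np.random.default_rng(seed)
    events: list[PlantedEvent] = []

    bands = cytoband_map.bands
    usable = bands[~bands["stain"].isin(config.excluded_stains)]

    def sample_cn(deletion: bool) -> int:
        if deletion:
            return 0 if rng.random() < config.homozygous_prob else 1
        return 4 if rng.random() < config.cn4_prob else 3

    def add_event(
        subject_id: str,
        band_row: pd.Series,
        deletion: bool,
        sub: tuple[int, int] | None = None,
    ) -> None:
        n_mk = int(rng.integers(config.min_markers, config.max_markers + 1))
        lo_b, hi_b = sub if sub is not None else (int(band_row["start"]), int(band_row["end"]))
        placed = _place_event(
            rng, marker_map, str(band_row["chrom"]), lo_b, hi_b, n_mk, config.min_markers
        )
        if placed is None:
            raise ValueError(
                f"event of {n_mk} markers does not fit in band {band_row['name']}"
            )
        lo, hi = placed
        events.append(
            PlantedEvent(
                subject_id=subject_id,
                chrom=str(band_row["chrom"]),
                start=lo,
                end=hi,
                copy_number=sample_cn(deletion),
                band=str(band_row["name"]),
            )
        )

    for _, subj in subjects.iterrows():
        sid = str(subj["subject_id"])
        is_case = subj["diagnosis"] == "case"
        for _, band_row in usable.iterrows():
            name = str(band_row["name"])
            if config.effect_band is not None and name == config.effect_band:
                rate = config.effect_case_rate if is_case else config.effect_control_rate
                if rng.random() < rate:
                    two = rng.random() < config.second_event_rate
                    if two:
                        # two disjoint deletions: one per band half
                        mid = (int(band_row["start"]) + int(band_row["end"])) // 2
                        add_event(sid, band_row, True, sub=(int(band_row["start"]), mid))
                        add_event(sid, band_row, True, sub=(mid, int(band_row["end"])))
                    else:
                        add_event(sid, band_row, deletion=True)
            else:
                if rng.random() < config.background_del_rate:
                    add_event(sid, band_row, deletion=True)
                if rng.random() < config.background_ins_rate:
                    add_event(sid, band_row, deletion=False)
    return CNVTruth(events=events, config=config)
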