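"""Marker maps and cytogenetic band maps.

Coordinates are 1-based. Band intervals are inclusive-start,
exclusive-end (a band [s, e) covers positions s .. e-1); everything
downstream that works on calls uses 1-based inclusive spans.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CytobandMap", "MarkerMap", "generate_marker_map"]


@dataclass
class CytobandMap:
    """Cytogenetic bands plus telomere/centromere annotation.

    Attributes
    ----------
    bands
        One row per band: ``chrom``, ``start`` (1-based, inclusive),
        ``end`` (exclusive), ``name``, ``stain``. Bands tile each
        chromosome without overlap.
    telomeres
        Per chromosome, list of ``(start, end)`` half-open intervals.
    centromeres
        Per chromosome, one ``(start, end)`` half-open interval.
    """

    bands: pd.DataFrame
    telomeres: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    centromeres: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, grp in self.bands.groupby("chrom", sort=False):
            g = grp.sort_values("start")
            if not (g["end"].to_numpy()[:-1] == g["start"].to_numpy()[1:]).all():
                raise ValueError(f"bands do not tile chromosome {chrom}")

    @property
    def n_bands(self) -> int:
        return len(self.bands)

    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.bands["chrom"]))

    def band_interval(self, name: str) -> tuple[str, int, int]:
        row = self.bands.loc[self.bands["name"] == name]
        if row.empty:
            raise KeyError(f"no such band: {name}")
        r = row.iloc[0]
        return str(r["chrom"]), int(r["start"]), int(r["end"])

    def assign(self, chrom: np.ndarray, position: np.ndarray) -> np.ndarray:
        """Band name for each (chrom, position) pair. Vectorized."""
        out = np.empty(len(position), dtype=object)
        for c, grp in self.bands.groupby("chrom", sort=False):
            mask = chrom == c
            if not mask.any():
                continue
            g = grp.sort_values("start")
            starts = g["start"].to_numpy()
            ends = g["end"].to_numpy()
            names = g["name"].to_numpy()
            idx = np.searchsorted(starts, position[mask], side="right") - 1
            if (idx < 0).any() or (position[mask] >= ends[np.clip(idx, 0, None)]).any():
                raise ValueError(f"position outside band range on chromosome {c}")
            out[mask] = names[idx]
        return out

    def tel_cen_intervals(self, chrom: str) -> list[tuple[int, int]]:
        ivs = list(self.telomeres.get(chrom, []))
        if chrom in self.centromeres:
            ivs.append(self.centromeres[chrom])
        return ivs


@dataclass
class MarkerMap:
    """Ordered genome map of array markers.

    Positions are strictly increasing within each chromosome and each
    marker carries a GC-fraction value (``gc_track``) and its cytoband
    assignment.
    """

    marker_id: np.ndarray
    chrom: np.ndarray
    position: np.ndarray
    gc_track: np.ndarray
    band: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.marker_id)
        for name in ("chrom", "position", "gc_track", "band"):
            if len(getattr(self, name)) != n:
                raise ValueError("marker map fields have unequal lengths")
        if not np.isfinite(self.gc_track).all():
            raise ValueError("gc_track contains non-finite values")
        for c in self.chromosomes():
            pos = self.position[self.chrom == c]
            if not (np.diff(pos) > 0).all():
                raise ValueError(f"positions not strictly increasing on {c}")

    @property
    def n_markers(self) -> int:
        return len(self.marker_id)

    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.chrom))

    def chrom_indices(self, chrom: str) -> np.ndarray:
        return np.flatnonzero(self.chrom == chrom)

    def markers_in(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Global indices of markers with start <= position <= end."""
        idx = self.chrom_indices(chrom)
        pos = self.position[idx]
        lo = np.searchsorted(pos, start, side="left")
        hi = np.searchsorted(pos, end, side="right")
        return idx[lo:hi]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "marker_id": self.marker_id,
                "chrom": self.chrom,
                "position": self.position,
                "gc": self.gc_track,
                "band": self.band,
            }
        )


def _unique_sorted_ints(rng: np.random.Generator, lo: int, hi: int, n: int) -> np.ndarray:
    """n distinct integers in [lo, hi), sorted."""
    if hi - lo < n:
        raise ValueError("interval too small for requested marker count")
    seen: set[int] = set()
    while len(seen) < n:
        seen.update(rng.integers(lo, hi, size=n - len(seen)).tolist())
    return np.array(sorted(seen), dtype=np.int64)


def _smooth_gc(position: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Low-frequency GC field mapped into [0.3, 0.7]."""
    span = max(position.max() - position.min(), 1)
    x = (position - position.min()) / span
    s = np.zeros_like(x, dtype=float)
    for freq in (1.0, 2.0, 5.0):
        phase = rng.uniform(0, 2 * np.pi)
        s += rng.uniform(0.3, 1.0) * np.sin(2 * np.pi * freq * x + phase)
    peak = np.abs(s).max()
    if peak > 0:
        s /= peak
    return 0.5 + 0.2 * s


def generate_marker_map(
    n_chrom: int,
    markers_per_band: int,
    bands_per_chrom: int,
    seed: int,
    band_bp: int = 1_000_000,
    telomere_bp: int | None = None,
) -> tuple[MarkerMap, CytobandMap]:
    """Generate a scaled-down array marker map and its cytoband map.

    Marker positions are drawn uniformly within each band and sorted;
    the GC track is a smooth low-frequency field in [0.3, 0.7]. The
    middle band(s) of each chromosome are stained ``acen`` and define
    the centromere; short terminal intervals define the telomeres.
    """
    if n_chrom < 1 or markers_per_band < 1 or bands_per_chrom < 1:
        raise ValueError("n_chrom, markers_per_band and bands_per_chrom must be >= 1")
    rng = np.random.default_rng(seed)
    if telomere_bp is None:
        telomere_bp = max(band_bp // 50, 1)

    band_rows = []
    telomeres: dict[str, list[tuple[int, int]]] = {}
    centromeres: dict[str, tuple[int, int]] = {}
    mid = bands_per_chrom / 2.0
    acen_idx = (
        {bands_per_chrom // 2 - 1, bands_per_chrom // 2}
        if bands_per_chrom % 2 == 0 and bands_per_chrom >= 4
        else {bands_per_chrom // 2}
        if bands_per_chrom >= 3
        else set()
    )

    ids, chroms, positions, bands_of_marker = [], [], [], []
    for ci in range(n_chrom):
        chrom = str(ci + 1)
        chrom_len = bands_per_chrom * band_bp
        telomeres[chrom] = [(1, 1 + telomere_bp), (chrom_len + 1 - telomere_bp, chrom_len + 1)]
        p_count = q_count = 0
        cen_lo, cen_hi = None, None
        for bi in range(bands_per_chrom):
            start = 1 + bi * band_bp
            end = start + band_bp
            if bi < mid:
                p_count += 1
                name = f"{chrom}p{p_count}"
            else:
                q_count += 1
                name = f"{chrom}q{q_count}"
            if bi in acen_idx:
                stain = "acen"
                cen_lo = start if cen_lo is None else cen_lo
                cen_hi = end
            else:
                stain = "gpos50" if bi % 2 else "gneg"
            band_rows.append({"chrom": chrom, "start": start, "end": end, "name": name, "stain": stain})

            pos = _unique_sorted_ints(rng, start, end, markers_per_band)
            positions.append(pos)
            chroms.extend([chrom] * markers_per_band)
            bands_of_marker.extend([name] * markers_per_band)
            ids.extend(f"m{chrom}_{bi}_{k}" for k in range(markers_per_band))
        if cen_lo is not None:
            centromeres[chrom] = (cen_lo, cen_hi)

    position = np.concatenate(positions)
    chrom_arr = np.array(chroms, dtype=object)
    gc = np.empty(len(position))
    for c in dict.fromkeys(chroms):
        m = chrom_arr == c
        gc[m] = _smooth_gc(position[m], rng)

    marker_map = MarkerMap(
        marker_id=np.array(ids, dtype=object),
        chrom=chrom_arr,
        position=position,
        gc_track=gc,
        band=np.array(bands_of_marker, dtype=object),
    )
    cyto = CytobandMap(bands=pd.DataFrame(band_rows), telomeres=telomeres, centromeres=centromeres)
    return marker_map, cyto
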