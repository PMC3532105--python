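"""LRR/BAF signal simulation over a marker map.

The emission model is configurable: per-copy-number LRR means/SDs and
BAF genotype clusters. Defaults follow standard SNP-array intensity
behavior (deletions shift LRR negative, duplications positive; BAF
clusters depend on the number of copies).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .maps import MarkerMap
from .planting import CNVTruth

__all__ = ["EmissionParams", "SampleArray", "simulate_array"]

# BAF cluster positions per copy number (CN0 draws uniform noise instead)
_BAF_CLUSTERS = {
    1: np.array([0.0, 1.0]),
    2: np.array([0.0, 0.5, 1.0]),
    3: np.array([0.0, 1 / 3, 2 / 3, 1.0]),
    4: np.array([0.0, 0.25, 0.5, 0.75, 1.0]),
}


@dataclass
class EmissionParams:
    """Per-copy-number LRR emission and BAF cluster noise."""

    lrr_mean: dict[int, float] = field(
        default_factory=lambda: {0: -3.5, 1: -0.55, 2: 0.0, 3: 0.35, 4: 0.65}
    )
    lrr_sd: dict[int, float] = field(
        default_factory=lambda: {0: 0.3, 1: 0.25, 2: 0.2, 3: 0.25, 4: 0.3}
    )
    baf_sd: float = 0.03
    b_allele_freq: float = 0.5

    def cluster_weights(self, cn: int) -> np.ndarray:
        """Binomial(cn, p) weights over the B-allele count clusters."""
        p = self.b_allele_freq
        k = np.arange(cn + 1)
        from scipy.stats import binom

        return binom.pmf(k, cn, p)


@dataclass
class SampleArray:
    """One subject's LRR and BAF vectors over a marker map."""

    subject_id: str
    lrr: np.ndarray
    baf: np.ndarray

    def __post_init__(self) -> None:
        if len(self.lrr) != len(self.baf):
            raise ValueError("lrr and baf lengths differ")
        if not np.isfinite(self.lrr).all():
            raise ValueError("lrr contains non-finite values")
        if (self.baf < 0).any() or (self.baf > 1).any():
            raise ValueError("baf outside [0, 1]")


def _baf_for_cn(rng: np.random.Generator, cn: int, n: int, params: EmissionParams) -> np.ndarray:
    if cn == 0:
        return rng.uniform(0.0, 1.0, size=n)  # no signal: uniform noise
    clusters = _BAF_CLUSTERS[cn]
    weights = params.cluster_weights(cn)
    idx = rng.choice(len(clusters), size=n, p=weights)
    vals = clusters[idx] + rng.normal(0.0, params.baf_sd, size=n)
    return np.clip(vals, 0.0, 1.0)


def simulate_array(
    subject_id: str,
    marker_map: MarkerMap,
    cnv_truth: CNVTruth | None,
    emission_params: EmissionParams,
    wave_amplitude: float,
    seed: int,
) -> SampleArray:
    """Simulate one subject's LRR/BAF track.

    Baseline LRR is Normal(CN2 mean, CN2 SD) plus an additive
    GC-correlated wave ``wave_amplitude * (gc - mean(gc))``. Inside
    planted events the LRR mean/SD switch to the event's copy number
    and BAF follows the copy-number-appropriate cluster pattern.
    """
    rng = np.random.default_rng(seed)
    m = marker_map.n_markers
    lrr = rng.normal(emission_params.lrr_mean[2], emission_params.lrr_sd[2], size=m)
    baf = _baf_for_cn(rng, 2, m, emission_params)

    if cnv_truth is not None:
        chroms = set(marker_map.chromosomes())
        for ev in cnv_truth.for_subject(subject_id):
            if ev.chrom not in chroms:
                raise ValueError(f"planted event on {ev.chrom} outside marker map")
            cpos = marker_map.position[marker_map.chrom_indices(ev.chrom)]
            if ev.start > cpos[-1] or ev.end < cpos[0]:
                raise ValueError("planted event outside marker map coordinates")
            idx = marker_map.markers_in(ev.chrom, ev.start, ev.end)
            if len(idx) == 0:
                continue
            cn = ev.copy_number
            lrr[idx] = rng.normal(emission_params.lrr_mean[cn], emission_params.lrr_sd[cn], size=len(idx))
            baf[idx] = _baf_for_cn(rng, cn, len(idx), emission_params)

    gc = marker_map.gc_track
    lrr = lrr + wave_amplitude * (gc - gc.mean())
    return SampleArray(subject_id=subject_id, lrr=lrr, baf=baf)
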