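"""Hidden-Markov segmentation of joint (LRR, BAF) tracks.

Five states correspond to copy numbers 0-4. LRR emissions are normal
per state; BAF emissions are cluster mixtures determined by the copy
number (uniform for CN0). Transition probability between adjacent
markers grows with genomic distance:
``p_change(d) = p_base * (1 - exp(-d / dist_scale))``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .types import Segment

__all__ = [
    "HmmParams",
    "hmm_segment",
    "segments_from_path",
    "transition_matrix",
    "viterbi_path",
    "viterbi_paths_batch",
]

STATES = (0, 1, 2, 3, 4)

_BAF_CLUSTERS = {
    1: np.array([0.0, 1.0]),
    2: np.array([0.0, 0.5, 1.0]),
    3: np.array([0.0, 1 / 3, 2 / 3, 1.0]),
    4: np.array([0.0, 0.25, 0.5, 0.75, 1.0]),
}


@dataclass
class HmmParams:
    lrr_mean: dict[int, float] = field(
        default_factory=lambda: {0: -3.5, 1: -0.55, 2: 0.0, 3: 0.35, 4: 0.65}
    )
    lrr_sd: dict[int, float] = field(
        default_factory=lambda: {0: 1.0, 1: 0.3, 2: 0.25, 3: 0.3, 4: 0.35}
    )
    baf_sd: float = 0.05
    b_allele_freq: float = 0.5
    use_baf: bool = True
    p_base: float = 0.02
    dist_scale: float = 50_000.0
    neutral_weight: float = 0.5  # share of change mass returning to CN2
    p_init_neutral: float = 0.99
    baf_mixture_floor: float = 0.05


def transition_matrix(d: float, params: HmmParams) -> np.ndarray:
    """Row-stochastic 5x5 transition matrix for a marker gap of d bp."""
    pc = params.p_base * (1.0 - np.exp(-d / params.dist_scale))
    A = np.zeros((5, 5))
    for s in range(5):
        A[s, s] = 1.0 - pc
        if s == 2:
            for t in range(5):
                if t != s:
                    A[s, t] = pc / 4.0
        else:
            others = [t for t in range(5) if t not in (s, 2)]
            A[s, 2] = pc * params.neutral_weight
            for t in others:
                A[s, t] = pc * (1.0 - params.neutral_weight) / len(others)
    return A


def initial_distribution(params: HmmParams) -> np.ndarray:
    pi = np.full(5, (1.0 - params.p_init_neutral) / 4.0)
    pi[2] = params.p_init_neutral
    return pi


def _baf_log_density(baf: np.ndarray, cn: int, params: HmmParams) -> np.ndarray:
    if cn == 0:
        return np.zeros(len(baf))  # Uniform(0,1)
    clusters = _BAF_CLUSTERS[cn]
    from scipy.stats import binom

    w = binom.pmf(np.arange(cn + 1), cn, params.b_allele_freq)
    dens = np.zeros(len(baf))
    for c, wc in zip(clusters, w):
        dens += wc * norm.pdf(baf, c, params.baf_sd)
    floor = params.baf_mixture_floor
    return np.log((1.0 - floor) * dens + floor)


def emission_log_likelihood(
    lrr: np.ndarray, baf: np.ndarray | None, params: HmmParams
) -> np.ndarray:
    """T x 5 log emission matrix."""
    lrr = np.asarray(lrr, dtype=float)
    E = np.empty((len(lrr), 5))
    for s in STATES:
        E[:, s] = norm.logpdf(lrr, params.lrr_mean[s], params.lrr_sd[s])
        if params.use_baf and baf is not None:
            E[:, s] += _baf_log_density(np.asarray(baf, dtype=float), s, params)
    return E


def viterbi_path(
    lrr: np.ndarray,
    baf: np.ndarray | None,
    positions: np.ndarray,
    params: HmmParams,
) -> tuple[np.ndarray, float]:
    """Most probable state path and its joint log probability."""
    pos = np.asarray(positions, dtype=float)
    if (np.diff(pos) <= 0).any():
        raise ValueError("positions must be strictly increasing")
    E = emission_log_likelihood(lrr, baf, params)
    T = E.shape[0]
    with np.errstate(divide="ignore"):
        delta = np.log(initial_distribution(params)) + E[0]
        psi = np.zeros((T, 5), dtype=np.int8)
        for t in range(1, T):
            logA = np.log(transition_matrix(pos[t] - pos[t - 1], params))
            cand = delta[:, None] + logA  # prev x next
            psi[t] = np.argmax(cand, axis=0)
            delta = cand[psi[t], np.arange(5)] + E[t]
    path = np.empty(T, dtype=np.int8)
    path[-1] = int(np.argmax(delta))
    for t in range(T - 2, -1, -1):
        path[t] = psi[t + 1][path[t + 1]]
    return path, float(delta.max())


def _log_transition_tensor(gaps: np.ndarray, params: HmmParams) -> np.ndarray:
    """(T-1) x 5 x 5 log transition matrices; same formulas as
    :func:`transition_matrix`, vectorized over marker gaps."""
    pc = params.p_base * (1.0 - np.exp(-np.asarray(gaps, dtype=float) / params.dist_scale))
    w = params.neutral_weight
    with np.errstate(divide="ignore"):
        log_stay = np.log1p(-pc)
        log_from2 = np.log(pc / 4.0)
        log_to2 = np.log(pc * w)
        log_other = np.log(pc * (1.0 - w) / 3.0)
    logA = np.empty((len(pc), 5, 5))
    for s in range(5):
        logA[:, s, s] = log_stay
    non2 = [0, 1, 3, 4]
    for t in non2:
        logA[:, 2, t] = log_from2
    for s in non2:
        logA[:, s, 2] = log_to2
        for t in non2:
            if t != s:
                logA[:, s, t] = log_other
    return logA


def viterbi_paths_batch(
    lrr: np.ndarray,
    baf: np.ndarray | None,
    positions: np.ndarray,
    params: HmmParams,
) -> np.ndarray:
    """Viterbi paths for a subjects x markers batch sharing one marker map.

    Returns a subjects x markers int8 state matrix. Equivalent to
    :func:`viterbi_path` per row, but amortizes the transition tensor.
    """
    pos = np.asarray(positions, dtype=float)
    if (np.diff(pos) <= 0).any():
        raise ValueError("positions must be strictly increasing")
    X = np.atleast_2d(np.asarray(lrr, dtype=float))
    B, T = X.shape
    Bf = None if baf is None else np.atleast_2d(np.asarray(baf, dtype=float))

    E = np.empty((B, T, 5))
    for s in STATES:
        E[:, :, s] = norm.logpdf(X, params.lrr_mean[s], params.lrr_sd[s])
        if params.use_baf and Bf is not None:
            E[:, :, s] += _baf_log_density(Bf.ravel(), s, params).reshape(B, T)

    logA = _log_transition_tensor(np.diff(pos), params)
    with np.errstate(divide="ignore"):
        delta = np.log(initial_distribution(params))[None, :] + E[:, 0, :]
    psi = np.zeros((T, B, 5), dtype=np.int8)
    rows = np.arange(B)[:, None]
    cols = np.arange(5)[None, :]
    for t in range(1, T):
        cand = delta[:, :, None] + logA[t - 1][None, :, :]  # B x prev x next
        arg = np.argmax(cand, axis=1)
        psi[t] = arg
        delta = cand[rows, arg, cols] + E[:, t, :]
    paths = np.empty((B, T), dtype=np.int8)
    paths[:, -1] = np.argmax(delta, axis=1)
    for t in range(T - 2, -1, -1):
        nxt = paths[:, t + 1]
        paths[:, t] = psi[t + 1][np.arange(B), nxt]
    return paths


def segments_from_path(
    path: np.ndarray, lrr: np.ndarray, positions: np.ndarray, chromosome: str
) -> list[Segment]:
    """Collapse a state path into same-state segments."""
    segments: list[Segment] = []
    start = 0
    x = np.asarray(lrr, dtype=float)
    for t in range(1, len(path) + 1):
        if t == len(path) or path[t] != path[start]:
            segments.append(
                Segment(
                    chromosome=chromosome,
                    first=start,
                    last=t - 1,
                    start=int(positions[start]),
                    end=int(positions[t - 1]),
                    mean_lrr=float(x[start:t].mean()),
                    source="HMM",
                    state=int(path[start]),
                )
            )
            start = t
    return segments


def hmm_segment(
    lrr: np.ndarray,
    baf: np.ndarray | None,
    positions: np.ndarray,
    params: HmmParams | None = None,
    chromosome: str = "1",
) -> list[Segment]:
    """Viterbi-decode one chromosome and collapse same-state runs.

    Neutral (CN2) segments are returned too — the consensus stage
    excludes them — so segments always cover every marker.
    """
    params = params or HmmParams()
    x = np.asarray(lrr, dtype=float)
    if len(x) == 0:
        return []
    path, _ = viterbi_path(x, baf, positions, params)
    return segments_from_path(path, x, positions, chromosome)
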