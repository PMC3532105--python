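"""Circular binary segmentation of an LRR vector.

Recursive change-point search over circular arcs: the test statistic
for an arc is the two-sample t-like contrast of the arc mean against
the rest of the (current) segment; a split is accepted iff its
permutation p-value is <= alpha. Because the noise scale enters both
the observed and the permuted statistics identically, permutation
comparisons are computed scale-free.

Arcs wider than half the segment are complements of narrower arcs and
carry the same |t|, so the search enumerates widths 1..n-1 only when
unbounded; ``max_width`` bounds the arc width for speed (long events
are then found as complements only up to that bound).
"""

from __future__ import annotations

import numpy as np

from .types import Segment

__all__ = ["cbs_segment", "max_arc_stat"]


def _arc_stats_batch(X: np.ndarray, max_width: int | None) -> np.ndarray:
    """Max |t| (sigma-free) over all arcs, per row of X (B x n)."""
    B, n = X.shape
    S = np.concatenate([np.zeros((B, 1)), np.cumsum(X, axis=1)], axis=1)
    tot = S[:, -1:]
    wmax = min(max_width or n - 1, n - 1)
    best = np.zeros(B)
    for k in range(1, wmax + 1):
        D = S[:, k:] - S[:, :-k]
        t = np.abs(D / k - (tot - D) / (n - k)) / np.sqrt(1.0 / k + 1.0 / (n - k))
        m = t.max(axis=1)
        np.maximum(best, m, out=best)
    return best


def max_arc_stat(
    x: np.ndarray, sigma: float | None = None, max_width: int | None = None
) -> tuple[float, int, int]:
    """Maximizing arc of a vector: returns (t_max, i, j) with arc x[i:j].

    ``sigma`` scales the reported statistic (default: robust estimate
    from successive differences); the location of the maximum does not
    depend on it.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 2:
        return 0.0, 0, n
    if sigma is None:
        sigma = estimate_sigma(x)
    S = np.concatenate([[0.0], np.cumsum(x)])
    tot = S[-1]
    wmax = min(max_width or n - 1, n - 1)
    best_t, best_i, best_j = -1.0, 0, n
    for k in range(1, wmax + 1):
        D = S[k:] - S[:-k]
        t = np.abs(D / k - (tot - D) / (n - k)) / np.sqrt(1.0 / k + 1.0 / (n - k))
        i = int(np.argmax(t))
        if t[i] > best_t:
            best_t, best_i, best_j = float(t[i]), i, i + k
    if sigma > 0:
        best_t /= sigma
    else:
        best_t = np.inf if best_t > 0 else 0.0
    return best_t, best_i, best_j


def estimate_sigma(x: np.ndarray) -> float:
    """Robust noise SD from successive differences (shift-insensitive)."""
    d = np.diff(np.asarray(x, dtype=float))
    if len(d) == 0:
        return 0.0
    return float(np.median(np.abs(d)) / (np.sqrt(2.0) * 0.674489750196082))


def _split_accepted(
    x: np.ndarray,
    t_obs_scalefree: float,
    alpha: float,
    n_perm: int,
    rng: np.random.Generator,
    max_width: int | None,
    batch: int = 64,
) -> bool:
    """Sequential permutation test of the max arc statistic.

    Early-rejects once the exceedance count guarantees p > alpha, and
    early-accepts on zero exceedances only once the 95% upper
    confidence bound on p (~3/done) is below alpha, so borderline-null
    splits are not waved through.
    """
    reject_at = alpha * (n_perm + 1) - 1  # exceed > this => p > alpha
    accept_done = int(np.ceil(3.0 / alpha))
    exceed = 0
    done = 0
    while done < n_perm:
        b = min(batch, n_perm - done)
        P = rng.permuted(np.broadcast_to(x, (b, len(x))).copy(), axis=1)
        stats = _arc_stats_batch(P, max_width)
        exceed += int((stats >= t_obs_scalefree).sum())
        done += b
        if exceed > reject_at:
            return False
        if exceed == 0 and done >= accept_done:
            return True
    return (exceed + 1) / (n_perm + 1) <= alpha


def cbs_segment(
    lrr: np.ndarray,
    positions: np.ndarray,
    alpha: float = 0.01,
    n_perm: int = 1000,
    min_markers: int = 3,
    seed: int = 0,
    max_width: int | None = None,
    prune_tol: float = 0.05,
    prune_sd: float | None = None,
    chromosome: str = "1",
) -> list[Segment]:
    """Segment one chromosome's LRR vector by circular binary segmentation.

    Returns ordered, disjoint segments covering every marker. A vector
    shorter than ``min_markers`` is returned as a single flagged
    segment. Adjacent segments whose means differ by less than
    ``prune_tol`` are merged after the recursion; ``prune_sd`` widens
    the tolerance to that many (robustly estimated) noise SDs, undoing
    splits that are significant but too shallow to be copy-number
    shifts.
    """
    x = np.asarray(lrr, dtype=float)
    pos = np.asarray(positions)
    n = len(x)
    if len(pos) != n:
        raise ValueError("positions length must match lrr length")
    if n == 0:
        return []

    def make_segment(lo: int, hi: int, flagged: bool = False) -> Segment:
        return Segment(
            chromosome=chromosome,
            first=lo,
            last=hi - 1,
            start=int(pos[lo]),
            end=int(pos[hi - 1]),
            mean_lrr=float(x[lo:hi].mean()),
            source="CBS",
            flagged=flagged,
        )

    if n < min_markers:
        return [make_segment(0, n, flagged=True)]

    rng = np.random.default_rng(seed)
    cuts: list[int] = []

    def recurse(lo: int, hi: int) -> None:
        m = hi - lo
        if m < 2:
            return
        seg = x[lo:hi]
        if np.allclose(seg, seg[0]):
            return
        # scale-free observed statistic for permutation comparison
        t_obs, i, j = max_arc_stat(seg, sigma=1.0, max_width=max_width)
        if not np.isfinite(t_obs) or t_obs <= 0:
            return
        if not _split_accepted(seg, t_obs, alpha, n_perm, rng, max_width):
            return
        for cut in (lo + i, lo + j):
            if lo < cut < hi:
                cuts.append(cut)
        pieces = sorted({lo, *(c for c in (lo + i, lo + j) if lo < c < hi), hi})
        for a, b in zip(pieces[:-1], pieces[1:]):
            if (a, b) != (lo, hi):
                recurse(a, b)

    recurse(0, n)

    bounds = sorted({0, n, *cuts})
    segments = [make_segment(a, b) for a, b in zip(bounds[:-1], bounds[1:])]

    tol = prune_tol
    if prune_sd is not None:
        tol = max(tol, prune_sd * estimate_sigma(x))

    # prune: merge adjacent segments with small mean difference
    merged = True
    while merged and len(segments) > 1:
        merged = False
        diffs = [abs(segments[i].mean_lrr - segments[i + 1].mean_lrr) for i in range(len(segments) - 1)]
        k = int(np.argmin(diffs))
        if diffs[k] < tol:
            a, b = segments[k], segments[k + 1]
            segments[k : k + 2] = [make_segment(a.first, b.last + 1)]
            merged = True
    return segments
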