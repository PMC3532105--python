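"""Burden metrics, cytoband CNV features, group tests and the
two-stage cytoband screen."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .cnvcall.regions import CNVRegion
from .cnvcall.types import CNVCall

__all__ = [
    "ancova_f",
    "compute_burden",
    "cytoband_features",
    "screen_cytobands",
    "testable_features",
    "two_sample_t",
]

KINDS = ("cnv", "del", "ins")


def compute_burden(
    calls: list[CNVCall], regions: list[CNVRegion], subjects: pd.DataFrame
) -> pd.DataFrame:
    """Per-subject totals: CNVs, deletions, rare CNVs, rare deletions.

    A call's rare status is inherited from the cross-sample region that
    contains it.
    """
    rare_of_call: dict[int, bool] = {}
    for r in regions:
        for m in r.members:
            rare_of_call[id(m)] = r.rare
    out = pd.DataFrame(
        0,
        index=pd.Index(subjects["subject_id"], name="subject_id"),
        columns=["total_cnvs", "total_deletions", "total_rare_cnvs", "total_rare_deletions"],
        dtype=int,
    )
    for c in calls:
        if c.subject_id not in out.index:
            continue
        rare = rare_of_call.get(id(c), False)
        is_del = c.cnv_class == "deletion"
        out.loc[c.subject_id, "total_cnvs"] += 1
        if is_del:
            out.loc[c.subject_id, "total_deletions"] += 1
        if rare:
            out.loc[c.subject_id, "total_rare_cnvs"] += 1
            if is_del:
                out.loc[c.subject_id, "total_rare_deletions"] += 1
    return out


def cytoband_features(
    calls: list[CNVCall],
    cytoband_map,
    subjects: pd.DataFrame,
    straddle: str = "overlap",
) -> pd.DataFrame:
    """Subject x (band, kind) count matrix for kinds cnv/del/ins.

    ``straddle="overlap"`` increments every band the call's bp span
    overlaps; ``"midpoint"`` uses only the band containing the call
    midpoint. ``cnv = del + ins`` holds per band/subject either way.
    """
    if straddle not in ("overlap", "midpoint"):
        raise ValueError("straddle must be 'overlap' or 'midpoint'")
    bands = cytoband_map.bands
    index = pd.Index(subjects["subject_id"], name="subject_id")
    cols = pd.MultiIndex.from_product([bands["name"], KINDS], names=["band", "kind"])
    feat = pd.DataFrame(0, index=index, columns=cols, dtype=int)
    for c in calls:
        if c.subject_id not in index:
            continue
        grp = bands[bands["chrom"] == c.chromosome]
        if straddle == "midpoint":
            mid = (c.start + c.end) // 2
            hit = grp[(grp["start"] <= mid) & (mid < grp["end"])]["name"]
        else:
            hit = grp[(c.start < grp["end"]) & (c.end >= grp["start"])]["name"]
        kind = "del" if c.cnv_class == "deletion" else "ins"
        for band in hit:
            feat.loc[c.subject_id, (band, "cnv")] += 1
            feat.loc[c.subject_id, (band, kind)] += 1
    return feat


def testable_features(features: pd.DataFrame) -> pd.Index:
    """Features (band, kind) with at least one nonzero count."""
    return features.columns[(features != 0).any(axis=0)]


def two_sample_t(
    x: np.ndarray | pd.Series | pd.DataFrame,
    is_case: np.ndarray,
    welch: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided two-sample t-test; positive t means higher mean in cases.

    Pooled-variance Student by default; Welch with ``welch=True``.
    Vectorized over columns when ``x`` is 2-D. Zero pooled variance
    yields (nan, nan).
    """
    arr = np.asarray(x, dtype=float)
    mask = np.asarray(is_case, dtype=bool)
    cases, controls = arr[mask], arr[~mask]
    if len(cases) < 2 or len(controls) < 2:
        raise ValueError("need at least two subjects per group")
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(cases, controls, axis=0, equal_var=not welch)
    return np.asarray(t, dtype=float), np.asarray(p, dtype=float)


def _design(covariates: pd.DataFrame) -> np.ndarray:
    if covariates.shape[1] == 0:
        return np.empty((len(covariates), 0))
    dummies = pd.get_dummies(covariates.astype({c: "category" for c in covariates.columns
                                                if covariates[c].dtype == object}),
                             drop_first=True, dtype=float)
    return dummies.to_numpy()


def _rss(y: np.ndarray, D: np.ndarray) -> tuple[float, int]:
    beta, _, rank, _ = np.linalg.lstsq(D, y, rcond=None)
    resid = y - D @ beta
    return float(resid @ resid), int(rank)


def ancova_f(
    feature: np.ndarray | pd.Series,
    diagnosis: np.ndarray | pd.Series,
    covariates: pd.DataFrame,
) -> tuple[float, float]:
    """Partial (Type II) F-test for diagnosis given the covariates.

    Linear model with categorical dummy encodings; F compares the full
    model against the model without the diagnosis term.
    """
    y = np.asarray(feature, dtype=float)
    if np.allclose(y, y[0]):
        return 0.0, 1.0
    diag_arr = np.asarray(diagnosis)
    if diag_arr.dtype.kind in "OUS":
        diag = (diag_arr == "case").astype(float)
    else:
        diag = diag_arr.astype(float)
    n = len(y)
    C = _design(covariates)
    ones = np.ones((n, 1))
    D_red = np.column_stack([ones, C])
    D_full = np.column_stack([ones, C, diag])
    rss_red, rank_red = _rss(y, D_red)
    rss_full, rank_full = _rss(y, D_full)
    q = rank_full - rank_red
    df_resid = n - rank_full
    if q <= 0 or df_resid <= 0 or rss_full <= 0:
        return 0.0, 1.0
    F = ((rss_red - rss_full) / q) / (rss_full / df_resid)
    F = max(F, 0.0)
    p = float(stats.f.sf(F, q, df_resid))
    return float(F), p


def screen_cytobands(
    features: pd.DataFrame,
    is_case: np.ndarray,
    white_mask: np.ndarray,
    p1: float = 0.01,
    p2: float = 0.05,
    welch: bool = False,
) -> pd.DataFrame:
    """Two-stage cytoband feature screen.

    Stage 1: pooled t-test on all subjects at ``p1`` (uncorrected).
    Stage 2: the same test restricted to White subjects at ``p2``, with
    the group difference required to have the same sign. Features with
    zero pooled variance in either stage are untestable (never
    selected) and reported as such. Returns one row per feature.
    """
    is_case = np.asarray(is_case, dtype=bool)
    white_mask = np.asarray(white_mask, dtype=bool)
    X = features.to_numpy(dtype=float)
    t_all, p_all = two_sample_t(X, is_case, welch=welch)
    Xw = X[white_mask]
    if min((is_case[white_mask]).sum(), (~is_case[white_mask]).sum()) >= 2:
        t_w, p_w = two_sample_t(Xw, is_case[white_mask], welch=welch)
    else:  # stage 2 undefined: nothing can be selected
        t_w = np.full(X.shape[1], np.nan)
        p_w = np.full(X.shape[1], np.nan)

    testable = ~(np.isnan(t_all) | np.isnan(t_w))
    same_dir = np.sign(t_all) == np.sign(t_w)
    with np.errstate(invalid="ignore"):
        selected = testable & (p_all < p1) & (p_w < p2) & same_dir & (t_all != 0)
    out = pd.DataFrame(
        {
            "t": t_all,
            "p": p_all,
            "t_white": t_w,
            "p_white": p_w,
            "same_direction": same_dir,
            "testable": testable,
            "selected": selected,
        },
        index=features.columns,
    )
    return out
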