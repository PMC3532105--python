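"""Association of cytoband CNV features with brain-network loadings:
covariate-adjusted regression with nested-model variance explained,
Bonferroni arithmetic, deletion-load group ANOVA and region spans."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cnvcall.types import CNVCall
from .linmod import build_design, ols

__all__ = [
    "AssociationResult",
    "DeletionGroupSummary",
    "bonferroni_threshold",
    "deletion_group_anova",
    "regress_loading_on_feature",
    "region_span",
    "voxelwise_regression",
]


@dataclass
class AssociationResult:
    """One (component, feature) regression row."""

    component: int
    feature: str
    beta: float
    p: float
    delta_r2: float  # nested-model R2 difference for the CNV term
    semipartial_r2: float  # squared semi-partial, reported alongside
    n: int
    threshold: float = np.nan
    significant: bool = False


def bonferroni_threshold(n_components: int, n_features: int = 1, alpha: float = 0.05) -> float:
    """alpha / (n_components * n_features)."""
    if n_components < 1 or n_features < 1:
        raise ValueError("family sizes must be >= 1")
    return alpha / (n_components * n_features)


def regress_loading_on_feature(
    loadings: np.ndarray,
    feature: np.ndarray,
    age: np.ndarray,
    gender: np.ndarray,
    site: np.ndarray,
    component: int = 0,
    feature_name: str = "feature",
) -> AssociationResult | None:
    """OLS of one component's loadings on covariates plus a CNV metric.

    Returns None (skip, not error) for a constant feature. ``delta_r2``
    is R2(full) - R2(without the CNV term); the squared semi-partial
    correlation is reported alongside (they coincide, both are the RSS
    drop over the total sum of squares).
    """
    y = np.asarray(loadings, dtype=float)
    f = np.asarray(feature, dtype=float)
    if np.allclose(f, f[0]):
        return None
    D_full, names = build_design(age=age, gender=gender, site=site, extra={"cnv": f})
    D_red, red_names = build_design(age=age, gender=gender, site=site)
    fit_full = ols(y, D_full, names)
    fit_red = ols(y, D_red, red_names)
    beta, t, p = fit_full.coef("cnv")
    delta_r2 = max(fit_full.r2 - fit_red.r2, 0.0)
    semip = (fit_red.rss - fit_full.rss) / fit_full.tss if fit_full.tss > 0 else 0.0
    return AssociationResult(
        component=component,
        feature=feature_name,
        beta=beta,
        p=p,
        delta_r2=delta_r2,
        semipartial_r2=max(semip, 0.0),
        n=len(y),
    )


@dataclass
class DeletionGroupSummary:
    """Loading means per deletion-load level with one-way ANOVA."""

    levels: list[int]
    n_per_level: dict[int, int]
    mean_per_level: dict[int, float]
    f: float
    p: float
    percent_reduction: dict[int, float] = field(default_factory=dict)
    sign_flipped: bool = False
    absent_levels: list[int] = field(default_factory=list)


def deletion_group_anova(
    loadings: np.ndarray,
    deletion_load: np.ndarray,
    restrict_to: np.ndarray | None = None,
    expected_levels: tuple[int, ...] = (0, 1, 2),
) -> DeletionGroupSummary:
    """One-way ANOVA of loadings across deletion-load levels.

    Percent reduction of level L vs level 0 is
    ``100 * (mean0 - meanL) / mean0`` under the positive-mean sign
    convention: if the load-0 mean is negative the loadings are flipped
    for reporting (flagged via ``sign_flipped``). Levels with no
    subjects are omitted from the ANOVA and reported as absent.
    """
    y = np.asarray(loadings, dtype=float)
    load = np.asarray(deletion_load).astype(int)
    if restrict_to is not None:
        mask = np.asarray(restrict_to, dtype=bool)
        y, load = y[mask], load[mask]
    present = sorted(set(load.tolist()))
    groups = [y[load == lv] for lv in present]
    absent = [lv for lv in expected_levels if lv not in present]

    if len(groups) >= 2 and all(len(g) > 0 for g in groups):
        f, p = stats.f_oneway(*groups)
        if not np.isfinite(f):  # all groups identical
            f, p = 0.0, 1.0
    else:
        f, p = 0.0, 1.0

    flipped = False
    means = {lv: float(g.mean()) for lv, g in zip(present, groups)}
    if 0 in means and means[0] < 0:
        flipped = True
        y = -y
        means = {lv: -m for lv, m in means.items()}
    reductions = {}
    if 0 in means and means[0] != 0:
        for lv in present:
            reductions[lv] = 100.0 * (means[0] - means[lv]) / means[0]
    return DeletionGroupSummary(
        levels=present,
        n_per_level={lv: int((load == lv).sum()) for lv in present},
        mean_per_level=means,
        f=float(f),
        p=float(p),
        percent_reduction=reductions,
        sign_flipped=flipped,
        absent_levels=absent,
    )


def region_span(calls: list[CNVCall] | pd.DataFrame) -> tuple[int, int, int] | None:
    """(min start, max end, span) over a band's calls; span = end - start.

    Returns None for an empty call set.
    """
    if isinstance(calls, pd.DataFrame):
        if calls.empty:
            return None
        start = int(calls["start"].min())
        end = int(calls["end"].max())
    else:
        if not calls:
            return None
        start = min(c.start for c in calls)
        end = max(c.end for c in calls)
    return start, end, end - start


def voxelwise_regression(
    X: np.ndarray,
    feature: np.ndarray,
    age: np.ndarray,
    gender: np.ndarray,
    site: np.ndarray,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-voxel OLS of GMC on covariates plus the CNV feature.

    Vectorized across voxels; returns per-voxel beta, t, p plus
    Bonferroni and Benjamini-Hochberg significance masks.
    """
    X = np.asarray(X, dtype=float)
    n, V = X.shape
    D, names = build_design(age=age, gender=gender, site=site, extra={"cnv": np.asarray(feature, float)})
    j = names.index("cnv")
    pinv = np.linalg.pinv(D)
    B = pinv @ X  # p x V
    resid = X - D @ B
    rank = np.linalg.matrix_rank(D)
    df = n - rank
    sigma2 = (resid**2).sum(axis=0) / df
    var_j = np.linalg.pinv(D.T @ D)[j, j]
    se = np.sqrt(var_j * sigma2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = B[j] / se
    p = 2.0 * stats.t.sf(np.abs(t), df)

    from statsmodels.stats.multitest import multipletests

    bh_sig = multipletests(p, alpha=alpha, method="fdr_bh")[0]
    return pd.DataFrame(
        {
            "beta": B[j],
            "t": t,
            "p": p,
            "bonferroni_significant": p < alpha / V,
            "bh_significant": bh_sig,
        }
    )
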