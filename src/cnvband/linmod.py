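"""Small OLS helper shared by the loading-level tests and the
association module: design building with dummy coding, rank handling
via pivoted QR, and classic t/F inference."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats

__all__ = ["OLSFit", "build_design", "ols"]


@dataclass
class OLSFit:
    names: list[str]
    beta: np.ndarray
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    rss: float
    tss: float
    r2: float
    df_resid: int
    dropped: list[str]

    def coef(self, name: str) -> tuple[float, float, float]:
        """(beta, t, p) for a named regressor."""
        i = self.names.index(name)
        return float(self.beta[i]), float(self.t[i]), float(self.p[i])


def build_design(
    age: np.ndarray | None = None,
    gender: np.ndarray | None = None,
    site: np.ndarray | None = None,
    extra: dict[str, np.ndarray] | None = None,
    n: int | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Intercept + age + gender dummy + (s-1) site dummies + extras."""
    cols: list[np.ndarray] = []
    names: list[str] = []
    for arr in (age, gender, site):
        if arr is not None:
            n = len(arr)
    if extra:
        for v in extra.values():
            n = len(v)
    if n is None:
        raise ValueError("cannot infer number of rows")
    cols.append(np.ones(n))
    names.append("intercept")
    if age is not None:
        cols.append(np.asarray(age, dtype=float))
        names.append("age")
    if gender is not None:
        g = np.asarray(gender)
        if g.dtype.kind in "OUS":
            ref = "M" if "M" in set(g.tolist()) else sorted(set(g.tolist()))[0]
            cols.append((g == ref).astype(float))
        else:
            cols.append(g.astype(float))
        names.append("gender")
    if site is not None:
        s = pd.Series(np.asarray(site))
        levels = sorted(s.unique())
        for lev in levels[1:]:  # reference coding against the first site
            cols.append((s == lev).to_numpy(dtype=float))
            names.append(f"site[{lev}]")
    if extra:
        for name, v in extra.items():
            cols.append(np.asarray(v, dtype=float))
            names.append(name)
    return np.column_stack(cols), names


def ols(y: np.ndarray, X: np.ndarray, names: list[str] | None = None) -> OLSFit:
    """OLS with pivoted-QR rank handling.

    Collinear columns are dropped (with a warning naming them) before
    the fit, so estimates for the remaining regressors are unchanged.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    names = names or [f"x{i}" for i in range(p)]

    Q, R, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = max(n, p) * np.finfo(float).eps * (diag[0] if len(diag) else 1.0)
    rank = int((diag > tol).sum())
    keep = sorted(piv[:rank])
    dropped = [names[i] for i in range(p) if i not in keep]
    if dropped:
        warnings.warn(f"dropping collinear columns: {dropped}", stacklevel=2)
    Xk = X[:, keep]
    kept_names = [names[i] for i in keep]

    beta, *_ = np.linalg.lstsq(Xk, y, rcond=None)
    resid = y - Xk @ beta
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    df_resid = n - len(keep)
    sigma2 = rss / df_resid if df_resid > 0 else np.nan
    XtX_inv = np.linalg.pinv(Xk.T @ Xk)
    se = np.sqrt(np.clip(np.diag(XtX_inv), 0, None) * sigma2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(t), df_resid) if df_resid > 0 else np.full_like(t, np.nan)
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    return OLSFit(
        names=kept_names,
        beta=beta,
        se=se,
        t=t,
        p=pvals,
        rss=rss,
        tss=tss,
        r2=r2,
        df_resid=df_resid,
        dropped=dropped,
    )
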