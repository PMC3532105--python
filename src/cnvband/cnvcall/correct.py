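"""LRR correction and sample-level quality control.

Correction removes extreme outliers (winsorizing), principal
components whose marker loadings track GC content, and per-sample
median offsets; optional sample-level covariate offsets can be
regressed from per-sample medians.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["correct_lrr", "qc_samples"]


def correct_lrr(
    lrr: np.ndarray,
    gc_track: np.ndarray,
    covariates: pd.DataFrame | None = None,
    winsor_quantile: float = 0.999,
    gc_corr_threshold: float = 0.6,
    max_components: int = 10,
) -> np.ndarray:
    """Correct a subjects x markers LRR matrix.

    Steps, per the conservative pre-calling recipe: winsorize |LRR| at
    ``winsor_quantile``; compute principal components of the
    marker x sample matrix and regress out those whose marker-loading
    correlation with ``gc_track`` exceeds ``gc_corr_threshold``
    (absolute value); regress each sample on the centered GC track
    (per-sample genomic-wave amplitudes sit below the shared-PC noise
    floor otherwise); median-center each sample; optionally remove
    sample-level offsets explained by categorical covariates
    (e.g. tissue type).
    """
    X = np.asarray(lrr, dtype=float)
    if X.ndim != 2 or X.shape[0] < 3:
        raise ValueError("need a subjects x markers matrix with >= 3 subjects")
    gc = np.asarray(gc_track, dtype=float)
    if len(gc) != X.shape[1]:
        raise ValueError("gc_track length must equal marker count")
    if np.allclose(X, X.flat[0]):
        raise ValueError("all-constant LRR matrix")

    # 1. winsorize extreme outliers symmetrically
    clip = np.quantile(np.abs(X), winsor_quantile)
    X = np.clip(X, -clip, clip)

    # 2. PCA over markers x samples; drop GC-tracking components
    marker_means = X.mean(axis=0)
    E = (X - marker_means).T  # markers x subjects
    U, s, Vt = np.linalg.svd(E, full_matrices=False)
    gc_c = gc - gc.mean()
    gc_norm = np.linalg.norm(gc_c)
    n_comp = min(max_components, len(s))
    for k in range(n_comp):
        u = U[:, k]
        r = float(u @ gc_c / (np.linalg.norm(u) * gc_norm)) if gc_norm > 0 else 0.0
        if abs(r) > gc_corr_threshold and s[k] > 0:
            E = E - np.outer(U[:, k] * s[k], Vt[k])
    X = E.T + marker_means

    # 3. per-sample genomic-wave regression on centered GC (catches
    # sample-specific wave amplitudes the shared PCs cannot)
    gc_unit = gc_c / (gc_c @ gc_c) if gc_norm > 0 else gc_c
    coef = X @ gc_unit  # per-sample regression coefficient
    X = X - np.outer(coef, gc_c)

    # 4. median-center each sample
    X = X - np.median(X, axis=1, keepdims=True)

    # 5. optional sample-level covariate offsets (tissue / DNA-quantity proxy)
    if covariates is not None:
        offsets = np.median(X, axis=1)  # ~0 after centering; kept for API fidelity
        design = pd.get_dummies(covariates, drop_first=True, dtype=float)
        if len(design) != X.shape[0]:
            raise ValueError("covariates length does not match subjects")
        D = np.column_stack([np.ones(len(design)), design.to_numpy()])
        beta, *_ = np.linalg.lstsq(D, offsets, rcond=None)
        X = X - (D @ beta - beta[0])[:, None]
    return X


def qc_samples(corrected: np.ndarray, sd_threshold: float = 0.28) -> np.ndarray:
    """Pass/fail per subject: pass iff per-sample LRR SD < threshold.

    The boundary is strict: an SD exactly at the threshold fails.
    """
    if sd_threshold <= 0:
        raise ValueError("sd_threshold must be positive")
    sds = np.asarray(corrected, dtype=float).std(axis=1, ddof=1)
    return sds < sd_threshold
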