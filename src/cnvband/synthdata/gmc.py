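"""Synthetic gray-matter-concentration matrices from a linear mixing
model ``X = A S`` with planted diagnosis and deletion-load effects."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GMCTruth", "GMCTruthConfig", "simulate_gmc"]


@dataclass
class GMCTruthConfig:
    """Shape of the planted mixing model.

    The deletion effect is multiplicative per copy: carriers of ``c``
    deletions have their loading on ``deletion_component`` scaled by
    ``(1 - deletion_reduction) ** c``.
    """

    loading_mean: float = 4.0
    loading_sd: float = 0.5
    diag_component: int | None = 0
    diag_effect: float = 0.6
    deletion_component: int | None = 1
    deletion_reduction: float = 0.10
    noise_sd: float = 0.3
    age_slope: float = 0.0
    gender_effect: float = 0.0
    site_sd: float = 0.0
    blob_width_frac: float = 0.12  # bump SD as a fraction of per-component spacing
    max_pairwise_r: float = 0.1


@dataclass
class GMCTruth:
    """Planted sources, loadings and the effect registry."""

    S_true: np.ndarray  # components x voxels
    A_true: np.ndarray  # subjects x components
    effects: dict = field(default_factory=dict)
    noise_sd: float = 0.0


def _blob_sources(k: int, n_voxels: int, width_frac: float, rng: np.random.Generator) -> np.ndarray:
    """k smooth localized bumps on a 1-D voxel lattice, pairwise near-uncorrelated.

    Mean-centering makes disjoint positive bumps correlate at about
    -f/(1-f) where f is the bump mass fraction, so the width is capped
    as a function of k to keep pairwise |r| < 0.1.
    """
    x = np.arange(n_voxels, dtype=float)
    spacing = n_voxels / k
    centers = (np.arange(k) + 0.5) * spacing + rng.uniform(-0.03, 0.03, size=k) * spacing
    width = min(width_frac, 0.022 * k) * spacing
    S = np.exp(-0.5 * ((x[None, :] - centers[:, None]) / width) ** 2)
    return S


def simulate_gmc(
    subjects: pd.DataFrame,
    n_components: int,
    n_voxels: int,
    config: GMCTruthConfig,
    deletion_load: pd.Series | np.ndarray | None,
    seed: int,
) -> tuple[np.ndarray, GMCTruth]:
    """Simulate a subjects x voxels GMC matrix with planted structure.

    Sources are localized positive bumps on a 1-D lattice (statistics
    downstream are voxel-order-agnostic); loadings carry a diagnosis
    shift on ``diag_component``, a per-copy multiplicative reduction on
    ``deletion_component`` and optional age/gender/site nuisance terms.
    """
    n = len(subjects)
    if not (0 < n_components < min(n, n_voxels)):
        raise ValueError("need 0 < n_components < min(n_subjects, n_voxels)")
    if not (0.0 <= config.deletion_reduction < 1.0):
        raise ValueError("deletion_reduction must be in [0, 1)")
    if config.loading_sd <= 0:
        raise ValueError("degenerate config: zero-variance loadings")
    rng = np.random.default_rng(seed)

    S = _blob_sources(n_components, n_voxels, config.blob_width_frac, rng)
    Sc = S - S.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Sc, axis=1)
    if (norms == 0).any():
        raise ValueError("degenerate config: zero-variance source")
    corr = (Sc / norms[:, None]) @ (Sc / norms[:, None]).T
    off = corr[~np.eye(n_components, dtype=bool)]
    if np.abs(off).max() >= config.max_pairwise_r:
        raise ValueError("source bumps overlap too much; reduce blob_width_frac or k")

    A = rng.normal(config.loading_mean, config.loading_sd, size=(n, n_components))

    is_case = (subjects["diagnosis"].to_numpy() == "case").astype(float)
    if config.diag_component is not None and config.diag_effect != 0.0:
        A[:, config.diag_component] -= config.diag_effect * is_case

    load = None
    if deletion_load is not None and config.deletion_component is not None:
        load = np.asarray(
            deletion_load.reindex(subjects["subject_id"]).to_numpy()
            if isinstance(deletion_load, pd.Series)
            else deletion_load,
            dtype=float,
        )
        if len(load) != n:
            raise ValueError("deletion_load length does not match subjects")
        A[:, config.deletion_component] *= (1.0 - config.deletion_reduction) ** load

    if config.age_slope:
        age = subjects["age"].to_numpy(dtype=float)
        A += config.age_slope * (age - age.mean())[:, None]
    if config.gender_effect:
        male = (subjects["gender"].to_numpy() == "M").astype(float)
        A[:, -1] += config.gender_effect * (male - male.mean())
    if config.site_sd:
        sites = subjects["site"].to_numpy()
        for s in np.unique(sites):
            A[sites == s] += rng.normal(0.0, config.site_sd, size=n_components)[None, :]

    X = A @ S
    if config.noise_sd > 0:
        X = X + rng.normal(0.0, config.noise_sd, size=X.shape)

    effects = {
        "diag_component": config.diag_component,
        "diag_effect": config.diag_effect,
        "deletion_component": config.deletion_component,
        "deletion_reduction": config.deletion_reduction,
        "deletion_load": None if load is None else load.copy(),
    }
    return X, GMCTruth(S_true=S, A_true=A, effects=effects, noise_sd=config.noise_sd)
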