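"""Synthetic subject tables (diagnosis, demographics, site, tissue)."""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["generate_cohort"]

ETHNICITIES = ("White", "AA", "Other")


def _check_mix(mix: dict[str, float] | list[float], labels: tuple[str, ...] | None, what: str) -> tuple[list[str], np.ndarray]:
    if isinstance(mix, dict):
        keys = list(mix.keys())
        probs = np.asarray([mix[k] for k in keys], dtype=float)
    else:
        probs = np.asarray(mix, dtype=float)
        keys = list(labels[: len(probs)]) if labels else [f"{what}{i+1}" for i in range(len(probs))]
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError(f"{what} mix must sum to 1 (got {probs.sum()!r})")
    if (probs < 0).any():
        raise ValueError(f"{what} mix has negative entries")
    return keys, probs


def generate_cohort(
    n_case: int,
    n_control: int,
    ethnicity_mix: dict[str, float] | tuple[dict[str, float], dict[str, float]],
    site_mix: dict[str, float],
    seed: int,
    age_mean: tuple[float, float] = (36.0, 33.0),
    age_sd: tuple[float, float] = (12.0, 11.0),
    male_fraction: tuple[float, float] = (0.76, 0.65),
    saliva_fraction: float = 0.25,
) -> pd.DataFrame:
    """Sample a case/control subject table.

    ``ethnicity_mix`` may be a single mix applied to both groups or a
    ``(case_mix, control_mix)`` pair (the latter creates the ethnicity
    confound used in the burden analyses). Ages are normal per group;
    gender, site and tissue are categorical draws. Deterministic under
    ``seed``.
    """
    if n_case < 0 or n_control < 0:
        raise ValueError("group sizes must be non-negative")
    rng = np.random.default_rng(seed)

    if isinstance(ethnicity_mix, tuple):
        case_mix, control_mix = ethnicity_mix
    else:
        case_mix = control_mix = ethnicity_mix
    eth_case_labels, eth_case_p = _check_mix(case_mix, ETHNICITIES, "ethnicity")
    eth_ctrl_labels, eth_ctrl_p = _check_mix(control_mix, ETHNICITIES, "ethnicity")
    site_labels, site_p = _check_mix(site_mix, None, "site")

    rows = []
    counter = 0
    for group, n, eth_labels, eth_p, mu, sd, male_p in (
        ("case", n_case, eth_case_labels, eth_case_p, age_mean[0], age_sd[0], male_fraction[0]),
        ("control", n_control, eth_ctrl_labels, eth_ctrl_p, age_mean[1], age_sd[1], male_fraction[1]),
    ):
        for _ in range(n):
            counter += 1
            rows.append(
                {
                    "subject_id": f"S{counter:04d}",
                    "diagnosis": group,
                    "age": float(np.clip(rng.normal(mu, sd), 18.0, 90.0)),
                    "gender": "M" if rng.random() < male_p else "F",
                    "site": site_labels[rng.choice(len(site_p), p=site_p)],
                    "ethnicity": eth_labels[rng.choice(len(eth_p), p=eth_p)],
                    "tissue": "saliva" if rng.random() < saliva_fraction else "blood",
                }
            )
    return pd.DataFrame(
        rows,
        columns=["subject_id", "diagnosis", "age", "gender", "site", "ethnicity", "tissue"],
    )
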