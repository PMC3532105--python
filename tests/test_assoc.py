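import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cnvband.assoc import (
    bonferroni_threshold,
    deletion_group_anova,
    region_span,
    regress_loading_on_feature,
    voxelwise_regression,
)
from cnvband.cnvcall.types import CNVCall


def _covariates(rng, n):
    return (
        rng.uniform(20, 60, n),
        rng.choice(["M", "F"], n),
        rng.choice(["A", "B", "C", "D"], n),
    )


def test_bonferroni_641_matches_printed_value():
    thr = bonferroni_threshold(641, 1, 0.05)
    # 7.8e-5 at two significant digits
    assert float(f"{thr:.1e}") == pytest.approx(7.8e-5)


def test_bonferroni_networks_by_features():
    assert bonferroni_threshold(18, 14, 0.05) == pytest.approx(0.05 / 252)
    assert bonferroni_threshold(1, 1, 0.05) == pytest.approx(0.05)
    with pytest.raises(ValueError):
        bonferroni_threshold(0, 5)


def test_region_span_printed_coordinates():
    calls = [
        CNVCall("a", "22", 42_712_496, 42_717_495, 0, 5, copy_number=1),
        CNVCall("b", "22", 44_030_020, 44_035_019, 0, 5, copy_number=1),
    ]
    start, end, span = region_span(calls)
    assert (start, end) == (42_712_496, 44_035_019)
    assert span == 1_322_523
    assert round(span / 1e6, 2) == 1.32


def test_region_span_single_and_empty():
    one = CNVCall("a", "1", 100, 599, 0, 3, copy_number=1)
    start, end, span = region_span([one])
    assert (start, end, span) == (100, 599, 499)
    assert region_span([]) is None
    df = pd.DataFrame({"start": [100, 300], "end": [200, 450]})
    assert region_span(df) == (100, 450, 350)


def test_regression_null_behavior():
    rng = np.random.default_rng(0)
    n = 200
    age, gender, site = _covariates(rng, n)
    d_r2s, ps = [], []
    for _ in range(100):
        y = rng.normal(0, 1, n)
        f = rng.poisson(0.3, n).astype(float)
        if np.allclose(f, f[0]):
            continue
        res = regress_loading_on_feature(y, f, age, gender, site)
        d_r2s.append(res.delta_r2)
        ps.append(res.p)
    assert np.mean(d_r2s) < 0.02
    assert stats.kstest(ps, "uniform").pvalue > 0.01


def test_regression_constant_feature_skipped():
    rng = np.random.default_rng(1)
    age, gender, site = _covariates(rng, 50)
    assert regress_loading_on_feature(rng.normal(size=50), np.zeros(50), age, gender, site) is None


def test_delta_r2_equals_squared_partial_on_orthogonal_design():
    """With the feature orthogonalized against the covariates, delta R2
    equals the squared semi-partial correlation (closed form)."""
    rng = np.random.default_rng(2)
    n = 300
    age, gender, site = _covariates(rng, n)
    from cnvband.linmod import build_design

    D, _ = build_design(age=age, gender=gender, site=site)
    f_raw = rng.normal(0, 1, n)
    f = f_raw - D @ np.linalg.lstsq(D, f_raw, rcond=None)[0]  # orthogonalized
    y = 0.3 * f + D @ rng.normal(0, 0.5, D.shape[1]) + rng.normal(0, 1, n)
    res = regress_loading_on_feature(y, f, age, gender, site)
    r_semipartial = float(f @ (y - y.mean()) / (np.linalg.norm(f) * np.linalg.norm(y - y.mean())))
    assert res.delta_r2 == pytest.approx(r_semipartial**2, abs=1e-10)
    assert res.semipartial_r2 == pytest.approx(res.delta_r2, abs=1e-10)


def test_planted_delta_r2_recovery():
    """True CNV-term delta R2 of 0.05 at n=300: recovered within +-0.03
    and detected at 0.05/18/14 in most seeds (scaled-down version; the
    full 50-seed run lives in the acceptance suite)."""
    thr = bonferroni_threshold(18, 14)
    recovered, detected = [], 0
    n_seeds = 15
    for seed in range(n_seeds):
        res = _simulate_delta_r2_run(seed, n=300, target=0.05)
        recovered.append(res.delta_r2)
        detected += res.p < thr
    assert abs(np.mean(recovered) - 0.05) < 0.03
    assert detected / n_seeds >= 0.7


def _simulate_delta_r2_run(seed, n, target):
    """Plant a CNV effect whose realized (in-sample) delta R2 is exact:
    add a multiple of the covariate-orthogonalized dose to y."""
    rng = np.random.default_rng(10_000 + seed)
    age, gender, site = _covariates(rng, n)
    from cnvband.linmod import build_design

    D, _ = build_design(age=age, gender=gender, site=site)
    dose = rng.choice([0.0, 1.0, 2.0], n, p=[0.85, 0.12, 0.03])
    d_perp = dose - D @ np.linalg.lstsq(D, dose, rcond=None)[0]
    u = d_perp / np.linalg.norm(d_perp)
    y0 = 5.0 + D[:, 1:] @ rng.normal(0, 0.02, D.shape[1] - 1) + rng.normal(0, 1.0, n)
    y_perp = y0 - u * (u @ y0)
    tss_perp = float(((y_perp - y_perp.mean()) ** 2).sum())
    c = np.sqrt(target * tss_perp / (1 - target))
    y = y_perp - c * u  # deletions lower the loading
    return regress_loading_on_feature(y, dose, age, gender, site)


def test_collinear_column_dropped_estimates_unchanged():
    rng = np.random.default_rng(3)
    n = 100
    age, gender, site = _covariates(rng, n)
    y = rng.normal(0, 1, n)
    f = rng.poisson(0.5, n).astype(float)
    from cnvband.linmod import build_design, ols

    D, names = build_design(age=age, gender=gender, site=site, extra={"cnv": f})
    # duplicate an existing site dummy
    j = names.index("site[B]")
    D2 = np.column_stack([D, D[:, j]])
    names2 = names + ["site[B]_dup"]
    with pytest.warns(UserWarning, match="collinear"):
        fit2 = ols(y, D2, names2)
    fit1 = ols(y, D, names)
    assert fit2.dropped == ["site[B]_dup"]
    np.testing.assert_allclose(fit1.beta, fit2.beta, atol=1e-10)


def test_deletion_group_anova_equal_means():
    rng = np.random.default_rng(4)
    y = rng.normal(5, 0.0001, 90)
    load = np.r_[np.zeros(60), np.ones(20), np.full(10, 2)]
    out = deletion_group_anova(y, load)
    assert out.p > 0.5
    assert abs(out.percent_reduction[1]) < 0.01
    assert out.percent_reduction[0] == 0.0


def test_deletion_group_anova_planted_reductions():
    """Planted 10%/19% multiplicative reductions recovered within 3 points."""
    rng = np.random.default_rng(5)
    n0, n1, n2 = 260, 30, 10
    base = 4.0
    y = np.r_[
        rng.normal(base, 0.1, n0),
        rng.normal(base * 0.90, 0.1, n1),
        rng.normal(base * 0.81, 0.1, n2),
    ]
    load = np.r_[np.zeros(n0), np.ones(n1), np.full(n2, 2)]
    out = deletion_group_anova(y, load)
    assert out.p < 1e-4
    assert out.percent_reduction[1] == pytest.approx(10.0, abs=3.0)
    assert out.percent_reduction[2] == pytest.approx(19.0, abs=3.0)
    assert out.n_per_level == {0: n0, 1: n1, 2: n2}


def test_deletion_group_anova_absent_level():
    rng = np.random.default_rng(6)
    y = rng.normal(4, 0.5, 50)
    load = np.r_[np.zeros(40), np.ones(10)]  # no 2-copy carriers
    out = deletion_group_anova(y, load)
    assert out.absent_levels == [2]
    assert set(out.levels) == {0, 1}


def test_deletion_group_anova_sign_convention():
    rng = np.random.default_rng(7)
    y = np.r_[rng.normal(-4, 0.1, 50), rng.normal(-3.6, 0.1, 20)]  # negative means
    load = np.r_[np.zeros(50), np.ones(20)]
    out = deletion_group_anova(y, load)
    assert out.sign_flipped
    assert out.percent_reduction[1] == pytest.approx(10.0, abs=3.0)


def test_deletion_group_anova_cases_only():
    rng = np.random.default_rng(8)
    y = np.r_[rng.normal(4, 0.1, 60), rng.normal(3.5, 0.1, 20)]
    load = np.r_[np.zeros(60), np.ones(20)]
    is_case = np.r_[np.ones(30, bool), np.zeros(30, bool), np.ones(20, bool)]
    out = deletion_group_anova(y, load, restrict_to=is_case)
    assert out.n_per_level == {0: 30, 1: 20}


def test_voxelwise_localization_and_consistency():
    rng = np.random.default_rng(9)
    n, V = 200, 800
    age, gender, site = _covariates(rng, n)
    support = np.zeros(V, dtype=bool)
    support[300:380] = True
    f = rng.choice([0.0, 1.0], n, p=[0.8, 0.2])
    X = rng.normal(0, 0.5, (n, V))
    X[:, support] -= 1.5 * f[:, None]  # strong localized effect
    res = voxelwise_regression(X, f, age, gender, site)
    top100 = np.argsort(res["p"].to_numpy())[:100]
    assert support[top100].mean() >= 0.7
    # spot-check 5 voxels against independent single-voxel regressions
    from cnvband.linmod import build_design, ols

    D, names = build_design(age=age, gender=gender, site=site, extra={"cnv": f})
    for v in (0, 150, 350, 500, 799):
        fit = ols(X[:, v], D, names)
        beta, t, p = fit.coef("cnv")
        assert res["beta"].iloc[v] == pytest.approx(beta, abs=1e-10)
        assert res["p"].iloc[v] == pytest.approx(p, abs=1e-12)


def test_voxelwise_null_bh_near_zero():
    rng = np.random.default_rng(10)
    n, V = 150, 600
    age, gender, site = _covariates(rng, n)
    X = rng.normal(0, 1, (n, V))
    f = rng.poisson(0.3, n).astype(float)
    res = voxelwise_regression(X, f, age, gender, site)
    assert res["bh_significant"].sum() <= 1
    assert res["bonferroni_significant"].sum() == 0
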