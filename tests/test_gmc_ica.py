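import numpy as np
import pytest
from scipy import stats

from cnvband.gmc_ica import (
    estimate_order_mdl,
    fix_signs,
    infomax_ica,
    loading_covariate_regression,
    network_group_test,
)
from cnvband.gmc_ica import _whiten


def planted_data(rng, n=200, V=3000, k=5, strength=3.0, noise=0.2):
    A = rng.normal(0, 1, (n, k))
    S = rng.laplace(0, 1, (k, V)) * strength
    return A @ S + rng.normal(0, noise, (n, V)), A, S


def test_mdl_recovers_planted_rank():
    hits = 0
    n_seeds = 20
    for seed in range(n_seeds):
        rng = np.random.default_rng(seed)
        X, _, _ = planted_data(rng)
        hits += estimate_order_mdl(X, voxel_stride=5, seed=seed) == 5
    assert hits / n_seeds >= 0.9


def test_mdl_pure_noise_small_k():
    for seed in range(5):
        rng = np.random.default_rng(100 + seed)
        X = rng.normal(0, 1, (50, 2000))
        assert estimate_order_mdl(X, voxel_stride=5, seed=seed) <= 2


def test_mdl_voxel_permutation_invariant():
    rng = np.random.default_rng(7)
    X, _, _ = planted_data(rng, n=60, V=1200, k=3)
    k1 = estimate_order_mdl(X, voxel_stride=1)
    perm = rng.permutation(X.shape[1])
    k2 = estimate_order_mdl(X[:, perm], voxel_stride=1)
    assert k1 == k2


def test_mdl_errors():
    rng = np.random.default_rng(0)
    with pytest.raises(ValueError):
        estimate_order_mdl(rng.normal(size=(5, 100)))  # too few subjects
    with pytest.raises(ValueError):
        estimate_order_mdl(rng.normal(size=(50, 100)), voxel_stride=10)  # N <= n


def _match_sources(S_est, S_true):
    """|corr| of each true source with its best-matching estimate."""
    C = np.corrcoef(np.vstack([S_true, S_est]))
    k = len(S_true)
    cross = np.abs(C[:k, k:])
    return cross.max(axis=1)


def test_infomax_recovers_supergaussian_sources():
    rng = np.random.default_rng(1)
    k, V, n = 3, 4000, 40
    S = rng.laplace(0, 1, (k, V))
    A = rng.normal(0, 1, (n, k))
    X = A @ S
    dec = infomax_ica(X, k, seed=0)
    assert dec.converged
    rs = _match_sources(dec.S, S)
    assert (rs > 0.95).all()


def test_full_rank_reconstruction():
    rng = np.random.default_rng(2)
    n, V = 25, 500
    X = rng.normal(0, 1, (n, V))
    dec = infomax_ica(X, n, seed=0, max_iter=64)
    assert dec.variance_explained > 0.999


def test_seed_determinism_and_stability():
    rng = np.random.default_rng(3)
    X, _, S = planted_data(rng, n=40, V=2000, k=3, noise=0.05)
    a = infomax_ica(X, 3, seed=5)
    b = infomax_ica(X, 3, seed=5)
    np.testing.assert_array_equal(a.S, b.S)
    np.testing.assert_array_equal(a.A, b.A)
    c = infomax_ica(X, 3, seed=9)
    # different seeds agree up to permutation/sign
    C = np.abs(np.corrcoef(np.vstack([a.S, c.S]))[:3, 3:])
    assert (C.max(axis=1) > 0.9).all()


def test_whitening_covariance_identity():
    rng = np.random.default_rng(4)
    X = rng.normal(0, 1, (30, 5000)) @ np.diag(np.r_[np.ones(2500) * 3, np.ones(2500)])
    Xc = X - X.mean(axis=1, keepdims=True)
    Z, _, _ = _whiten(Xc, 10)
    C = (Z @ Z.T) / Z.shape[1]
    np.testing.assert_allclose(C, np.eye(10), atol=1e-8)


def test_variance_explained_monotone_in_k():
    rng = np.random.default_rng(5)
    X, _, _ = planted_data(rng, n=50, V=1500, k=6, noise=1.0)
    ves = [infomax_ica(X, k, seed=0, max_iter=128).variance_explained for k in (2, 4, 6, 8)]
    assert all(b >= a - 1e-9 for a, b in zip(ves, ves[1:]))


def test_recovery_degrades_with_noise():
    rs = []
    for noise in (0.2, 2.0, 8.0):
        vals = []
        for seed in range(3):
            rng = np.random.default_rng(10 * seed + 1)
            S = rng.laplace(0, 1, (3, 2500))
            A = rng.normal(0, 1, (40, 3))
            X = A @ S + rng.normal(0, noise, (40, 2500))
            dec = infomax_ica(X, 3, seed=seed)
            vals.append(_match_sources(dec.S, S).mean())
        rs.append(np.mean(vals))
    assert rs[0] > rs[1] > rs[2]


def test_fix_signs_idempotent_and_invariant():
    rng = np.random.default_rng(6)
    X, _, _ = planted_data(rng, n=30, V=1000, k=3)
    dec = infomax_ica(X, 3, seed=0)
    recon_before = dec.A @ dec.S
    once = fix_signs(dec)
    np.testing.assert_allclose(once.A @ once.S, recon_before, atol=1e-10)
    S_once, A_once = once.S.copy(), once.A.copy()
    twice = fix_signs(once)
    np.testing.assert_array_equal(twice.S, S_once)
    np.testing.assert_array_equal(twice.A, A_once)
    assert (stats.skew(twice.S, axis=1) >= 0).all()


def test_fix_signs_positive_blob_keeps_peak():
    from cnvband.synthdata.cohort import generate_cohort
    from cnvband.synthdata.gmc import GMCTruthConfig, simulate_gmc

    subjects = generate_cohort(20, 20, {"White": 1.0}, {"NM": 1.0}, seed=0)
    X, truth = simulate_gmc(subjects, 4, 1200, GMCTruthConfig(noise_sd=0.1), None, seed=1)
    dec = fix_signs(infomax_ica(X, 4, seed=0))
    # each planted positive bump should match a fixed component positively
    C = np.corrcoef(np.vstack([truth.S_true, dec.S]))[:4, 4:]
    assert (C.max(axis=1) > 0.9).all()  # positive correlation after sign fixing


def _covariates(rng, n):
    age = rng.uniform(20, 60, n)
    gender = rng.choice(["M", "F"], n)
    site = rng.choice(["A", "B", "C", "D"], n)
    return age, gender, site


def test_network_group_test_power_and_type1():
    k = 5
    flagged_effect = 0
    false_flags = 0
    n_seeds = 20
    for seed in range(n_seeds):
        rng = np.random.default_rng(200 + seed)
        n = 150
        diag = rng.permutation(np.r_[np.ones(75), np.zeros(75)])
        A = rng.normal(0, 1, (n, k))
        A[:, 2] += 0.8 * diag  # planted effect on component 2 only
        age, gender, site = _covariates(rng, n)
        res = network_group_test(A, diag, age, gender, site)
        flagged_effect += bool(res.loc[2, "significant"])
        false_flags += int(res.drop(index=2)["significant"].sum())
    assert flagged_effect / n_seeds >= 0.9
    # 20 seeds x 4 null components at alpha/k = 0.01 -> ~0.8 expected
    assert false_flags <= 4


def test_network_group_test_null_fwe():
    k = 8
    any_flag = 0
    n_cohorts = 20
    for seed in range(n_cohorts):
        rng = np.random.default_rng(300 + seed)
        n = 120
        diag = rng.permutation(np.r_[np.ones(60), np.zeros(60)])
        A = rng.normal(0, 1, (n, k))
        age, gender, site = _covariates(rng, n)
        res = network_group_test(A, diag, age, gender, site)
        any_flag += bool(res["significant"].any())
    # family-wise 0.05: P(>=4 of 20) < 0.002 under the null
    assert any_flag <= 3


def test_permuting_labels_destroys_flag():
    rng = np.random.default_rng(9)
    n, k = 150, 4
    diag = np.r_[np.ones(75), np.zeros(75)]
    A = rng.normal(0, 1, (n, k))
    A[:, 1] += 1.0 * diag
    age, gender, site = _covariates(rng, n)
    res = network_group_test(A, diag, age, gender, site)
    assert res.loc[1, "significant"]
    perm = rng.permutation(diag)
    res_p = network_group_test(A, perm, age, gender, site)
    assert not res_p.loc[1, "significant"]


def test_loading_covariate_regression():
    rng = np.random.default_rng(10)
    n, k = 120, 3
    A = rng.normal(0, 1, (n, k))
    dose = A[:, 1] + rng.normal(0, 0.3, n)
    age, gender, site = _covariates(rng, n)
    res = loading_covariate_regression(A, dose, age, gender, site)
    assert res.loc[1, "p"] < 0.05 / k
    with pytest.raises(ValueError):
        loading_covariate_regression(A, np.ones(n), age, gender, site)


def test_loading_regression_null_p_uniform():
    """Dose orthogonal to loadings: p-values uniform under the null (KS)."""
    rng = np.random.default_rng(11)
    ps = []
    age, gender, site = _covariates(rng, 80)
    for _ in range(200):
        A = rng.normal(0, 1, (80, 1))
        dose = rng.normal(0, 1, 80)
        res = loading_covariate_regression(A, dose, age, gender, site)
        ps.append(float(res.loc[0, "p"]))
    assert stats.kstest(ps, "uniform").pvalue > 0.01


def test_single_level_diagnosis_rejected():
    rng = np.random.default_rng(12)
    A = rng.normal(0, 1, (30, 2))
    age, gender, site = _covariates(rng, 30)
    with pytest.raises(ValueError):
        network_group_test(A, np.ones(30), age, gender, site)
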