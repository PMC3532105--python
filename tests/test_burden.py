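import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cnvband.burden import (
    ancova_f,
    compute_burden,
    cytoband_features,
    screen_cytobands,
    two_sample_t,
)
from cnvband.burden import testable_features as nonzero_features  # avoid test-name collection
from cnvband.cnvcall.regions import define_regions
from cnvband.cnvcall.types import CNVCall
from cnvband.synthdata.cohort import generate_cohort
from cnvband.synthdata.maps import generate_marker_map


def make_call(subject, first, last, cn=1, chrom="1"):
    return CNVCall(
        subject_id=subject,
        chromosome=chrom,
        start=first * 1000 + 1,
        end=last * 1000 + 1,
        first=first,
        last=last,
        copy_number=cn,
    )


def subjects_frame(ids):
    return pd.DataFrame({"subject_id": ids})


def test_no_calls_all_zero():
    subs = subjects_frame(["A", "B"])
    out = compute_burden([], [], subs)
    assert (out.to_numpy() == 0).all()


def test_hand_tally():
    """2 deletions (1 rare) + 1 common insertion -> (3, 2, 1, 1)."""
    # 150 subjects; deletion region 2 carried only by A (rare at 1/150),
    # deletion region 1 and insertion region carried by many (common)
    calls = [make_call("A", 10, 15, cn=1), make_call("A", 400, 405, cn=1), make_call("A", 200, 210, cn=3)]
    for i in range(20):
        calls.append(make_call(f"F{i}", 10, 15, cn=1))
        calls.append(make_call(f"F{i}", 200, 210, cn=3))
    subs = subjects_frame(["A"] + [f"F{i}" for i in range(20)])
    regions = define_regions(calls, n_subjects=150)
    out = compute_burden(calls, regions, subs)
    row = out.loc["A"]
    assert tuple(row) == (3, 2, 1, 1)


def test_conservation():
    rng = np.random.default_rng(0)
    ids = [f"S{i}" for i in range(12)]
    calls = []
    for i, s in enumerate(ids):
        for j in range(rng.integers(0, 4)):
            first = 30 * j + 7 * i
            calls.append(make_call(s, first, first + 3, cn=rng.choice([0, 1, 3])))
    subs = subjects_frame(ids)
    regions = define_regions(calls, n_subjects=len(ids))
    out = compute_burden(calls, regions, subs)
    assert out["total_cnvs"].sum() == len(calls)
    assert out["total_deletions"].sum() == sum(c.cnv_class == "deletion" for c in calls)
    assert (out["total_rare_cnvs"] <= out["total_cnvs"]).all()
    assert (out["total_rare_deletions"] <= out["total_deletions"]).all()
    assert (out["total_rare_deletions"] <= out["total_rare_cnvs"]).all()


@pytest.fixture(scope="module")
def cyto():
    return generate_marker_map(1, 10, 6, seed=0)[1]


def test_feature_counting_inside_band(cyto):
    b = cyto.bands.iloc[0]
    call = CNVCall("A", "1", int(b["start"]) + 10, int(b["start"]) + 500, 0, 2, copy_number=1)
    subs = subjects_frame(["A"])
    feats = cytoband_features([call], cyto, subs)
    assert feats.loc["A", (b["name"], "cnv")] == 1
    assert feats.loc["A", (b["name"], "del")] == 1
    assert feats.loc["A", (b["name"], "ins")] == 0
    other = feats.drop(columns=[(b["name"], k) for k in ("cnv", "del", "ins")])
    assert (other.to_numpy() == 0).all()


def test_straddling_call_counts_in_both_bands(cyto):
    b1, b2 = cyto.bands.iloc[0], cyto.bands.iloc[1]
    call = CNVCall("A", "1", int(b1["end"]) - 500, int(b2["start"]) + 500, 0, 2, copy_number=3)
    subs = subjects_frame(["A"])
    feats = cytoband_features([call], cyto, subs)
    assert feats.loc["A", (b1["name"], "ins")] == 1
    assert feats.loc["A", (b2["name"], "ins")] == 1
    # midpoint mode counts once
    feats_mid = cytoband_features([call], cyto, subs, straddle="midpoint")
    assert feats_mid.loc["A"].sum() == 2  # one band x (cnv + ins)


def test_deletion_count_conservation_inequality(cyto):
    rng = np.random.default_rng(1)
    ids = [f"S{i}" for i in range(8)]
    calls = []
    chrom_end = int(cyto.bands[cyto.bands["chrom"] == "1"]["end"].max())
    for s in ids:
        for _ in range(rng.integers(1, 4)):
            start = int(rng.integers(1, chrom_end - 2000))
            calls.append(CNVCall(s, "1", start, start + int(rng.integers(100, 1500)), 0, 2, copy_number=1))
    feats = cytoband_features(calls, cyto, subjects_frame(ids))
    n_del = sum(c.cnv_class == "deletion" for c in calls)
    del_cols = feats.loc[:, (slice(None), "del")]
    assert del_cols.to_numpy().sum() >= n_del
    # cnv = del + ins per band/subject
    for band in cyto.bands["name"]:
        assert (
            feats[(band, "cnv")] == feats[(band, "del")] + feats[(band, "ins")]
        ).all()


def test_two_sample_t_textbook():
    x = np.array([2.0, 3.0, 4.0, 0.0, 1.0, 2.0])
    is_case = np.array([True, True, True, False, False, False])
    t, p = two_sample_t(x, is_case)
    # pooled t by hand: means 3 and 1, sp^2 = (2+2)/4 = 1
    t_ref = (3 - 1) / np.sqrt(1 * (1 / 3 + 1 / 3))
    p_ref = 2 * stats.t.sf(abs(t_ref), 4)
    assert t == pytest.approx(t_ref, rel=1e-12)
    assert p == pytest.approx(p_ref, rel=1e-12)


def test_two_sample_t_null_and_symmetry():
    x = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
    is_case = np.array([True, True, True, False, False, False])
    t, p = two_sample_t(x, is_case)
    assert t == pytest.approx(0.0)
    assert p == pytest.approx(1.0)
    x2 = np.array([2.0, 3.0, 4.0, 0.0, 1.0, 2.0])
    t1, p1 = two_sample_t(x2, is_case)
    t2, p2 = two_sample_t(x2, ~is_case)
    assert t1 == pytest.approx(-t2)
    assert p1 == pytest.approx(p2)


def test_ancova_f_orthogonal_matches_oneway():
    """Balanced design, covariate orthogonal to diagnosis and inert:
    partial F equals the plain one-way ANOVA F."""
    rng = np.random.default_rng(2)
    n = 40
    diag = np.array(["case", "control"] * (n // 2))
    eth = np.array((["White"] * 2 + ["AA"] * 2) * (n // 4))
    y = rng.normal(0, 1, n) + 0.8 * (diag == "case")
    F, p = ancova_f(y, diag, pd.DataFrame({"ethnicity": eth}))
    g1, g2 = y[diag == "case"], y[diag == "control"]
    F_ref, p_ref = stats.f_oneway(g1, g2)
    # covariate uses a residual df, so match F loosely and sign of effect
    assert F == pytest.approx(F_ref, rel=0.1)
    assert p < 0.05 and p_ref < 0.05


def test_ancova_confounding_attenuates():
    """Feature driven purely by ethnicity, diagnosis confounded with
    ethnicity: adjusting for ethnicity attenuates the diagnosis F."""
    rng = np.random.default_rng(3)
    n = 200
    is_aa = rng.random(n) < 0.3
    diag = np.where((rng.random(n) < 0.75) & is_aa | (rng.random(n) < 0.35) & ~is_aa, "case", "control")
    y = 2.0 * is_aa + rng.normal(0, 1, n)
    eth = pd.DataFrame({"ethnicity": np.where(is_aa, "AA", "White")})
    t, p_unadj = two_sample_t(y, diag == "case")
    F_adj, p_adj = ancova_f(y, diag, eth)
    assert p_adj > p_unadj
    F_unadj, _ = ancova_f(y, diag, pd.DataFrame(index=range(n)))
    assert F_adj < F_unadj


def test_ancova_constant_feature():
    diag = np.array(["case", "control"] * 10)
    cov = pd.DataFrame({"ethnicity": ["White"] * 10 + ["AA"] * 10})
    F, p = ancova_f(np.ones(20), diag, cov)
    assert F == 0.0 and p == 1.0


def _feature_frame(X, bands):
    cols = pd.MultiIndex.from_product([bands, ["cnv"]], names=["band", "kind"])
    return pd.DataFrame(X, columns=cols)


def test_screen_stage_rules():
    rng = np.random.default_rng(4)
    n = 200
    is_case = np.r_[np.ones(100, bool), np.zeros(100, bool)]
    white = rng.random(n) < 0.8
    # feature 0: real effect everywhere; feature 1: effect only outside White
    x0 = rng.poisson(0.2, n) + is_case * rng.poisson(0.5, n)
    x1 = rng.poisson(0.2, n).astype(float)
    x1[~white & is_case] += 3.0
    X = np.c_[x0, x1]
    res = screen_cytobands(_feature_frame(X, ["b0", "b1"]), is_case, white, p1=0.01, p2=0.05)
    assert res.loc[("b0", "cnv"), "selected"]
    r1 = res.loc[("b1", "cnv")]
    if r1["p"] < 0.01:  # stage 1 may trigger, stage 2 must block
        assert not r1["selected"]


def test_screen_untestable_feature_reported():
    is_case = np.r_[np.ones(20, bool), np.zeros(20, bool)]
    white = np.ones(40, bool)
    X = np.zeros((40, 1))
    res = screen_cytobands(_feature_frame(X, ["b0"]), is_case, white)
    assert not res["testable"].iloc[0]
    assert not res["selected"].iloc[0]


def test_testable_features_helper():
    X = np.zeros((10, 2))
    X[0, 1] = 1
    f = _feature_frame(X, ["b0", "b1"])
    assert list(nonzero_features(f)) == [("b1", "cnv")]


def test_screen_monotone_in_effect_size():
    """Selection frequency never decreases along a 3-point effect grid."""
    rates = [0.05, 0.25, 0.5]
    freqs = []
    for rate in rates:
        hits = 0
        for seed in range(15):
            rng = np.random.default_rng(100 * seed + 17)
            n = 160
            is_case = np.r_[np.ones(80, bool), np.zeros(80, bool)]
            white = rng.random(n) < 0.85
            x = rng.poisson(0.05, n) + (rng.random(n) < rate * is_case)
            res = screen_cytobands(_feature_frame(x[:, None], ["b0"]), is_case, white)
            hits += bool(res["selected"].iloc[0])
        freqs.append(hits / 15)
    assert freqs[0] <= freqs[1] <= freqs[2]
    assert freqs[2] >= 0.8


def test_cohort_integration_counts():
    subs = generate_cohort(6, 6, {"White": 1.0}, {"NM": 1.0}, seed=0)
    _, cyto = generate_marker_map(1, 10, 6, seed=0)
    b = cyto.bands.iloc[0]
    calls = [
        CNVCall(sid, "1", int(b["start"]), int(b["start"]) + 900, 0, 3, copy_number=1)
        for sid in subs["subject_id"][:3]
    ]
    feats = cytoband_features(calls, cyto, subs)
    assert feats[(b["name"], "del")].sum() == 3
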