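import itertools

import numpy as np
import pandas as pd
import pytest

from homoeokit import cistrans as ct
from homoeokit import expression as ex
from homoeokit.config import AnalysisConfig
from homoeokit.simulate import SimulationParams, simulate_expression, simulate_genome


def oracle_classify7(sig_p, sig_h, sig_t, h, t):
    """Independent rule-table enumeration of the seven-category scheme."""
    table = {
        (False, False, False): "conserved",
        (True, True, False): "cis_only",
        (True, False, True): "trans_only",
        (False, True, True): "compensatory",
        (True, False, False): "ambiguous",
        (False, False, True): "ambiguous",
        (False, True, False): "ambiguous",
    }
    key = (sig_p, sig_h, sig_t)
    if key in table:
        return table[key]
    # (T, T, T): direction decides
    if abs(h) <= 1e-9 or abs(t) <= 1e-9:
        return "ambiguous"
    return "cis_plus_trans" if (h > 0) == (t > 0) else "cis_x_trans"


def test_classify7_matches_enumeration_oracle():
    signs = (-1.7, -1e-12, 0.0, 1e-12, 2.3)
    for sig in itertools.product([False, True], repeat=3):
        for h, t in itertools.product(signs, signs):
            assert ct.classify7(*sig, h, t) == oracle_classify7(*sig, h, t), (sig, h, t)


@pytest.mark.parametrize(
    "sig,h,t,expected",
    [
        ((True, True, False), 1.8, 0.0, "cis_only"),
        ((True, True, True), 1.0, -0.5, "cis_x_trans"),
        ((True, True, True), 1.0, 0.5, "cis_plus_trans"),
        ((False, True, True), -2.0, 2.0, "compensatory"),
        ((False, False, False), 0.0, 0.0, "conserved"),
    ],
)
def test_classify7_examples(sig, h, t, expected):
    assert ct.classify7(*sig, h, t) == expected


def test_count_diff_test_contract(config):
    same = ct.count_diff_test((100, 110, 90), (100, 110, 90), config)
    assert same.log2fc == pytest.approx(0.0)
    assert not same.significant

    strong = ct.count_diff_test((100, 110, 90), (10, 11, 9), config)
    # log2((100 + 0.5) / (10 + 0.5)): the 0.5 pseudocount acts on the means
    assert abs(strong.log2fc) == pytest.approx(3.2587, abs=1e-3)
    assert abs(strong.log2fc) > 2
    assert strong.p < 0.01 and strong.significant

    with pytest.raises(ValueError):
        ct.count_diff_test((100,), (10, 11), config)


def test_count_diff_fold_change_gate():
    gated = AnalysisConfig(fc_gate=True)
    res = ct.count_diff_test((100, 110, 90), (60, 66, 54), gated)
    assert abs(res.log2fc) < 2  # ~0.74-fold short of the 4-fold gate
    assert not res.significant
    strong = ct.count_diff_test((100, 110, 90), (10, 11, 9), gated)
    assert strong.significant


def test_ratio_diff_test_contract(config):
    # identical degenerate sets: jitter rule keeps the test defined, p ~ 1
    p = ct.ratio_diff_test((1.0, 1.0, 1.0), (1.0, 1.0, 1.0), config)
    assert p > 0.9
    p = ct.ratio_diff_test((2.0, 2.1, 1.9), (0.0, 0.1, -0.1), config)
    assert p < 0.01
    p = ct.ratio_diff_test((2.0, 2.0), (0.0, 0.0, 0.0), config)
    assert 0.0 <= p <= 1.0
    with pytest.raises(ValueError):
        ct.ratio_diff_test((np.inf, 1.0), (0.0, 0.0), config)


@pytest.mark.parametrize(
    "cat,p,h,dm,expected,strong",
    [
        ("cis_only", 2.4, 2.5, np.nan, "cis_only_toR", True),
        ("trans_only", -2.1, 0.1, np.nan, "trans_only_toC", True),
        ("conserved", 0.1, 0.0, np.nan, "conserved", False),
        ("cis_only", -1.5, -1.4, np.nan, "cis_only_toC", False),
        ("compensatory", 0.0, -1.8, np.nan, "compensatory_toR", False),
        ("cis_only", 1.5, 1.4, 0.5, "cis_only_toR", True),
    ],
)
def test_subpattern13_rule(cat, p, h, dm, expected, strong, config):
    label, flag = ct.subpattern13(cat, p, h, dm, config)
    assert label == expected and flag is strong


def test_thirteen_pattern_space(config):
    labels = {"conserved"}
    for cat in ct.CATEGORIES7:
        if cat == "conserved":
            continue
        for p, h in [(2.0, 1.0), (-2.0, -1.0), (0.5, 2.0), (-0.5, -2.0)]:
            labels.add(ct.subpattern13(cat, p, h, np.nan, config)[0])
    assert len(labels) == 13


def _simulated(seed=21, n=400, **kw):
    params = SimulationParams(n_pairs=n, n_chrom_pairs=2, seed=seed, **kw)
    g = simulate_genome(params)
    mat, truth = simulate_expression(g.pairs, params)
    return ex.normalize(mat), g.pairs, truth


def test_classify_pairs_recovers_planted_categories(config):
    mat, pairs, truth = _simulated()
    calls = ct.classify_pairs(mat, pairs, "F1", config)
    merged = calls.merge(truth, on="pair_id")
    for cat in ("cis_only", "trans_only", "compensatory"):
        sub = merged[merged["true_category7"] == cat]
        assert (sub["category7"] == cat).mean() >= 0.8, cat
    cons = merged[merged["true_category7"] == "conserved"]
    assert (
        ~cons["category7"].isin(["conserved", "ambiguous"])
    ).mean() <= 0.05


def test_classify_pairs_t_equals_p_minus_h(config):
    mat, pairs, _ = _simulated(seed=3, n=100)
    calls = ct.classify_pairs(mat, pairs, "F22", config)
    np.testing.assert_allclose(calls["T"], calls["P"] - calls["H"], atol=1e-9)
    assert calls["category7"].isin(ct.CATEGORIES7).all()


def test_classify_pairs_mirror_symmetry(config):
    """Relabelling R as C mirrors every directional category."""
    mat, pairs, _ = _simulated(seed=5, n=150)
    swapped = pairs.rename(columns={"r_gene": "c_gene", "c_gene": "r_gene"})
    # swap parental roles too: the R parent now carries the C genes
    sheet = mat.samples.copy()
    sheet["role"] = sheet["role"].map(
        {"parent_R": "parent_C", "parent_C": "parent_R", "hybrid": "hybrid"}
    )
    from homoeokit.core import ExpressionMatrix

    mat_sw = ex.normalize(ExpressionMatrix(counts=mat.counts, samples=sheet))
    a = ct.classify_pairs(mat, pairs, "F1", config).set_index("pair_id")
    b = ct.classify_pairs(mat_sw, swapped, "F1", config).set_index("pair_id")
    common = a.index.intersection(b.index)
    np.testing.assert_allclose(a.loc[common, "P"], -b.loc[common, "P"], atol=1e-9)
    np.testing.assert_allclose(a.loc[common, "H"], -b.loc[common, "H"], atol=1e-9)
    assert (a.loc[common, "category7"] == b.loc[common, "category7"]).all()
    mirror = lambda s: s.replace("_toR", "_toX").replace("_toC", "_toR").replace("_toX", "_toC")
    assert all(
        mirror(x) == y
        for x, y in zip(a.loc[common, "subpattern13"], b.loc[common, "subpattern13"])
    )


def test_recovery_improves_with_depth(config):
    """Monotonicity: deeper libraries recover at least as many planted effects."""
    rates = []
    for depth in (20.0, 400.0):
        mat, pairs, truth = _simulated(seed=13, n=300, depth_mean=depth)
        calls = ct.classify_pairs(mat, pairs, "F1", config)
        merged = calls.merge(truth, on="pair_id")
        planted = merged[merged["true_category7"].isin(["cis_only", "trans_only"])]
        rates.append((planted["category7"] == planted["true_category7"]).mean())
    assert rates[1] >= rates[0]


def test_classify_pair_scalar_route(config):
    mat, pairs, truth = _simulated(seed=2, n=60, depth_mean=500.0)
    pid = truth.loc[truth["true_category7"] == "cis_only", "pair_id"].iloc[0]
    call = ct.classify_pair(mat, pairs, pid, "F1", config)
    assert call is not None and call["generation"] == "F1"
    assert np.isfinite(call["p_P"]) and np.isfinite(call["p_T"])


def test_kaks_group_stats(config, rng):
    calls = pd.DataFrame(
        {
            "pair_id": [f"p{i}" for i in range(400)],
            "category7": ["cis_only"] * 200 + ["conserved"] * 199 + ["trans_only"],
        }
    )
    kaks = pd.DataFrame(
        {
            "pair_id": calls["pair_id"],
            "ka": 0.1,
            "ks": 1.0,
            "ka_ks": np.concatenate([rng.normal(0.4, 0.1, 200), rng.normal(0.2, 0.1, 200)]),
        }
    )
    out = ct.kaks_group_stats(kaks, calls, config).set_index("category7")
    assert out.loc["cis_only", "p_vs_all"] < 0.05        # planted shift detected
    assert np.isnan(out.loc["trans_only", "p_vs_all"])   # single member: no test
    assert out.loc["all", "n"] == 400


def test_kaks_identical_group_not_significant(config):
    calls = pd.DataFrame(
        {"pair_id": [f"p{i}" for i in range(10)], "category7": ["cis_only"] * 10}
    )
    kaks = pd.DataFrame(
        {"pair_id": calls["pair_id"], "ka": 0.1, "ks": 1.0,
         "ka_ks": np.linspace(0.1, 0.5, 10)}
    )
    out = ct.kaks_group_stats(kaks, calls, config).set_index("category7")
    assert out.loc["cis_only", "p_vs_all"] > 0.9


def test_binary_association_contract(rng):
    phi, p = ct.binary_association([1, 0, 1, 0], [1, 0, 1, 0])
    assert phi == pytest.approx(1.0)
    phi, _ = ct.binary_association([1, 0, 1, 0], [0, 1, 0, 1])
    assert phi == pytest.approx(-1.0)
    with pytest.raises(ValueError, match="constant"):
        ct.binary_association([1, 1, 1], [1, 0, 1])
    a = rng.random(1000) < 0.3
    b = rng.random(1000) < 0.3
    phi, p = ct.binary_association(a, b)
    assert abs(phi) < 0.1


def test_variance_moderation_calibrated_under_null(rng):
    """Moderated two-sample test keeps ~nominal size on null normal data."""
    a = rng.normal(0, 1, size=(5000, 3))
    b = rng.normal(0, 1, size=(5000, 3))
    _, p = ct.moderated_two_sample(a, b)
    assert 0.002 < (p < 0.01).mean() < 0.025
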