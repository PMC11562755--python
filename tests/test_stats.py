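import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from drgstereo import (
    mixed_anova,
    one_way_anova,
    paired_t,
    power_sample_size_t,
    shapiro_wilk,
    sidak_adjust,
    two_sample_t_power,
)


def split_plot_oracle(data, dv="value", subject="subject", between="between", within="within"):
    """Independent cell-means sums-of-squares decomposition for a balanced
    split-plot design; returns the three F statistics with their dfs."""
    d = data.copy()
    grand = d[dv].mean()
    n_w = d[within].nunique()
    subj_mean = d.groupby(subject)[dv].mean()
    grp_of = d.groupby(subject)[between].first()
    grp_mean = d.groupby(between)[dv].mean()
    w_mean = d.groupby(within)[dv].mean()
    cell = d.groupby([between, within])[dv].mean()
    n_subj_per_grp = grp_of.value_counts()

    ss_between = n_w * sum(
        n_subj_per_grp[g] * (grp_mean[g] - grand) ** 2 for g in grp_mean.index
    )
    ss_subj = n_w * sum(
        (subj_mean[s] - grp_mean[grp_of[s]]) ** 2 for s in subj_mean.index
    )
    n_subj = len(subj_mean)
    ss_within = n_subj * sum((w_mean[w] - grand) ** 2 for w in w_mean.index)
    ss_inter = sum(
        n_subj_per_grp[g] * (cell[(g, w)] - grp_mean[g] - w_mean[w] + grand) ** 2
        for g in grp_mean.index
        for w in w_mean.index
    )
    ss_total = ((d[dv] - grand) ** 2).sum()
    ss_err = ss_total - ss_between - ss_subj - ss_within - ss_inter

    k = len(grp_mean)
    df_b, df_subj = k - 1, n_subj - k
    df_w = n_w - 1
    df_i = df_b * df_w
    df_e = df_subj * df_w
    return {
        "between": ((ss_between / df_b) / (ss_subj / df_subj), (df_b, df_subj)),
        "within": ((ss_within / df_w) / (ss_err / df_e), (df_w, df_e)),
        "interaction": ((ss_inter / df_i) / (ss_err / df_e), (df_i, df_e)),
    }


def _toy_2x2():
    # group A subjects with (w1, w2) = (1,2), (1,3); group B (3,4), (5,6)
    rows = []
    for s, grp, vals in [
        ("s1", "A", (1, 2)), ("s2", "A", (1, 3)),
        ("s3", "B", (3, 4)), ("s4", "B", (5, 6)),
    ]:
        for w, v in zip(("w1", "w2"), vals):
            rows.append({"subject": s, "between": grp, "within": w, "value": float(v)})
    return pd.DataFrame(rows)


def test_paired_t_frozen():
    res = paired_t([1, 2, 4], [2, 2, 7])
    eff = res.effects["effect"]
    assert eff["statistic"] == pytest.approx(-1.5119, abs=1e-4)
    assert eff["df"] == 2
    assert eff["p"] == pytest.approx(0.2698, abs=1e-3)
    ref = sps.ttest_rel([1, 2, 4], [2, 2, 7])
    assert eff["statistic"] == pytest.approx(ref.statistic)
    assert eff["p"] == pytest.approx(ref.pvalue)


def test_paired_t_degenerate():
    res = paired_t([1.0, 2.0], [1.0, 2.0])
    assert res.effects["effect"]["statistic"] == 0.0
    assert res.effects["effect"]["p"] == 1.0
    res2 = paired_t([2.0, 3.0], [1.0, 2.0])  # constant nonzero difference
    assert res2.effects["effect"]["p"] <= 1e-15
    assert res2.flags
    with pytest.raises(ValueError):
        paired_t([1.0], [2.0])
    with pytest.raises(ValueError):
        paired_t([1, 2, 3], [1, 2])


def test_one_way_frozen():
    res = one_way_anova([[1, 2, 3], [2, 3, 4], [3, 4, 5]])
    eff = res.effects["effect"]
    assert eff["statistic"] == pytest.approx(3.0)
    assert tuple(eff["df"]) == (2, 6)
    assert eff["p"] == pytest.approx(0.125)
    ref = sps.f_oneway([1, 2, 3], [2, 3, 4], [3, 4, 5])
    assert eff["p"] == pytest.approx(ref.pvalue)


def test_one_way_identical_groups():
    res = one_way_anova([[1, 2, 3], [1, 2, 3]])
    assert res.effects["effect"]["statistic"] == pytest.approx(0.0)
    assert res.effects["effect"]["p"] == pytest.approx(1.0)


def test_one_way_tukey_matches_scipy(rng):
    groups = [rng.normal(loc=m, size=6) for m in (0.0, 0.5, 2.0)]
    res = one_way_anova(groups, labels=["a", "b", "c"])
    ref = sps.tukey_hsd(*groups)
    got = {pt["comparison"]: pt["p_adj"] for pt in res.posttests}
    assert got["a vs b"] == pytest.approx(ref.pvalue[0, 1])
    assert got["a vs c"] == pytest.approx(ref.pvalue[0, 2])
    assert got["b vs c"] == pytest.approx(ref.pvalue[1, 2])
    # adjusted p never below raw pairwise p
    for (i, j), key in [((0, 1), "a vs b"), ((0, 2), "a vs c"), ((1, 2), "b vs c")]:
        raw = sps.ttest_ind(groups[i], groups[j]).pvalue
        assert got[key] >= raw - 1e-9


def test_one_way_validation():
    with pytest.raises(ValueError):
        one_way_anova([[1, 2, 3]])
    with pytest.raises(ValueError):
        one_way_anova([[1.0], [2.0, 3.0]])


def test_mixed_anova_toy_oracle():
    data = _toy_2x2()
    res = mixed_anova(data)
    oracle = split_plot_oracle(data)
    assert res.effects["between"]["statistic"] == pytest.approx(oracle["between"][0])
    assert res.effects["within"]["statistic"] == pytest.approx(oracle["within"][0])
    assert res.effects["interaction"]["statistic"] == pytest.approx(
        oracle["interaction"][0]
    )
    # frozen hand-computed values for this toy
    assert res.effects["between"]["statistic"] == pytest.approx(7.1176, abs=1e-3)
    assert res.effects["within"]["statistic"] == pytest.approx(25.0)
    assert res.effects["interaction"]["statistic"] == pytest.approx(1.0)
    assert tuple(res.effects["between"]["df"]) == (1, 2)
    assert tuple(res.effects["within"]["df"]) == (1, 2)


def test_mixed_anova_flat_within():
    data = _toy_2x2()
    wide = data.pivot_table(index=["subject", "between"], columns="within", values="value")
    wide["w2"] = wide["w1"]  # identical within levels per subject
    flat = wide.reset_index().melt(
        id_vars=["subject", "between"], var_name="within", value_name="value"
    )
    res = mixed_anova(flat)
    assert res.effects["within"]["statistic"] == pytest.approx(0.0, abs=1e-10)
    assert res.effects["interaction"]["statistic"] == pytest.approx(0.0, abs=1e-10)


def test_mixed_anova_single_between_level():
    data = _toy_2x2()
    data["between"] = "A"
    res = mixed_anova(data)
    assert "within" in res.effects
    assert any("single between level" in f for f in res.flags)


def test_mixed_anova_incomplete_errors():
    data = _toy_2x2().iloc[:-1]
    with pytest.raises(ValueError, match="incomplete"):
        mixed_anova(data)
    dup = pd.concat([_toy_2x2(), _toy_2x2().iloc[[0]]], ignore_index=True)
    with pytest.raises(ValueError):
        mixed_anova(dup)


def test_mixed_anova_sidak_posttests():
    data = _toy_2x2()
    res = mixed_anova(
        data,
        posttests={"method": "sidak", "comparisons": [("within", "w1", "w2")]},
    )
    pt = res.posttests[0]
    wide = data.pivot_table(index="subject", columns="within", values="value")
    raw = paired_t(wide["w1"], wide["w2"]).effects["effect"]["p"]
    assert pt["p_adj"] == pytest.approx(float(sidak_adjust([raw], 1)[0]))
    with pytest.raises(ValueError, match="family size"):
        mixed_anova(
            data,
            posttests={
                "method": "sidak",
                "comparisons": [("within", "w1", "w2")],
                "family_size": 0,
            },
        )


def test_mixed_anova_tukey_posttests():
    data = _toy_2x2()
    res = mixed_anova(data, posttests={"method": "tukey"})
    assert res.posttests and res.posttests[0]["method"] == "tukey"


def test_sidak_frozen_and_monotone():
    assert float(sidak_adjust([0.05], 3)[0]) == pytest.approx(0.142625)
    assert float(sidak_adjust([0.2], 1)[0]) == pytest.approx(0.2)
    ps = np.linspace(0, 1, 11)
    adj = sidak_adjust(ps, 4)
    assert (np.diff(adj) >= -1e-12).all()
    assert (adj >= ps - 1e-12).all() and (adj <= 1.0).all()
    with pytest.raises(ValueError):
        sidak_adjust([0.1, 0.2], 0)
    with pytest.raises(ValueError):
        sidak_adjust([1.5], 2)


def test_shapiro():
    rng = np.random.default_rng(0)
    res = shapiro_wilk(rng.normal(size=50))
    assert res.effects["effect"]["p"] > 0.01
    skewed = shapiro_wilk(rng.exponential(size=200))
    assert skewed.effects["effect"]["p"] < 1e-4
    with pytest.raises(ValueError):
        shapiro_wilk([1.0, 2.0])
    with pytest.raises(ValueError):
        shapiro_wilk([3.0, 3.0, 3.0])


def test_power_frozen():
    assert power_sample_size_t(4.81) == 3
    assert two_sample_t_power(2, 4.81) < 0.8 <= two_sample_t_power(3, 4.81)
    assert power_sample_size_t(1.0) == 17
    with pytest.raises(ValueError):
        power_sample_size_t(0.0)
    with pytest.raises(ValueError):
        power_sample_size_t(1.0, alpha=1.5)
    with pytest.raises(ValueError):
        power_sample_size_t(1e-6, n_max=100)


def test_report_formatting():
    res = mixed_anova(_toy_2x2())
    txt = res.report()
    assert "F1,2" in txt
    assert "P" in txt
    t = paired_t([1, 2, 4], [2, 2, 7]).report()
    assert t.startswith("t2 =")
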