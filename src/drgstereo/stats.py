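"""Classical inference toolkit: paired t, one-way ANOVA with Tukey HSD,
two-way mixed (split-plot) repeated-measures ANOVA with Šídák or Tukey
posttests, Shapiro–Wilk normality gating, Šídák familywise adjustment, and
noncentral-t power / sample-size computation.

Conventions: all p-values are two-sided; posttest families are declared
explicitly by the caller (never inferred from the data); the mixed ANOVA
assumes sphericity (no Greenhouse–Geisser correction by default, matching
uncorrected repeated-measures reporting).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestResult",
    "paired_t",
    "one_way_anova",
    "mixed_anova",
    "sidak_adjust",
    "shapiro_wilk",
    "two_sample_t_power",
    "power_sample_size_t",
]

_P_FLOOR = 1e-15


@dataclass
class TestResult:
    """Outcome of one inference operation.

    ``effects`` maps an effect label to ``{"statistic", "df", "p"}`` (df is a
    number or a (df1, df2) tuple); ``posttests`` is a list of
    ``{"comparison", "statistic", "p_adj", "method"}`` dicts.
    """

    test: str
    effects: dict
    posttests: list = field(default_factory=list)
    flags: list = field(default_factory=list)

    def report(self) -> str:
        """Figure-legend-style summary, e.g. ``F4,10 = 37.98, P < 0.001``."""
        parts = []
        for name, e in self.effects.items():
            stat, df, p = e["statistic"], e["df"], e["p"]
            if isinstance(df, (tuple, list)):
                head = f"F{df[0]},{df[1]} = {stat:.2f}"
            else:
                letter = "t" if self.test.startswith(("paired", "t")) else "W"
                head = f"{letter}{df:g} = {stat:.3g}" if df is not None else f"{stat:.3g}"
            ptxt = "P < 0.001" if p < 0.001 else f"P = {p:.3f}"
            parts.append(f"{name}: {head}, {ptxt}" if name != "effect" else f"{head}, {ptxt}")
        for pt in self.posttests:
            ptxt = "P < 0.001" if pt["p_adj"] < 0.001 else f"P = {pt['p_adj']:.3f}"
            parts.append(f"{pt['comparison']} ({pt['method']}): {ptxt}")
        return "; ".join(parts)

    def to_dict(self) -> dict:
        return {
            "test": self.test,
            "effects": self.effects,
            "posttests": self.posttests,
            "flags": self.flags,
        }


def paired_t(x, y) -> TestResult:
    """Two-sided paired t test on per-animal values (paired by position)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("paired samples must have equal length")
    if x.size < 2:
        raise ValueError("need at least 2 pairs")
    d = x - y
    n = d.size
    sd = d.std(ddof=1)
    flags = []
    if sd == 0:
        if d.mean() == 0:
            t_stat, p = 0.0, 1.0
        else:
            t_stat, p = np.inf * np.sign(d.mean()), _P_FLOOR
            flags.append("zero variance of differences; p reported as < 1e-15")
    else:
        t_stat = d.mean() / (sd / np.sqrt(n))
        p = 2 * sps.t.sf(abs(t_stat), n - 1)
    return TestResult(
        test="paired_t",
        effects={"effect": {"statistic": float(t_stat), "df": n - 1, "p": float(p)}},
        flags=flags,
    )


def one_way_anova(groups, labels=None, posttest: str = "tukey") -> TestResult:
    """One-way ANOVA (F = MSB/MSW) with Tukey HSD posttests on all pairs."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(g.size < 2 for g in groups):
        raise ValueError("every group needs n >= 2")
    if labels is None:
        labels = [f"g{i}" for i in range(len(groups))]
    k = len(groups)
    n_total = sum(g.size for g in groups)
    grand = np.concatenate(groups).mean()
    ssb = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df1, df2 = k - 1, n_total - k
    msw = ssw / df2
    flags = []
    posttests = []
    if msw == 0:
        if ssb == 0:
            f_stat, p = float("nan"), float("nan")
            flags.append("all values identical; F undefined")
        else:
            f_stat, p = np.inf, _P_FLOOR
            flags.append("zero within-group variance; p reported as < 1e-15")
        if posttest == "tukey":
            for i in range(k):
                for j in range(i + 1, k):
                    diff = groups[i].mean() - groups[j].mean()
                    posttests.append(
                        {
                            "comparison": f"{labels[i]} vs {labels[j]}",
                            "statistic": float(diff),
                            "p_adj": 1.0 if diff == 0 else _P_FLOOR,
                            "method": "tukey",
                        }
                    )
    else:
        f_stat = (ssb / df1) / msw
        p = float(sps.f.sf(f_stat, df1, df2))
        if posttest == "tukey":
            res = sps.tukey_hsd(*groups)
            for i in range(k):
                for j in range(i + 1, k):
                    posttests.append(
                        {
                            "comparison": f"{labels[i]} vs {labels[j]}",
                            "statistic": float(groups[i].mean() - groups[j].mean()),
                            "p_adj": float(res.pvalue[i, j]),
                            "method": "tukey",
                        }
                    )
    return TestResult(
        test="one_way_anova",
        effects={"effect": {"statistic": float(f_stat), "df": (df1, df2), "p": float(p)}},
        posttests=posttests,
        flags=flags,
    )


def _check_complete(data, dv, subject, between, within):
    pivot = data.pivot_table(index=subject, columns=within, values=dv, aggfunc="count")
    if pivot.isna().any().any() or (pivot != 1).any().any():
        raise ValueError(
            "incomplete or duplicated within-subject data; every subject needs "
            "exactly one value per within level (no imputation is performed)"
        )
    per_subj_groups = data.groupby(subject)[between].nunique()
    if (per_subj_groups != 1).any():
        raise ValueError("each subject must belong to exactly one between-group level")


def mixed_anova(
    data: pd.DataFrame,
    dv: str = "value",
    subject: str = "subject",
    between: str = "between",
    within: str = "within",
    posttests: dict | None = None,
) -> TestResult:
    """Two-way mixed (split-plot) repeated-measures ANOVA.

    The between-subjects effect is tested against the subject-within-group
    error; the within effect and the group × within interaction against the
    residual within-subject error. With a single between level this reduces to
    a one-way repeated-measures ANOVA on the within factor.

    ``posttests`` declares the comparison family explicitly, e.g.
    ``{"method": "sidak", "comparisons": [("within", lvl_a, lvl_b), ...]}``
    for paired within-level contrasts, or ``{"method": "tukey"}`` for
    all-pairs contrasts of between-group means. The Šídák family size is the
    number of declared comparisons.
    """
    import pingouin as pg

    _check_complete(data, dv, subject, between, within)
    flags = []
    g_sizes = data.groupby(between)[subject].nunique()
    if g_sizes.min() < 2:
        raise ValueError("need >= 2 subjects per between-group level")
    effects: dict = {}
    def _effect(name, f, dfs, p, ss):
        # a zero-SS effect has no signal: F = 0, p = 1 even when the error
        # term is also degenerate (e.g. within levels identical per subject)
        if not np.isfinite(f):
            if ss == 0:
                f, p = 0.0, 1.0
            else:
                f, p = float("inf"), _P_FLOOR
            flags.append(f"degenerate error term for {name}")
        effects[name] = {"statistic": float(f), "df": dfs, "p": float(p)}

    if g_sizes.size == 1:
        aov = pg.rm_anova(data=data, dv=dv, within=within, subject=subject, detailed=True)
        row = aov.iloc[0]
        _effect(
            within,
            row["F"],
            (int(row["DF"]), int(aov.iloc[1]["DF"])),
            row["p_unc"],
            float(row["SS"]),
        )
        flags.append("single between level: one-way repeated-measures ANOVA")
    else:
        if g_sizes.nunique() > 1:
            flags.append("unbalanced between-group sizes; Type-III-equivalent sums of squares")
        aov = pg.mixed_anova(
            data=data, dv=dv, within=within, subject=subject, between=between
        )
        for _, row in aov.iterrows():
            name = {between: between, within: within, "Interaction": "interaction"}.get(
                row["Source"], row["Source"]
            )
            _effect(
                name,
                row["F"],
                (int(row["DF1"]), int(row["DF2"])),
                row["p_unc"],
                float(row["SS"]),
            )
    result = TestResult(test="mixed_anova", effects=effects, flags=flags)
    if posttests:
        result.posttests = _mixed_posttests(
            data, dv, subject, between, within, posttests
        )
    return result


def _mixed_posttests(data, dv, subject, between, within, spec) -> list:
    method = spec.get("method", "sidak")
    out = []
    if method == "sidak":
        comps = spec["comparisons"]
        m = spec.get("family_size", len(comps))
        if m < len(comps):
            raise ValueError("declared family size smaller than number of comparisons")
        for comp in comps:
            factor, a, b = comp
            if factor == within:
                wide = data.pivot_table(index=subject, columns=within, values=dv)
                res = paired_t(wide[a].to_numpy(), wide[b].to_numpy())
                stat = res.effects["effect"]["statistic"]
                p_raw = res.effects["effect"]["p"]
            elif factor == between:
                xs = data.loc[data[between] == a].groupby(subject)[dv].mean()
                ys = data.loc[data[between] == b].groupby(subject)[dv].mean()
                t_res = sps.ttest_ind(xs, ys)
                stat, p_raw = float(t_res.statistic), float(t_res.pvalue)
            else:
                raise ValueError(f"unknown posttest factor {factor!r}")
            out.append(
                {
                    "comparison": f"{a} vs {b}",
                    "statistic": stat,
                    "p_adj": float(sidak_adjust([p_raw], m)[0]),
                    "method": "sidak",
                }
            )
    elif method == "tukey":
        means = data.groupby([between, subject])[dv].mean().reset_index()
        groups, labels = [], []
        for lvl, sub in means.groupby(between):
            groups.append(sub[dv].to_numpy())
            labels.append(str(lvl))
        res = sps.tukey_hsd(*groups)
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                out.append(
                    {
                        "comparison": f"{labels[i]} vs {labels[j]}",
                        "statistic": float(groups[i].mean() - groups[j].mean()),
                        "p_adj": float(res.pvalue[i, j]),
                        "method": "tukey",
                    }
                )
    else:
        raise ValueError(f"unknown posttest method {method!r}")
    return out


def sidak_adjust(p, m: int):
    """Šídák familywise adjustment p_adj = 1 − (1 − p)^m, capped at 1."""
    p = np.asarray(p, dtype=float)
    if m < 1:
        raise ValueError("family size m must be >= 1")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must be in [0, 1]")
    return np.minimum(1.0, 1.0 - (1.0 - p) ** m)


def shapiro_wilk(x) -> TestResult:
    """Shapiro–Wilk normality test (Royston's approximation; 3 ≤ n ≤ 5000),
    used as a gate at α = 0.05 before parametric testing."""
    x = np.asarray(x, dtype=float)
    if not 3 <= x.size <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise ValueError("sample has zero variance")
    w, p = sps.shapiro(x)
    return TestResult(
        test="shapiro_wilk",
        effects={"effect": {"statistic": float(w), "df": int(x.size), "p": float(p)}},
    )


def two_sample_t_power(n: int, d: float, alpha: float = 0.05) -> float:
    """Power of a two-sided two-sample t test with n per group, pooled
    variance, noncentrality d·√(n/2) and df 2n − 2."""
    if n < 2:
        return 0.0
    df = 2 * n - 2
    nc = d * np.sqrt(n / 2.0)
    tc = sps.t.ppf(1 - alpha / 2, df)
    return float(sps.nct.sf(tc, df, nc) + sps.nct.cdf(-tc, df, nc))


def power_sample_size_t(
    d: float, alpha: float = 0.05, power: float = 0.8, n_max: int = 10**6
) -> int:
    """Smallest integer per-group n ≥ 2 at which the two-sample t test
    attains the requested power for standardized effect size d."""
    if d <= 0:
        raise ValueError("effect size d must be > 0")
    if not 0 < alpha < 1 or not 0 < power < 1:
        raise ValueError("alpha and power must be in (0, 1)")
    hi = 2
    while two_sample_t_power(hi, d, alpha) < power:
        hi *= 2
        if hi > n_max:
            raise ValueError(f"requested power unattainable at n <= {n_max}")
    lo = max(2, hi // 2)
    while lo < hi:
        mid = (lo + hi) // 2
        if two_sample_t_power(mid, d, alpha) >= power:
            hi = mid
        else:
            lo = mid + 1
    return hi
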