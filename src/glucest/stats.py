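"""Group statistics: normality, one-way ANOVA, Tukey HSD, ANOVA power.

The ANOVA accepts either raw per-subject values or published
(n, mean, SD) summaries — the two routes are algebraically identical for
a fixed-effects one-way design, which lets published group tables be
re-analysed without the raw data.  Power and sample size use the
noncentral F distribution with the G*Power noncentrality convention
``lambda = f^2 * N`` (N = total sample size) for Cohen's f.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors

__all__ = [
    "GroupSummary",
    "PowerSpec",
    "PairwiseComparison",
    "AnovaResult",
    "test_normality",
    "summarize",
    "anova_oneway",
    "tukey_hsd",
    "power_anova",
    "required_sample_size",
]


@dataclass(frozen=True)
class GroupSummary:
    """Published-table form of one group: n, mean and sample SD (n-1)."""

    label: str
    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("each group needs n >= 2")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


@dataclass(frozen=True)
class PowerSpec:
    """Fixed-effects one-way ANOVA power specification."""

    alpha: float = 0.05
    target_power: float = 0.8
    effect_size_f: float = 0.8
    k_groups: int = 3

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1 or not 0 < self.target_power < 1:
            raise ValueError("alpha and target_power must be in (0, 1)")
        if self.effect_size_f <= 0:
            raise ValueError("effect size f must be positive")
        if self.k_groups < 2:
            raise ValueError("need at least 2 groups")


@dataclass(frozen=True)
class PairwiseComparison:
    pair: tuple[str, str]
    mean_diff: float
    q_stat: float
    adjusted_p: float


@dataclass(frozen=True)
class AnovaResult:
    f_stat: float
    df_between: int
    df_within: int
    p: float
    ms_within: float
    groups: tuple[GroupSummary, ...]
    pairwise: tuple[PairwiseComparison, ...] = ()


def test_normality(sample) -> dict:
    """Kolmogorov–Smirnov (Lilliefors-style, against the fitted normal)
    and Shapiro–Wilk normality tests.

    Returns the two p-values plus a per-test "normal at alpha = 0.05"
    verdict.  A constant sample leaves both tests undefined and raises.
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 3:
        raise ValueError("normality tests need n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("constant sample: normality tests undefined")
    # KS against the normal fitted to the sample requires the Lilliefors
    # null distribution, not the plain KS one.
    _, ks_p = lilliefors(x, dist="norm")
    sw = sps.shapiro(x)
    return {
        "ks_p": float(ks_p),
        "shapiro_p": float(sw.pvalue),
        "ks_normal": bool(ks_p > 0.05),
        "shapiro_normal": bool(sw.pvalue > 0.05),
        "ks_variant": "Lilliefors (KS against the fitted normal)",
    }


def summarize(label: str, values) -> GroupSummary:
    """Reduce raw values to the (n, mean, sample SD) summary form."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("each group needs n >= 2")
    return GroupSummary(
        label=label, n=int(x.size), mean=float(np.mean(x)), sd=float(np.std(x, ddof=1))
    )


def _coerce_groups(groups) -> tuple[GroupSummary, ...]:
    out = []
    for i, g in enumerate(groups):
        if isinstance(g, GroupSummary):
            out.append(g)
        else:
            out.append(summarize(f"group{i + 1}", g))
    return tuple(out)


def anova_oneway(groups, with_tukey: bool = True) -> AnovaResult:
    """One-way fixed-effects ANOVA from raw value lists or summaries.

    Sums of squares are reconstructed from the summary statistics:
    ``SS_between = sum n_i (mean_i - grand_mean)^2`` and
    ``SS_within = sum (n_i - 1) sd_i^2`` — exactly the raw-data
    decomposition, so both input forms give identical results.
    """
    summaries = _coerce_groups(groups)
    if len(summaries) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    ns = np.array([g.n for g in summaries], dtype=float)
    means = np.array([g.mean for g in summaries])
    sds = np.array([g.sd for g in summaries])
    k = len(summaries)
    n_total = ns.sum()
    grand = float(np.sum(ns * means) / n_total)
    df_between = k - 1
    df_within = int(n_total - k)
    ms_between = float(np.sum(ns * (means - grand) ** 2) / df_between)
    ms_within = float(np.sum((ns - 1) * sds**2) / df_within)
    if ms_within == 0:
        if np.allclose(means, grand):
            raise ValueError("zero variance everywhere: F undefined")
        f_stat, p = float("inf"), 0.0
    else:
        f_stat = ms_between / ms_within
        p = float(sps.f.sf(f_stat, df_between, df_within))
    result = AnovaResult(
        f_stat=f_stat,
        df_between=df_between,
        df_within=df_within,
        p=p,
        ms_within=ms_within,
        groups=summaries,
    )
    if with_tukey and np.isfinite(f_stat):
        result = AnovaResult(
            **{**result.__dict__, "pairwise": tukey_hsd(summaries, ms_within, df_within)}
        )
    return result


def tukey_hsd(
    summaries, ms_within: float, df_within: int
) -> tuple[PairwiseComparison, ...]:
    """All-pairs Tukey HSD from group summaries and the within-group MS.

    Equal-n groups use ``q = |m_i - m_j| / sqrt(MS_w / n)``; unequal n
    falls back to the Tukey–Kramer standard error
    ``sqrt(MS_w/2 * (1/n_i + 1/n_j))``.  Adjusted p-values come from the
    studentized-range distribution with (k, df_within).
    """
    summaries = _coerce_groups(summaries)
    if ms_within <= 0:
        raise ValueError("MS_within must be positive for Tukey HSD")
    k = len(summaries)
    out = []
    for gi, gj in combinations(summaries, 2):
        se = np.sqrt(ms_within / 2.0 * (1.0 / gi.n + 1.0 / gj.n))
        q = abs(gi.mean - gj.mean) / se
        p_adj = float(np.clip(sps.studentized_range.sf(q, k, df_within), 0.0, 1.0))
        out.append(
            PairwiseComparison(
                pair=(gi.label, gj.label),
                mean_diff=gi.mean - gj.mean,
                q_stat=float(q),
                adjusted_p=p_adj,
            )
        )
    return tuple(out)


def power_anova(spec: PowerSpec, n_per_group: int) -> float:
    """Power of the one-way ANOVA at ``n_per_group`` subjects per group.

    ``lambda = f^2 * k * n`` (the G*Power total-N convention); power is the
    probability that a noncentral F with (k-1, k(n-1)) df and that
    noncentrality exceeds the central-F critical value at ``alpha``.
    """
    if n_per_group < 2:
        raise ValueError("n per group must be >= 2")
    k = spec.k_groups
    df1, df2 = k - 1, k * (n_per_group - 1)
    lam = spec.effect_size_f**2 * k * n_per_group
    f_crit = sps.f.ppf(1.0 - spec.alpha, df1, df2)
    return float(sps.ncf.sf(f_crit, df1, df2, lam))


def required_sample_size(spec: PowerSpec, n_max: int = 10_000) -> dict:
    """Smallest per-group n reaching the target power, plus the total N
    and the achieved power at that n."""
    for n in range(2, n_max + 1):
        achieved = power_anova(spec, n)
        if achieved >= spec.target_power:
            return {
                "n_per_group": n,
                "total_n": n * spec.k_groups,
                "achieved_power": achieved,
            }
    raise RuntimeError(f"target power not reached by n = {n_max} per group")
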