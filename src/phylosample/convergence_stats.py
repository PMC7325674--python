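"""Statistics for the resampling-convergence experiment.

Per-effort RF distance distributions are summarized box-plot style (mean,
sample SD, 10/25/50/75/90th percentiles, points outside the 10–90 whiskers
flagged as outliers), compared with a classical one-way ANOVA, and probed
pairwise with three post hoc procedures (Tukey HSD, Bonferroni-corrected
pairwise t, Scheffé).  The convergence effort is the smallest effort whose
comparison with the next larger effort is non-significant under all three
procedures — the point at which adding columns no longer shifts the RF
distribution.  A Thompson Tau screen for outliers in assembly-completeness
values is included for the dataset-assembly stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class GroupSummary:
    n: int
    mean: float
    sd: float
    percentiles: dict[int, float]  # keys 10, 25, 50, 75, 90
    outliers: list[float]


@dataclass
class AnovaResult:
    F: float
    df1: int
    df2: int
    p: float


@dataclass
class ConvergenceReport:
    efforts: list[float]
    summaries: dict[float, GroupSummary]
    anova: AnovaResult
    posthoc: dict[str, pd.DataFrame]
    selected_effort: float | None
    alpha: float


PERCENTILES = (10, 25, 50, 75, 90)
PROCEDURES = ("tukey", "bonferroni", "scheffe")


def group_summary(groups: Mapping[float, Sequence[float]]) -> dict[float, GroupSummary]:
    """Box-plot style summaries per group (sample SD, linear-interpolated
    percentiles, points outside the 10/90 whiskers as outliers)."""
    out: dict[float, GroupSummary] = {}
    for key, values in groups.items():
        x = np.asarray(values, dtype=float)
        if x.size == 0:
            raise ValueError(f"empty group {key!r}")
        pct = {p: float(np.percentile(x, p)) for p in PERCENTILES}
        sd = float(np.std(x, ddof=1)) if x.size > 1 else 0.0
        outliers = sorted(float(v) for v in x[(x < pct[10]) | (x > pct[90])])
        out[key] = GroupSummary(int(x.size), float(x.mean()), sd, pct, outliers)
    return out


def _group_arrays(groups: Mapping[float, Sequence[float]]) -> list[np.ndarray]:
    return [np.asarray(v, dtype=float) for v in groups.values()]


def one_way_anova(groups: Mapping[float, Sequence[float]]) -> AnovaResult:
    """Classical fixed-effects one-way ANOVA (between/within decomposition)."""
    xs = _group_arrays(groups)
    if len(xs) < 2 or any(x.size < 2 for x in xs):
        raise ValueError("need >= 2 groups with >= 2 values each")
    grand = np.concatenate(xs).mean()
    n_total = sum(x.size for x in xs)
    k = len(xs)
    ssb = sum(x.size * (x.mean() - grand) ** 2 for x in xs)
    ssw = sum(((x - x.mean()) ** 2).sum() for x in xs)
    df1, df2 = k - 1, n_total - k
    if ssw == 0 and ssb == 0:
        raise ValueError("degenerate: zero variance within and between groups")
    if ssw == 0:
        return AnovaResult(math.inf, df1, df2, 0.0)
    F = (ssb / df1) / (ssw / df2)
    p = float(stats.f.sf(F, df1, df2))
    return AnovaResult(float(F), df1, df2, p)


def posthoc_pairwise(
    groups: Mapping[float, Sequence[float]],
    procedure: str = "tukey",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pairwise significance table after a one-way ANOVA.

    tukey: studentized-range HSD on the pooled within-group MS.
    bonferroni: pooled-variance pairwise t tests at alpha / (number of pairs).
    scheffe: contrast criterion (mean difference tested against
    sqrt((k−1)·F_crit·MSW·(1/ni+1/nj))).

    Returns a DataFrame with columns group1, group2, diff, stat, p, significant
    (p is the procedure-adjusted p-value; for Scheffé, the p of the scaled F).
    """
    if procedure not in PROCEDURES:
        raise ValueError(f"unknown procedure {procedure!r}; expected one of {PROCEDURES}")
    keys = list(groups)
    xs = _group_arrays(groups)
    if len(xs) < 2 or any(x.size < 2 for x in xs):
        raise ValueError("need >= 2 groups with >= 2 values each")
    k = len(xs)
    df2 = sum(x.size for x in xs) - k
    msw = sum(((x - x.mean()) ** 2).sum() for x in xs) / df2
    if msw == 0:
        raise ValueError("degenerate: zero within-group variance")
    m_pairs = k * (k - 1) // 2
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            xi, xj = xs[i], xs[j]
            diff = xi.mean() - xj.mean()
            se_t = math.sqrt(msw * (1.0 / xi.size + 1.0 / xj.size))
            if procedure == "tukey":
                se_q = math.sqrt(msw / 2.0 * (1.0 / xi.size + 1.0 / xj.size))
                q = abs(diff) / se_q
                p = float(stats.studentized_range.sf(q, k, df2))
                stat = q
            elif procedure == "bonferroni":
                t = abs(diff) / se_t
                p = min(1.0, 2.0 * float(stats.t.sf(t, df2)) * m_pairs)
                stat = t
            else:  # scheffe
                f = (diff / se_t) ** 2 / (k - 1)
                p = float(stats.f.sf(f, k - 1, df2))
                stat = f
            rows.append(
                {"group1": keys[i], "group2": keys[j], "diff": diff,
                 "stat": stat, "p": p, "significant": p < alpha}
            )
    return pd.DataFrame(rows)


def convergence_effort(
    groups: Mapping[float, Sequence[float]],
    alpha: float = 0.01,
) -> float | None:
    """Smallest effort whose adjacent pairwise comparison is non-significant.

    Efforts are taken in increasing order; effort e_i is selected if the
    (e_i, e_{i+1}) comparison is non-significant at `alpha` under all of
    Tukey, Bonferroni and Scheffé; None if every adjacent pair differs.
    """
    efforts = sorted(groups)
    if len(efforts) < 2:
        raise ValueError("need at least 2 efforts")
    tables = {proc: posthoc_pairwise(groups, proc, alpha) for proc in PROCEDURES}

    def significant(e1: float, e2: float) -> bool:
        for table in tables.values():
            row = table[((table.group1 == e1) & (table.group2 == e2))
                        | ((table.group1 == e2) & (table.group2 == e1))]
            if bool(row.significant.iloc[0]):
                return True
        return False

    for e1, e2 in zip(efforts, efforts[1:]):
        if not significant(e1, e2):
            return e1
    return None


def thompson_tau_outliers(values: Sequence[float], alpha: float = 0.05) -> list[float]:
    """Iterative Thompson Tau outlier screen.

    At each step the single point with the largest |x − mean| is flagged if
    that deviation exceeds τ·SD, where τ = t·(n−1)/(√n·√(n−2+t²)) with
    t = t_{α/2, n−2}; the flagged point is removed and the test repeated.
    """
    x = [float(v) for v in values]
    if len(x) < 3:
        raise ValueError("Thompson Tau needs at least 3 values")
    flagged: list[float] = []
    while len(x) >= 3:
        arr = np.asarray(x)
        sd = arr.std(ddof=1)
        if sd == 0:
            break
        n = arr.size
        t = stats.t.ppf(1.0 - alpha / 2.0, n - 2)
        tau = t * (n - 1) / (math.sqrt(n) * math.sqrt(n - 2 + t * t))
        dev = np.abs(arr - arr.mean())
        worst = int(np.argmax(dev))
        if dev[worst] > tau * sd:
            flagged.append(x.pop(worst))
        else:
            break
    return flagged


def build_convergence_report(
    groups: Mapping[float, Sequence[float]], alpha: float = 0.01
) -> ConvergenceReport:
    """Full report: summaries, ANOVA, all three post hoc tables, selection."""
    efforts = sorted(groups)
    ordered = {e: groups[e] for e in efforts}
    return ConvergenceReport(
        efforts=efforts,
        summaries=group_summary(ordered),
        anova=one_way_anova(ordered),
        posthoc={proc: posthoc_pairwise(ordered, proc, alpha) for proc in PROCEDURES},
        selected_effort=convergence_effort(ordered, alpha),
        alpha=alpha,
    )


def plot_effort_distributions(groups: Mapping[float, Sequence[float]], path: str) -> None:
    """Box plot of per-effort RF distributions (10/90 whiskers, median line)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    efforts = sorted(groups)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.boxplot([groups[e] for e in efforts], whis=(10, 90),
               tick_labels=[f"{e:g}" for e in efforts], showfliers=True)
    ax.set_xlabel("resampling effort (fraction of columns)")
    ax.set_ylabel("normalized RF distance to reference")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
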