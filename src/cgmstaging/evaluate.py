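"""Evaluation statistics: classification accuracy, ROC, survival, group tests.

Conventions:

* reported percentages are rounded half-up to the nearest integer (the exact
  counts are always carried alongside, and undefined ratios are ``None``,
  never zero);
* AUC is the Mann–Whitney U statistic divided by n1·n0 with midrank tie
  handling, with a DeLong-style variance for the confidence interval;
* the Kaplan–Meier cumulative risk at the horizon is 1 − S(horizon) with a
  Greenwood standard error and a linear 95 % CI clipped to [0, 100] %;
* Fisher's exact test replaces chi-square for 2×2 tables with any expected
  cell below 5;
* group medians are compared with Kruskal–Wallis across groups and pairwise
  Mann–Whitney U, two-tailed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from .classify import ThresholdSet, any_k_rule
from .metrics import DISCRIMINATING_METRICS


def _round_half_up_pct(x: float | None) -> int | None:
    if x is None:
        return None
    return int(math.floor(x + 0.5))


# ---------------------------------------------------------------------------
# confusion statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionStats:
    tp: int
    fp: int
    fn: int
    tn: int

    def _ratio(self, num: int, den: int) -> float | None:
        return 100.0 * num / den if den else None

    @property
    def sensitivity(self) -> float | None:
        return self._ratio(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> float | None:
        return self._ratio(self.tn, self.tn + self.fp)

    @property
    def ppv(self) -> float | None:
        return self._ratio(self.tp, self.tp + self.fp)

    @property
    def npv(self) -> float | None:
        return self._ratio(self.tn, self.tn + self.fn)

    def rounded(self) -> dict[str, int | None]:
        """Integer percentages, round-half-up (report parity)."""
        return {
            "sensitivity": _round_half_up_pct(self.sensitivity),
            "specificity": _round_half_up_pct(self.specificity),
            "ppv": _round_half_up_pct(self.ppv),
            "npv": _round_half_up_pct(self.npv),
        }


def confusion_stats(flags: Sequence[bool], outcomes: Sequence[bool]) -> ConfusionStats:
    """Counts and predictive values of a binary classifier vs a binary outcome."""
    f = np.asarray(flags, dtype=bool)
    o = np.asarray(outcomes, dtype=bool)
    if f.shape != o.shape:
        raise ValueError("flags and outcomes must have equal length")
    if f.size == 0:
        raise ValueError("empty input")
    return ConfusionStats(
        tp=int(np.sum(f & o)),
        fp=int(np.sum(f & ~o)),
        fn=int(np.sum(~f & o)),
        tn=int(np.sum(~f & ~o)),
    )


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ROCResult:
    auc: float
    ci_low: float
    ci_high: float
    thresholds: np.ndarray
    sensitivity: np.ndarray       # per threshold
    one_minus_specificity: np.ndarray

    def curve_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "sensitivity": self.sensitivity,
                "one_minus_specificity": self.one_minus_specificity,
            }
        )


def roc(scores: Sequence[float], labels: Sequence[bool]) -> ROCResult:
    """ROC with midrank-tie AUC (Mann–Whitney U / n1·n0) and DeLong CI."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if s.shape != y.shape:
        raise ValueError("scores and labels must have equal length")
    n1 = int(y.sum())
    n0 = int((~y).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")

    ranks = stats.rankdata(s)  # midranks
    auc = (ranks[y].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)

    # DeLong placement values for the variance
    psi = (s[y][:, None] > s[~y][None, :]).astype(float)
    psi += 0.5 * (s[y][:, None] == s[~y][None, :])
    v10 = psi.mean(axis=1)
    v01 = psi.mean(axis=0)
    var = 0.0
    if n1 > 1:
        var += v10.var(ddof=1) / n1
    if n0 > 1:
        var += v01.var(ddof=1) / n0
    half = 1.959963984540054 * math.sqrt(var)

    # curve: one operating point per distinct threshold (flag iff score >= t)
    thresholds = np.unique(s)[::-1]
    thresholds = np.concatenate(([np.inf], thresholds))
    sens = np.array([(s[y] >= t).mean() for t in thresholds])
    fpr = np.array([(s[~y] >= t).mean() for t in thresholds])
    return ROCResult(
        auc=float(auc),
        ci_low=float(max(auc - half, 0.0)),
        ci_high=float(min(auc + half, 1.0)),
        thresholds=thresholds,
        sensitivity=sens,
        one_minus_specificity=fpr,
    )


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KMCurve:
    event_times: np.ndarray
    survival: np.ndarray
    greenwood_se: np.ndarray
    horizon: float
    risk_pct: float              # 100 * (1 - S(horizon))
    risk_ci: tuple[float, float]

    def curve_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.event_times,
                "survival": self.survival,
                "greenwood_se": self.greenwood_se,
            }
        )


def km_estimate(
    times: Sequence[float], events: Sequence[bool], horizon: float = 1.0
) -> KMCurve:
    """Product-limit cumulative risk at ``horizon`` with Greenwood 95 % CI."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if t.size == 0:
        raise ValueError("empty input")
    if np.any(t < 0):
        raise ValueError("times must be non-negative")

    kmf = KaplanMeierFitter()
    kmf.fit(t, e)
    table = kmf.event_table
    d = table["observed"].to_numpy(dtype=float)
    n = table["at_risk"].to_numpy(dtype=float)
    ts = table.index.to_numpy(dtype=float)
    keep = d > 0
    d, n, ts = d[keep], n[keep], ts[keep]

    surv = np.cumprod(1.0 - d / n)
    gw = np.cumsum(d / (n * (n - d)))  # n == d terminal step gives inf SE, kept
    with np.errstate(divide="ignore", invalid="ignore"):
        se = surv * np.sqrt(gw)
    se = np.nan_to_num(se, nan=0.0, posinf=0.0)

    at = np.searchsorted(ts, horizon, side="right") - 1
    if at < 0:
        s_h, se_h = 1.0, 0.0
    else:
        s_h, se_h = float(surv[at]), float(se[at])
    risk = 100.0 * (1.0 - s_h)
    half = 1.959963984540054 * 100.0 * se_h
    return KMCurve(
        event_times=ts,
        survival=surv,
        greenwood_se=se,
        horizon=horizon,
        risk_pct=risk,
        risk_ci=(max(risk - half, 0.0), min(risk + half, 100.0)),
    )


def logrank(groups: Sequence[tuple[Sequence[float], Sequence[bool]]]) -> tuple[float, float]:
    """Log-rank chi-square statistic and p-value across >= 2 groups."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    times, events, labels = [], [], []
    for i, (t, e) in enumerate(groups):
        t = np.asarray(t, dtype=float)
        e = np.asarray(e, dtype=bool)
        if t.size == 0:
            raise ValueError("empty group")
        times.append(t)
        events.append(e)
        labels.append(np.full(t.size, i))
    res = multivariate_logrank_test(
        np.concatenate(times), np.concatenate(labels), np.concatenate(events)
    )
    return float(res.test_statistic), float(res.p_value)


# ---------------------------------------------------------------------------
# group comparisons and correlations
# ---------------------------------------------------------------------------

def _median_iqr(x: np.ndarray) -> str:
    q1, q2, q3 = np.percentile(x, [25, 50, 75])
    return f"{q2:.1f} ({q1:.1f}-{q3:.1f})"


def group_compare(
    metrics_by_group: Mapping[str, pd.DataFrame],
    numeric_cols: Sequence[str] | None = None,
    categorical_cols: Sequence[str] = (),
) -> pd.DataFrame:
    """Participant-characteristics table: medians, rank tests, count tests.

    Numeric columns get median (IQR) per group, a Kruskal–Wallis p across all
    groups and pairwise Mann–Whitney U p-values.  Categorical columns get
    counts and a chi-square test (Fisher's exact for 2×2 tables with any
    expected cell < 5).
    """
    names = list(metrics_by_group)
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    for g, df in metrics_by_group.items():
        if len(df) == 0:
            raise ValueError(f"group {g!r} is empty")
    if numeric_cols is None:
        numeric_cols = [
            c for c in next(iter(metrics_by_group.values())).columns
            if all(pd.api.types.is_numeric_dtype(d[c]) for d in metrics_by_group.values())
        ]

    rows = []
    pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
    for col in numeric_cols:
        samples = {g: metrics_by_group[g][col].to_numpy(dtype=float) for g in names}
        row: dict = {"variable": col, "kind": "numeric"}
        for g in names:
            row[f"{g}_summary"] = _median_iqr(samples[g])
            row[f"{g}_median"] = float(np.median(samples[g]))
        try:
            row["kruskal_p"] = float(stats.kruskal(*samples.values()).pvalue)
        except ValueError:  # all values identical across every group
            row["kruskal_p"] = 1.0
        for a, b in pairs:
            row[f"p_{a}_vs_{b}"] = float(
                stats.mannwhitneyu(samples[a], samples[b], alternative="two-sided").pvalue
            )
        rows.append(row)

    for col in categorical_cols:
        levels = sorted(
            set().union(*(set(metrics_by_group[g][col].unique()) for g in names))
        )
        counts = np.array(
            [[int((metrics_by_group[g][col] == lv).sum()) for lv in levels] for g in names]
        )
        row = {"variable": col, "kind": "categorical"}
        for g, c in zip(names, counts):
            row[f"{g}_summary"] = "/".join(f"{lv}:{k}" for lv, k in zip(levels, c))
        row["kruskal_p"] = float(_categorical_p(counts))
        for a, b in pairs:
            sub = counts[[names.index(a), names.index(b)]]
            sub = sub[:, sub.sum(axis=0) > 0]
            row[f"p_{a}_vs_{b}"] = float(_categorical_p(sub))
        rows.append(row)
    return pd.DataFrame(rows)


def _categorical_p(table: np.ndarray) -> float:
    """Chi-square, or Fisher's exact for sparse 2x2 tables."""
    table = np.asarray(table)
    if table.shape == (2, 2):
        expected = stats.contingency.expected_freq(table)
        if (expected < 5).any():
            return stats.fisher_exact(table)[1]
    if min(table.shape) < 2:
        return 1.0
    return stats.chi2_contingency(table)[1]


def offset_correlations(
    metrics_rows: pd.DataFrame,
    targets: Sequence[str] = ("ta140", "sd_glucose", "cv"),
    method: str = "pearson",
) -> pd.DataFrame:
    """Correlation of the nocturnal mean with TA140, SD and CV.

    Under purely biological between-participant variation the nocturnal
    (near-fasting) mean is only loosely tied to daytime excursions; a strong
    nocturnal-mean/TA140 correlation with no nocturnal-mean/CV correlation
    is the signature of additive per-session sensor offsets.
    """
    if len(metrics_rows) < 3:
        raise ValueError("need at least 3 rows")
    x = metrics_rows["nocturnal_mean"].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("nocturnal_mean is constant")
    corr = stats.pearsonr if method == "pearson" else stats.spearmanr
    rows = []
    for target in targets:
        yv = metrics_rows[target].to_numpy(dtype=float)
        if np.ptp(yv) == 0:
            raise ValueError(f"{target} is constant")
        r, p = corr(x, yv)
        rows.append({"metric": target, "r": float(r), "p": float(p)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# repeat-wear concordance
# ---------------------------------------------------------------------------

def repeatability_report(
    metrics_rows: pd.DataFrame,
    thresholds: ThresholdSet,
    k: int = 2,
    delta_mean_limit: float = 10.0,
    metric_names: Sequence[str] = DISCRIMINATING_METRICS,
) -> tuple[pd.DataFrame, dict]:
    """Paired-wear deltas and classification concordance.

    ``metrics_rows`` must contain exactly two sessions per participant
    (ordered by ``session_id``).  Deltas are second minus first.  Returns a
    per-participant table and a cohort summary with the count of pairs whose
    mean glucose moved by more than ``delta_mean_limit`` mg/dL and the
    concordance fraction of the any-k rule.
    """
    rows = []
    for pid, grp in metrics_rows.groupby("participant_id", sort=True):
        if len(grp) != 2:
            raise ValueError(f"participant {pid!r} does not have exactly 2 sessions")
        grp = grp.sort_values("session_id")
        first, second = grp.iloc[0], grp.iloc[1]
        row: dict = {"participant_id": pid}
        for m in ("mean_glucose", "nocturnal_mean", *metric_names):
            row[f"delta_{m}"] = float(second[m]) - float(first[m])
        flags1 = thresholds.is_elevated(first[list(thresholds.metric_names)].to_dict())
        flags2 = thresholds.is_elevated(second[list(thresholds.metric_names)].to_dict())
        for m in thresholds.metric_names:
            row[f"concordant_{m}"] = flags1[m] == flags2[m]
        rule1 = any_k_rule(first[list(thresholds.metric_names)].to_dict(), thresholds, k)
        rule2 = any_k_rule(second[list(thresholds.metric_names)].to_dict(), thresholds, k)
        row["any_k_first"] = rule1
        row["any_k_second"] = rule2
        row["any_k_concordant"] = rule1 == rule2
        rows.append(row)
    if not rows:
        raise ValueError("no paired sessions")
    table = pd.DataFrame(rows)
    n_big = int((table["delta_mean_glucose"].abs() > delta_mean_limit).sum())
    summary = {
        "n_pairs": len(table),
        "n_abs_delta_mean_gt_limit": n_big,
        "fraction_abs_delta_mean_gt_limit": n_big / len(table),
        "any_k_concordance_fraction": float(table["any_k_concordant"].mean()),
    }
    return table, summary
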