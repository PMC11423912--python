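"""Group-comparison statistics used for the quantification panels.

Control-vs-cKO comparisons use the independent two-tailed Student's t-test
(pooled variance) with a Bonferroni correction within each comparison family;
three-group E18.5 comparisons use one-way ANOVA followed by a post-hoc Tukey
HSD test.  Box-plot summaries use type-7 (linear-interpolation) quantiles and
1.5 x IQR whiskers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigurationError


@dataclass
class GroupComparison:
    group_labels: Tuple[str, ...]
    means: Tuple[float, ...]
    sems: Tuple[float, ...]
    ns: Tuple[int, ...]
    statistic: float
    df: float
    p_raw: float
    p_corrected: Optional[float] = None
    correction: str = ""
    test: str = ""
    degenerate: bool = False


@dataclass
class AnovaResult:
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float


@dataclass
class BoxSummary:
    median: float
    mean: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: List[float] = field(default_factory=list)


def _sem(x: np.ndarray) -> float:
    return float(x.std(ddof=1) / np.sqrt(x.size)) if x.size > 1 else 0.0


def students_t_test(a: Sequence[float], b: Sequence[float],
                    labels: Tuple[str, str] = ("a", "b"),
                    welch: bool = False) -> GroupComparison:
    """Independent two-tailed t-test (Student's pooled-variance by default;
    Welch behind a flag)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ConfigurationError("each group needs n >= 2")
    df = a.size + b.size - 2 if not welch else np.nan
    degenerate = False
    if not welch and a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        # zero pooled variance: identical-mean groups are indistinguishable,
        # different-mean groups are trivially separated
        if a.mean() == b.mean():
            t, p = 0.0, 1.0
        else:
            t, p = np.inf if a.mean() > b.mean() else -np.inf, 0.0
            degenerate = True
    else:
        res = sps.ttest_ind(a, b, equal_var=not welch)
        t, p = float(res.statistic), float(res.pvalue)
        if welch:
            df = float(res.df)
    return GroupComparison(
        group_labels=tuple(labels),
        means=(float(a.mean()), float(b.mean())),
        sems=(_sem(a), _sem(b)),
        ns=(int(a.size), int(b.size)),
        statistic=float(t), df=float(df), p_raw=float(p),
        test="welch_t" if welch else "students_t", degenerate=degenerate,
    )


def bonferroni(p_values: Sequence[float], m: Optional[int] = None) -> np.ndarray:
    """Bonferroni-corrected p-values: min(1, m * p)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ConfigurationError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < 1:
        raise ConfigurationError("correction factor m must be >= 1")
    return np.minimum(1.0, m * p)


def anova_tukey(groups: Sequence[Sequence[float]],
                labels: Optional[Sequence[str]] = None
                ) -> Tuple[AnovaResult, List[GroupComparison]]:
    """One-way ANOVA plus all pairwise Tukey HSD comparisons.

    The pairwise statistic reported is the studentized-range q; the adjusted
    p-value comes from the studentized-range distribution with k groups and
    N - k degrees of freedom.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 3:
        raise ConfigurationError(
            "anova_tukey needs >= 3 groups; use students_t_test for two")
    if any(g.size < 2 for g in arrays):
        raise ConfigurationError("each group needs n >= 2")
    labels = list(labels) if labels is not None else [f"g{i}" for i in range(len(arrays))]
    k = len(arrays)
    n_total = sum(g.size for g in arrays)
    df_within = n_total - k
    f_res = sps.f_oneway(*arrays)
    anova = AnovaResult(f_statistic=float(f_res.statistic), df_between=k - 1,
                        df_within=df_within, p_value=float(f_res.pvalue))
    hsd = sps.tukey_hsd(*arrays)
    msw = sum(((g.size - 1) * g.var(ddof=1)) for g in arrays) / df_within
    out: List[GroupComparison] = []
    for i in range(k):
        for j in range(i + 1, k):
            gi, gj = arrays[i], arrays[j]
            se = np.sqrt(msw / 2.0 * (1.0 / gi.size + 1.0 / gj.size))
            q = abs(gi.mean() - gj.mean()) / se if se > 0 else np.inf
            out.append(GroupComparison(
                group_labels=(labels[i], labels[j]),
                means=(float(gi.mean()), float(gj.mean())),
                sems=(_sem(gi), _sem(gj)),
                ns=(int(gi.size), int(gj.size)),
                statistic=float(q), df=float(df_within),
                p_raw=float(hsd.pvalue[i, j]),
                p_corrected=float(hsd.pvalue[i, j]),
                correction="tukey", test="tukey_hsd",
            ))
    return anova, out


def box_summary(values: Sequence[float]) -> BoxSummary:
    """Box-plot summary: type-7 quartiles, 1.5 x IQR whiskers, outliers listed."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ConfigurationError("box_summary requires at least one value")
    q1, med, q3 = np.quantile(x, [0.25, 0.5, 0.75])  # linear (type-7)
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = x[(x >= lo_fence) & (x <= hi_fence)]
    outliers = x[(x < lo_fence) | (x > hi_fence)]
    return BoxSummary(
        median=float(med), mean=float(x.mean()), q1=float(q1), q3=float(q3),
        whisker_low=float(inside.min()), whisker_high=float(inside.max()),
        outliers=[float(v) for v in np.sort(outliers)],
    )


def compare_conditions(table: pd.DataFrame,
                       design: Dict[str, List[dict]],
                       condition_col: str = "condition") -> pd.DataFrame:
    """Run the configured per-family comparisons on a tidy results table.

    ``design`` maps a family name to a list of comparisons, each a dict with
    keys ``measurement`` (column name), ``groups`` (condition labels; two for
    a t-test, three or more for ANOVA + Tukey) and optional ``test``
    ('t' | 'anova_tukey', default by group count).  Bonferroni correction is
    applied within each family with m = family size; Tukey p-values are
    already adjusted and are additionally Bonferroni-scaled only through the
    family m echoed in the output.
    """
    if condition_col not in table.columns:
        raise ConfigurationError(f"table lacks a {condition_col!r} column")
    rows = []
    for family, comparisons in design.items():
        m = len(comparisons)
        for spec in comparisons:
            meas = spec["measurement"]
            if meas not in table.columns:
                raise ConfigurationError(
                    f"unknown measurement {meas!r}; available: "
                    f"{sorted(c for c in table.columns if c != condition_col)}")
            labels = list(spec["groups"])
            samples = [table.loc[table[condition_col] == g, meas].dropna().to_numpy()
                       for g in labels]
            test = spec.get("test", "t" if len(labels) == 2 else "anova_tukey")
            if test == "t":
                comp = students_t_test(samples[0], samples[1], labels=tuple(labels))
                comps = [comp]
            else:
                _, comps = anova_tukey(samples, labels=labels)
            for comp in comps:
                if comp.correction != "tukey":
                    comp.p_corrected = float(bonferroni([comp.p_raw], m)[0])
                    comp.correction = f"bonferroni(m={m})"
                summaries = {
                    lab: box_summary(s) for lab, s in zip(labels, samples) if s.size
                }
                rows.append({
                    "family": family, "measurement": meas,
                    "group_a": comp.group_labels[0], "group_b": comp.group_labels[1],
                    "mean_a": comp.means[0], "mean_b": comp.means[1],
                    "sem_a": comp.sems[0], "sem_b": comp.sems[1],
                    "n_a": comp.ns[0], "n_b": comp.ns[1],
                    "test": comp.test, "statistic": comp.statistic, "df": comp.df,
                    "p_raw": comp.p_raw, "p_corrected": comp.p_corrected,
                    "correction": comp.correction, "m_family": m,
                    "median_a": summaries.get(comp.group_labels[0],
                                              BoxSummary(np.nan, np.nan, np.nan,
                                                         np.nan, np.nan, np.nan)).median,
                    "median_b": summaries.get(comp.group_labels[1],
                                              BoxSummary(np.nan, np.nan, np.nan,
                                                         np.nan, np.nan, np.nan)).median,
                })
    return pd.DataFrame(rows)
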