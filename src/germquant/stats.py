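"""Statistical layer for longevity and phenotype comparisons.

Implements the analyses used on CFU longevity assays and germination
phenotype tables: normalization of colony counts to the day-0 value,
trapezoidal area under the survival curve compared between conditions by a
two-sample t test on per-replicate AUCs, Fisher's exact test on
germinated/not-germinated counts, one-way ANOVA on first-division times,
and percent survival after an acute stress (treated/control CFU ratio).

Conventions: the t test defaults to the Student (pooled-variance) form with
Welch available via a flag; the two-sided Fisher p-value follows the
probability-ordering convention (sum of hypergeometric probabilities of all
tables, at the observed margins, no more probable than the observed table,
with 1e-12 relative tie slack); no multiple-testing correction is applied
by default, with Bonferroni / Benjamini-Hochberg available as an option.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "CFUSeries",
    "StatResult",
    "normalize_cfu",
    "auc",
    "compare_survival_auc",
    "fisher_exact",
    "anova_oneway",
    "stress_survival",
    "adjust_pvalues",
    "read_cfu_table",
    "write_cfu_table",
]


@dataclass
class CFUSeries:
    """Colony-forming-unit counts of one condition/replicate over storage time."""

    condition: str
    replicate: int
    times_days: np.ndarray
    cfu: np.ndarray
    normalized: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times_days = np.asarray(self.times_days, dtype=float)
        self.cfu = np.asarray(self.cfu, dtype=float)
        if self.times_days.shape != self.cfu.shape:
            raise ValueError("times and counts must have equal length")
        if np.any(np.diff(self.times_days) < 0):
            raise ValueError("times must be ascending")
        if not np.isclose(self.times_days[0], 0.0):
            raise ValueError("series must start at day 0")
        if np.any(self.cfu < 0):
            raise ValueError("CFU counts must be non-negative")


@dataclass
class StatResult:
    """Outcome of one hypothesis test."""

    test: str
    statistic: float
    p_value: float
    df: float | tuple | None = None
    group_sizes: tuple = ()
    note: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValueError(f"p-value out of range: {self.p_value}")

    def to_dict(self) -> dict:
        return {
            "test": self.test,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "df": self.df,
            "group_sizes": list(self.group_sizes),
            "note": self.note,
        }


def normalize_cfu(series: CFUSeries) -> CFUSeries:
    """Divide every count by the day-0 count (day 0 maps to exactly 1)."""
    if series.cfu[0] <= 0:
        raise ValueError("cannot normalize: day-0 CFU count is zero")
    normalized = series.cfu / series.cfu[0]
    normalized[0] = 1.0
    return CFUSeries(
        condition=series.condition,
        replicate=series.replicate,
        times_days=series.times_days.copy(),
        cfu=series.cfu.copy(),
        normalized=normalized,
    )


def auc(series: CFUSeries) -> float:
    """Trapezoidal area under the normalized survival curve, in days."""
    if series.times_days.size < 2:
        raise ValueError("AUC needs at least two time points")
    y = series.normalized if series.normalized is not None else normalize_cfu(series).normalized
    return float(np.trapezoid(y, series.times_days))


def compare_survival_auc(
    group_a: list[CFUSeries],
    group_b: list[CFUSeries],
    welch: bool = False,
) -> StatResult:
    """Two-sided two-sample t test on per-replicate survival-curve AUCs.

    Degenerate variance (all AUCs identical within each group) is handled
    explicitly: equal means give t = 0, p = 1; unequal means give p = 0.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 replicate series")
    a = np.array([auc(s) for s in group_a])
    b = np.array([auc(s) for s in group_b])
    note = ""
    if np.var(a, ddof=1) == 0.0 and np.var(b, ddof=1) == 0.0:
        note = "degenerate zero-variance groups; epsilon-floor convention"
        if np.isclose(a.mean(), b.mean()):
            stat, p = 0.0, 1.0
        else:
            stat, p = math.copysign(math.inf, a.mean() - b.mean()), 0.0
        df = len(a) + len(b) - 2
    else:
        res = sps.ttest_ind(a, b, equal_var=not welch)
        stat, p = float(res.statistic), float(res.pvalue)
        df = float(res.df)
    return StatResult(
        test="welch_t" if welch else "student_t",
        statistic=stat,
        p_value=p,
        df=df,
        group_sizes=(len(a), len(b)),
        note=note,
    )


_TIE_SLACK = 1e-12  # relative slack when comparing table probabilities


def fisher_exact(table) -> StatResult:
    """Two-sided Fisher's exact test on a 2x2 contingency table.

    The p-value sums hypergeometric probabilities, over all tables with the
    observed margins, that do not exceed the observed table's probability
    (within 1e-12 relative slack). All four margins must be positive and the
    entries non-negative integers.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0) or not np.all(np.equal(np.mod(t, 1), 0)):
        raise ValueError("table entries must be non-negative integers")
    t = t.astype(np.int64)
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if min(r1, r2, c1, n - c1) <= 0:
        raise ValueError("all margins of the 2x2 table must be positive")
    lo, hi = max(0, c1 - r2), min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = sps.hypergeom.pmf(support, n, r1, c1)
    p_obs = pmf[a - lo]
    p = float(pmf[pmf <= p_obs * (1.0 + _TIE_SLACK)].sum())
    p = min(p, 1.0)
    return StatResult(
        test="fisher_exact",
        statistic=float(p_obs),
        p_value=p,
        df=None,
        group_sizes=(r1, r2),
    )


def anova_oneway(groups: list) -> StatResult:
    """Classical one-way ANOVA across >= 2 groups of first-division times."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValueError("ANOVA needs >= 2 groups with >= 2 values each")
    n_total = sum(g.size for g in groups)
    if n_total <= len(groups):
        raise ValueError("total sample size must exceed the number of groups")
    df = (len(groups) - 1, n_total - len(groups))
    flat = np.concatenate(groups)
    if np.all(flat == flat[0]):
        return StatResult(
            test="anova_oneway",
            statistic=0.0,
            p_value=1.0,
            df=df,
            group_sizes=tuple(g.size for g in groups),
            note="degenerate: all values identical",
        )
    res = sps.f_oneway(*groups)
    return StatResult(
        test="anova_oneway",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        df=df,
        group_sizes=tuple(g.size for g in groups),
    )


def stress_survival(control_cfu, treated_cfu) -> dict:
    """Percent survival after an acute stress, per paired replicate.

    Each replicate's survival is 100 x treated / control; the summary is the
    mean, standard deviation (ddof=1, 0.0 for a single replicate) and n.
    """
    control = np.asarray(control_cfu, dtype=float)
    treated = np.asarray(treated_cfu, dtype=float)
    if control.shape != treated.shape or control.ndim != 1 or control.size == 0:
        raise ValueError("control and treated must be equal-length 1-D arrays")
    if np.any(control <= 0):
        raise ValueError("control CFU must be positive in every replicate")
    percent = 100.0 * treated / control
    sd = float(np.std(percent, ddof=1)) if percent.size > 1 else 0.0
    return {
        "percent_survival": percent,
        "mean": float(percent.mean()),
        "sd": sd,
        "n": int(percent.size),
    }


def adjust_pvalues(p_values, method: str = "none") -> np.ndarray:
    """Optional multiple-testing correction ('none', 'bonferroni', 'bh')."""
    p = np.asarray(p_values, dtype=float)
    if method == "none":
        return p.copy()
    if method == "bonferroni":
        return np.minimum(p * p.size, 1.0)
    if method == "bh":
        order = np.argsort(p)
        ranked = p[order] * p.size / (np.arange(p.size) + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        out = np.empty_like(p)
        out[order] = np.minimum(ranked, 1.0)
        return out
    raise ValueError(f"unknown correction method {method!r}")


# ---------------------------------------------------------------------------
# CFU table I/O (columns: condition, replicate, day, cfu)
# ---------------------------------------------------------------------------


def write_cfu_table(series_list: list[CFUSeries], path: str | Path) -> None:
    rows = []
    for s in series_list:
        for t, v in zip(s.times_days, s.cfu):
            rows.append({"condition": s.condition, "replicate": s.replicate, "day": t, "cfu": v})
    pd.DataFrame(rows, columns=["condition", "replicate", "day", "cfu"]).to_csv(
        path, index=False, float_format="%.9g"
    )


def read_cfu_table(path: str | Path) -> list[CFUSeries]:
    df = pd.read_csv(path)
    required = {"condition", "replicate", "day", "cfu"}
    if not required.issubset(df.columns):
        raise ValueError(f"CFU table must have columns {sorted(required)}")
    out = []
    for (cond, rep), grp in df.groupby(["condition", "replicate"], sort=True):
        grp = grp.sort_values("day")
        out.append(
            CFUSeries(
                condition=str(cond),
                replicate=int(rep),
                times_days=grp["day"].to_numpy(),
                cfu=grp["cfu"].to_numpy(),
            )
        )
    return out
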