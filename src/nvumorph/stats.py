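"""Group summaries and two-sample comparisons.

Per-capillary measurements (feature frequencies per 10 µm, mean/max BM
thickness) are summarised as mean ± SEM and compared between groups
with unpaired two-tailed tests: the classical pooled-variance Student t
test, or the Mann–Whitney U test with an exact small-sample p value
obtained by full enumeration of rank assignments (falling back to the
tie-corrected normal approximation for larger samples or tied data).

The test-selection rule (when ``test="auto"``) is: Mann–Whitney if
either group has n < 5, is constant, or fails a Shapiro–Wilk normality
screen at p < 0.05; otherwise Student's t.  The rule and the method
actually used are recorded in every result.  The capillary is the
statistical unit; no mouse-level clustering is modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb, sqrt

import numpy as np
import pandas as pd
from scipy import stats as sps

SIGNIFICANCE_LEVELS = (0.05, 0.01, 0.001)

#: Largest tie-free combined sample size for which the exact
#: Mann–Whitney null distribution is enumerated (C(14,7) = 3432 subsets).
EXACT_MW_LIMIT = 14


def stars(p: float) -> str:
    """Asterisk notation: *** p<0.001, ** p<0.01, * p<0.05, else ns."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass(frozen=True)
class GroupSample:
    """Per-capillary measurements for one group (one number per capillary)."""

    group_label: str
    values: np.ndarray
    unit: str = ""

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 1:
            raise ValueError("values must be a non-empty 1D sequence")
        if not np.all(np.isfinite(v)):
            raise ValueError("values must be finite")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return self.values.size


def summarize(values) -> tuple[float, float | None, int]:
    """Mean, SEM and n.  SEM is sd(n-1)/sqrt(n); undefined (None) at n=1."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot summarise an empty sample")
    mean = float(v.mean())
    sem = float(v.std(ddof=1) / sqrt(v.size)) if v.size > 1 else None
    return mean, sem, int(v.size)


@dataclass(frozen=True)
class ComparisonResult:
    """Outcome of one unpaired two-tailed group comparison."""

    test_name: str  # student_t_unpaired | mann_whitney_u
    method: str  # pooled | exact_enumeration | normal_approx
    statistic: float
    p_two_tailed: float
    group_a: str
    group_b: str
    mean_a: float
    mean_b: float
    sem_a: float | None
    sem_b: float | None
    n_a: int
    n_b: int
    metric: str = ""
    significant_at: dict[float, bool] = field(default_factory=dict)

    def __post_init__(self):
        if not 0.0 <= self.p_two_tailed <= 1.0:
            raise ValueError("p must lie in [0, 1]")
        sig = {lvl: bool(self.p_two_tailed < lvl) for lvl in SIGNIFICANCE_LEVELS}
        object.__setattr__(self, "significant_at", sig)

    @property
    def stars(self) -> str:
        return stars(self.p_two_tailed)


def _result(test_name, method, statistic, p, a: GroupSample, b: GroupSample, metric=""):
    mean_a, sem_a, n_a = summarize(a.values)
    mean_b, sem_b, n_b = summarize(b.values)
    return ComparisonResult(
        test_name=test_name,
        method=method,
        statistic=float(statistic),
        p_two_tailed=float(min(p, 1.0)),
        group_a=a.group_label,
        group_b=b.group_label,
        mean_a=mean_a,
        mean_b=mean_b,
        sem_a=sem_a,
        sem_b=sem_b,
        n_a=n_a,
        n_b=n_b,
        metric=metric,
    )


def students_t_unpaired(a: GroupSample, b: GroupSample, metric: str = "") -> ComparisonResult:
    """Classical pooled-variance unpaired t test, two-tailed.

    With zero pooled variance: p = 1 if the means agree (t = 0), else
    p = 0 (infinite t) by convention.
    """
    if a.n < 2 or b.n < 2:
        raise ValueError("Student's t requires n >= 2 in both groups")
    xa, xb = a.values, b.values
    df = a.n + b.n - 2
    sp2 = ((a.n - 1) * xa.var(ddof=1) + (b.n - 1) * xb.var(ddof=1)) / df
    diff = xa.mean() - xb.mean()
    if sp2 == 0:
        t = 0.0 if diff == 0 else float(np.inf) * np.sign(diff)
        p = 1.0 if diff == 0 else 0.0
    else:
        t = diff / sqrt(sp2 * (1 / a.n + 1 / b.n))
        p = 2.0 * sps.t.sf(abs(t), df)
    return _result("student_t_unpaired", "pooled", t, p, a, b, metric)


def _u_statistic(xa: np.ndarray, xb: np.ndarray) -> float:
    """U for group a, with ties counted half (midrank form)."""
    combined = np.concatenate([xa, xb])
    ranks = sps.rankdata(combined)
    r_a = ranks[: xa.size].sum()
    return float(r_a - xa.size * (xa.size + 1) / 2)


def exact_mann_whitney_p(xa: np.ndarray, xb: np.ndarray) -> float:
    """Exact two-tailed Mann–Whitney p by full enumeration of rank
    assignments (tie-free data, n_a + n_b <= EXACT_MW_LIMIT).

    Counts the assignments whose U deviates from the null mean at least
    as much as the observed U; the null distribution is symmetric, so
    this equals the doubled one-tailed tail mass.
    """
    n_a, n_b = xa.size, xb.size
    N = n_a + n_b
    if N > EXACT_MW_LIMIT:
        raise ValueError(f"exact enumeration limited to n_a+n_b <= {EXACT_MW_LIMIT}")
    combined = np.concatenate([xa, xb])
    if np.unique(combined).size != N:
        raise ValueError("exact enumeration requires tie-free data")
    u_obs = _u_statistic(xa, xb)
    mu = n_a * n_b / 2
    dev = abs(u_obs - mu)
    hits = 0
    offset = n_a * (n_a + 1) / 2
    for subset in combinations(range(1, N + 1), n_a):
        u = sum(subset) - offset
        if abs(u - mu) >= dev - 1e-12:
            hits += 1
    return hits / comb(N, n_a)


def mann_whitney_u(
    a: GroupSample, b: GroupSample, metric: str = "", method: str = "auto"
) -> ComparisonResult:
    """Mann–Whitney U test, two-tailed.

    With ``method="auto"``: exact enumeration when the pooled sample is
    tie-free with n_a + n_b <= 14, otherwise midranks with the
    tie-corrected normal approximation and continuity correction.
    ``method="exact"`` / ``"normal"`` force one path.  The method used
    is recorded in the result.
    """
    if method not in ("auto", "exact", "normal"):
        raise ValueError(f"unknown method {method!r}")
    xa, xb = a.values, b.values
    n_a, n_b, N = a.n, b.n, a.n + b.n
    u = _u_statistic(xa, xb)
    tie_free = np.unique(np.concatenate([xa, xb])).size == N
    if method == "exact" or (method == "auto" and tie_free and N <= EXACT_MW_LIMIT):
        return _result("mann_whitney_u", "exact_enumeration", u,
                       exact_mann_whitney_p(xa, xb), a, b, metric)
    combined = np.concatenate([xa, xb])
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (N * (N - 1))) if N > 1 else 0.0
    mu = n_a * n_b / 2
    var = n_a * n_b / 12 * ((N + 1) - tie_term)
    if var <= 0:
        return _result("mann_whitney_u", "normal_approx", u, 1.0, a, b, metric)
    dev = abs(u - mu)
    z = max(dev - 0.5, 0.0) / sqrt(var)  # continuity correction
    p = 2.0 * sps.norm.sf(z)
    return _result("mann_whitney_u", "normal_approx", u, p, a, b, metric)


def _is_normalish(x: np.ndarray, alpha: float = 0.05) -> bool:
    if np.unique(x).size < 3:
        return False  # constant or near-degenerate: no evidence of normality
    return sps.shapiro(x).pvalue >= alpha


def choose_test(a: GroupSample, b: GroupSample, rule: str = "auto") -> str:
    """Pick the comparison test.

    ``auto``: Mann–Whitney when either group has n < 5 or fails the
    Shapiro–Wilk screen (p < 0.05); else Student's t.
    """
    if rule in ("student_t", "mann_whitney"):
        return rule
    if rule != "auto":
        raise ValueError(f"unknown test rule {rule!r}")
    if a.n < 5 or b.n < 5 or not _is_normalish(a.values) or not _is_normalish(b.values):
        return "mann_whitney"
    return "student_t"


def compare_groups(a: GroupSample, b: GroupSample, test: str = "auto", metric: str = "") -> ComparisonResult:
    chosen = choose_test(a, b, test)
    if chosen == "student_t":
        return students_t_unpaired(a, b, metric)
    return mann_whitney_u(a, b, metric)


def compare_metric_table(
    table: pd.DataFrame,
    metric: str,
    test: str = "auto",
    group_col: str = "group",
) -> ComparisonResult:
    """Compare one per-capillary metric between the two groups of a table.

    ``table`` has one row per capillary with a group column and metric
    columns (as produced by the pipeline).
    """
    if metric not in table.columns:
        raise KeyError(f"metric {metric!r} absent from table")
    if group_col not in table.columns:
        raise KeyError(f"group column {group_col!r} absent from table")
    groups = sorted(table[group_col].unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, found {groups} (missing group?)")
    ga = GroupSample(str(groups[0]), table.loc[table[group_col] == groups[0], metric].to_numpy())
    gb = GroupSample(str(groups[1]), table.loc[table[group_col] == groups[1], metric].to_numpy())
    return compare_groups(ga, gb, test, metric)
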