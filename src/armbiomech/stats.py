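"""Two-group statistics: summaries, independent-samples t-tests, correlations.

Conventions follow common sports-science reporting: group means ± sample SD
(n−1 denominator), a signed A−B mean difference, a two-sided independent
samples t-test (pooled-variance Student by default, Welch selectable), and
Pearson correlations graded by configurable |r| bands.  Significance is
flagged at P < 0.05 and P < 0.01.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sstats

from .errors import InsufficientDataError, InvalidArgumentError, UndefinedCorrelationError

__all__ = [
    "GroupSummary",
    "TTestResult",
    "CorrelationResult",
    "GradeBands",
    "CorrelationPanel",
    "group_summary",
    "independent_t_test",
    "pearson_correlation",
    "correlation_panel",
    "holm_adjust",
]


@dataclass(frozen=True)
class GroupSummary:
    metric: str
    group: str
    mean: float
    sd: float
    n: int


@dataclass(frozen=True)
class TTestResult:
    metric: str
    t: float
    df: float
    p: float
    significant_05: bool = field(init=False)
    significant_01: bool = field(init=False)

    def __post_init__(self) -> None:
        if not (np.isnan(self.p) or 0.0 <= self.p <= 1.0):
            raise InvalidArgumentError("p must lie in [0, 1]")
        object.__setattr__(self, "significant_05", bool(self.p < 0.05))
        object.__setattr__(self, "significant_01", bool(self.p < 0.01))


@dataclass(frozen=True)
class GradeBands:
    """|r| thresholds for the verbal correlation grade.

    ``none`` below ``weak``; ``weak`` up to ``moderate``; ``moderate`` up to
    ``strong``; ``strong`` above that.
    """

    weak: float = 0.1
    moderate: float = 0.3
    strong: float = 0.7

    def grade(self, r: float) -> str:
        a = abs(r)
        if a < self.weak:
            return "none"
        if a < self.moderate:
            return "weak"
        if a <= self.strong:
            return "moderate"
        return "strong"


@dataclass(frozen=True)
class CorrelationResult:
    pair: tuple[str, str]
    r: float
    p: float
    grade: str

    def __post_init__(self) -> None:
        if abs(self.r) > 1 + 1e-12:
            raise InvalidArgumentError("|r| cannot exceed 1")


@dataclass(frozen=True)
class CorrelationPanel:
    """All pairwise correlations per group; undefined pairs recorded separately."""

    results: Mapping[tuple[str, str, str], CorrelationResult]  # (group, x, y)
    errors: Mapping[tuple[str, str, str], str]


def _clean(values: Sequence[float], label: str, min_n: int = 2) -> np.ndarray:
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size < min_n:
        raise InsufficientDataError(f"{label}: need at least {min_n} values")
    if not np.all(np.isfinite(v)):
        raise InvalidArgumentError(f"{label}: values must be finite")
    return v


def group_summary(
    values_by_group: Mapping[str, Sequence[float]],
    metric: str = "",
    group_a: str = "A",
    group_b: str = "B",
) -> tuple[GroupSummary, GroupSummary, float]:
    """Mean ± sample SD per group and the signed A−B mean difference."""
    summaries = {}
    for g in (group_a, group_b):
        if g not in values_by_group:
            raise InsufficientDataError(f"group {g} missing")
        v = _clean(values_by_group[g], f"group {g}")
        summaries[g] = GroupSummary(
            metric=metric, group=g, mean=float(v.mean()), sd=float(v.std(ddof=1)), n=v.size
        )
    diff = summaries[group_a].mean - summaries[group_b].mean
    return summaries[group_a], summaries[group_b], diff


def independent_t_test(
    a: Sequence[float],
    b: Sequence[float],
    variant: str = "student",
    metric: str = "",
) -> TTestResult:
    """Two-sided independent-samples t-test.

    ``variant='student'`` (default) pools variances with df = n_a + n_b − 2;
    ``variant='welch'`` uses the Welch–Satterthwaite approximation.  If both
    groups are constant with equal means the statistic is undefined and the
    result is reported as non-significant (t = 0, p = 1) with a warning.
    """
    if variant not in ("student", "welch"):
        raise InvalidArgumentError(f"unknown t-test variant {variant!r}")
    va = _clean(a, "sample a")
    vb = _clean(b, "sample b")
    if va.std(ddof=1) == 0 and vb.std(ddof=1) == 0 and va.mean() == vb.mean():
        warnings.warn(
            "t statistic undefined (zero variance, equal means); "
            "reporting non-significant",
            RuntimeWarning,
            stacklevel=2,
        )
        return TTestResult(metric=metric, t=0.0, df=float(va.size + vb.size - 2), p=1.0)
    res = sstats.ttest_ind(va, vb, equal_var=(variant == "student"))
    df = float(va.size + vb.size - 2) if variant == "student" else float(res.df)
    return TTestResult(metric=metric, t=float(res.statistic), df=df, p=float(res.pvalue))


def pearson_correlation(
    x: Sequence[float],
    y: Sequence[float],
    bands: GradeBands | None = None,
    pair: tuple[str, str] = ("x", "y"),
) -> CorrelationResult:
    """Pearson r with a two-sided p value and a verbal |r| grade."""
    vx = _clean(x, "x", min_n=3)
    vy = _clean(y, "y", min_n=3)
    if vx.size != vy.size:
        raise InvalidArgumentError("x and y must be paired (equal length)")
    if vx.std() == 0 or vy.std() == 0:
        raise UndefinedCorrelationError(f"zero variance in pair {pair}")
    bands = bands or GradeBands()
    res = sstats.pearsonr(vx, vy)
    r = float(np.clip(res.statistic, -1.0, 1.0))
    return CorrelationResult(pair=pair, r=r, p=float(res.pvalue), grade=bands.grade(r))


def correlation_panel(
    data_by_group: Mapping[str, Mapping[str, Sequence[float]]],
    bands: GradeBands | None = None,
) -> CorrelationPanel:
    """All pairwise correlations among each group's aligned metrics.

    Degenerate pairs (zero variance, too few subjects) are surfaced in
    ``errors`` rather than aborting the panel.
    """
    results: dict[tuple[str, str, str], CorrelationResult] = {}
    errors: dict[tuple[str, str, str], str] = {}
    for group in sorted(data_by_group):
        metrics = data_by_group[group]
        for x_name, y_name in itertools.combinations(sorted(metrics), 2):
            key = (group, x_name, y_name)
            try:
                results[key] = pearson_correlation(
                    metrics[x_name], metrics[y_name], bands=bands, pair=(x_name, y_name)
                )
            except (UndefinedCorrelationError, InsufficientDataError) as exc:
                errors[key] = str(exc)
    return CorrelationPanel(results=results, errors=errors)


def holm_adjust(results: Sequence[TTestResult]) -> list[TTestResult]:
    """Holm step-down adjustment of a family of t-test p values (optional)."""
    ps = np.array([r.p for r in results])
    order = np.argsort(ps)
    m = len(ps)
    adjusted = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * ps[i])
        adjusted[i] = min(1.0, running)
    return [
        TTestResult(metric=r.metric, t=r.t, df=r.df, p=float(p_adj))
        for r, p_adj in zip(results, adjusted)
    ]
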