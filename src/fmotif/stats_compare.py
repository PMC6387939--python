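"""Group-comparison layer: parameter t-tests, input-output correlation,
one-way ANOVA and the configurable comparison battery over per-chunk features.

The defaults mirror common practice in corpus comparison studies: pooled-
variance two-sample t-tests (Welch behind a flag), Cohen's d on the pooled
standard deviation, zero-lagged Pearson correlation with a simple linear
regression for the adjusted R-squared, and plain one-way ANOVA.  No
multiple-testing correction is applied; the report carries the number of
tests run so users can apply their own.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ComparisonResult",
    "CorrelationResult",
    "ComparisonReport",
    "DegenerateVarianceError",
    "UndefinedCorrelationError",
    "ttest_ind",
    "correlate_io",
    "anova_oneway",
    "compare_groups",
]


class DegenerateVarianceError(ValueError):
    """Zero pooled variance with unequal group means: t is undefined."""


class UndefinedCorrelationError(ValueError):
    """Pearson correlation is undefined for a constant vector."""


@dataclass
class ComparisonResult:
    """One test outcome: statistic, df, p, effect size and group summaries."""

    name: str
    statistic: float
    df: float | tuple[float, float]
    p_value: float
    effect_size: float | None = None
    group_stats: dict[str, tuple[float, float, int]] = field(default_factory=dict)
    significant: bool | None = None

    def flag(self, alpha: float = 0.05) -> "ComparisonResult":
        self.significant = bool(self.p_value < alpha)
        return self


class CorrelationResult(NamedTuple):
    r: float
    p_value: float
    adjusted_r2: float
    f_stat: float
    df: tuple[int, int]


def _summ(v: np.ndarray) -> tuple[float, float, int]:
    return float(v.mean()), float(v.std(ddof=1)) if len(v) > 1 else 0.0, len(v)


def ttest_ind(
    x: Sequence[float],
    y: Sequence[float],
    *,
    welch: bool = False,
    name: str = "t-test",
) -> ComparisonResult:
    """Two-sample t-test, pooled-variance by default (Welch behind a flag).

    Cohen's d is the mean difference over the pooled standard deviation, so
    its sign always matches the direction of the mean difference.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 values")
    n1, n2 = len(x), len(y)
    m1, m2 = x.mean(), y.mean()
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    if sp2 == 0.0:
        if m1 == m2:
            t, df, p, d = 0.0, float(n1 + n2 - 2), 1.0, 0.0
            return ComparisonResult(name, t, df, p, d, {"x": _summ(x), "y": _summ(y)})
        raise DegenerateVarianceError(
            "zero pooled variance with unequal means — t undefined"
        )
    if welch:
        se2 = v1 / n1 + v2 / n2
        t = (m1 - m2) / math.sqrt(se2)
        df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    else:
        t = (m1 - m2) / math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        df = float(n1 + n2 - 2)
    p = 2.0 * float(stats.t.sf(abs(t), df))
    d = (m1 - m2) / math.sqrt(sp2)
    return ComparisonResult(
        name, float(t), df, p, float(d), {"x": _summ(x), "y": _summ(y)}
    )


def correlate_io(paired: Iterable[tuple[float, float]]) -> CorrelationResult:
    """Zero-lagged Pearson correlation of paired input/output values.

    Also regresses output on input and reports the adjusted R-squared and
    the regression F statistic on (1, n-2) degrees of freedom.
    """
    pairs = np.asarray(list(paired), dtype=float)
    if pairs.ndim != 2 or pairs.shape[0] < 3:
        raise ValueError("correlation needs at least 3 pairs")
    xin, yout = pairs[:, 0], pairs[:, 1]
    if np.ptp(xin) == 0 or np.ptp(yout) == 0:
        raise UndefinedCorrelationError("constant vector: correlation undefined")
    n = len(xin)
    r, p = stats.pearsonr(xin, yout)
    r2 = r * r
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    if r2 >= 1.0:
        f = math.inf
    else:
        f = r2 / (1.0 - r2) * (n - 2)
    return CorrelationResult(float(r), float(p), float(adj), float(f), (1, n - 2))


def anova_oneway(groups: Sequence[Sequence[float]], name: str = "ANOVA") -> ComparisonResult:
    """Standard one-way ANOVA with (g-1, N-g) degrees of freedom."""
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    ntot = sum(len(a) for a in arrs)
    if ntot < 3 or any(len(a) < 1 for a in arrs):
        raise ValueError("ANOVA needs >= 3 values across non-empty groups")
    grand = np.concatenate(arrs).mean()
    ssb = sum(len(a) * (a.mean() - grand) ** 2 for a in arrs)
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrs)
    dfb, dfw = len(arrs) - 1, ntot - len(arrs)
    if ssw == 0.0:
        fstat = 0.0 if ssb == 0.0 else math.inf
        p = 1.0 if ssb == 0.0 else 0.0
    else:
        fstat = (ssb / dfb) / (ssw / dfw)
        p = float(stats.f.sf(fstat, dfb, dfw))
    gs = {str(i): _summ(a) for i, a in enumerate(arrs)}
    return ComparisonResult(name, float(fstat), (float(dfb), float(dfw)), p, None, gs)


@dataclass
class ComparisonReport:
    """Outcome of a comparison battery over per-chunk features."""

    results: list[ComparisonResult]
    alpha: float = 0.05
    skipped: list[str] = field(default_factory=list)

    @property
    def n_tests(self) -> int:
        return len(self.results)

    @property
    def n_flagged(self) -> int:
        return sum(bool(r.significant) for r in self.results)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            df = r.df if not isinstance(r.df, tuple) else f"{r.df[0]:g},{r.df[1]:g}"
            row = {
                "test": r.name,
                "statistic": r.statistic,
                "df": df,
                "p_value": r.p_value,
                "effect_size": r.effect_size,
                "significant": r.significant,
            }
            for g, (mean, sd, n) in r.group_stats.items():
                row[f"mean_{g}"] = mean
                row[f"sd_{g}"] = sd
                row[f"n_{g}"] = n
            rows.append(row)
        return pd.DataFrame(rows)


DEFAULT_FEATURES = ("a", "b", "k", "m", "q", "short_count", "long_count")


def compare_groups(
    features: pd.DataFrame,
    design: dict,
) -> ComparisonReport:
    """Run the declared comparison battery over a per-chunk feature table.

    ``design`` keys:

    * ``groups`` — the two group labels to contrast (required);
    * ``features`` — feature column names to t-test (default: fitted
      parameters and short/long motif counts);
    * ``cells`` — position-grid cells as (L, p) pairs, tested via their
      ``L{L}P{p}`` columns (default: none);
    * ``alpha`` — two-tailed flagging level (default 0.05);
    * ``welch`` — use the Welch t variant (default False).

    Chunks with a failed fit carry NaN features and are dropped per test,
    never zero-filled.
    """
    if not design:
        return ComparisonReport(results=[], alpha=0.05)
    try:
        g1, g2 = design["groups"]
    except (KeyError, ValueError) as exc:
        raise ValueError("design must name exactly two groups") from exc
    feats = list(design.get("features", DEFAULT_FEATURES))
    cells = [tuple(c) for c in design.get("cells", [])]
    alpha = float(design.get("alpha", 0.05))
    welch = bool(design.get("welch", False))
    if "group" not in features.columns:
        raise ValueError("feature table lacks a 'group' column")

    columns = feats + [f"L{L}P{p}" for L, p in cells]
    missing = [c for c in columns if c not in features.columns]
    if missing:
        raise ValueError(f"feature table lacks column(s) {missing}")

    report = ComparisonReport(results=[], alpha=alpha)
    for col in columns:
        x = features.loc[features["group"] == g1, col].dropna().to_numpy(float)
        y = features.loc[features["group"] == g2, col].dropna().to_numpy(float)
        if len(x) < 2 or len(y) < 2:
            report.skipped.append(col)
            continue
        res = ttest_ind(x, y, welch=welch, name=f"{col}: {g1} vs {g2}")
        res.group_stats = {g1: res.group_stats["x"], g2: res.group_stats["y"]}
        report.results.append(res.flag(alpha))
    return report
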