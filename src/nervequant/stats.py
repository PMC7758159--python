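"""Group statistics: pooled two-sample t test and two-way ANOVA with a
Tukey-Kramer post hoc, with explicit degrees-of-freedom bookkeeping.

The post hoc uses the cell-means construction for unbalanced designs: the
error mean square is pooled over all cells and its degrees of freedom are
``N - k`` for ``k`` cells, the df that appears inside the printed ``q(df)``.
Two-sided p-values throughout; no multiplicity correction beyond Tukey.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats as _st

from .errors import DataError, DegenerateDataWarning, ParameterError

__all__ = [
    "TestResult",
    "GroupDesign",
    "t_test_two_sample",
    "tukey_kramer",
    "two_way_anova_tukey",
]


@dataclass(frozen=True)
class TestResult:
    statistic: float  # t or q
    df: int  # error degrees of freedom
    p: float
    comparison: tuple[str, str]
    kind: str = "t"  # "t" | "q"

    def __post_init__(self) -> None:
        if self.df < 1:
            raise ParameterError("df must be >= 1")


@dataclass(frozen=True)
class GroupDesign:
    """Per-observation values with two crossed factor labels."""

    values: np.ndarray
    factor_a: list[str]
    factor_b: list[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if not len(self.values) == len(self.factor_a) == len(self.factor_b):
            raise ParameterError("values, factor_a and factor_b must be equal length")

    def cells(self) -> dict[str, np.ndarray]:
        """Group values by crossed cell, labelled ``"a:b"``."""
        out: dict[str, list[float]] = {}
        for v, a, b in zip(self.values, self.factor_a, self.factor_b):
            out.setdefault(f"{a}:{b}", []).append(float(v))
        return {k: np.array(v) for k, v in out.items()}


def t_test_two_sample(
    x: np.ndarray,
    y: np.ndarray,
    labels: tuple[str, str] = ("x", "y"),
) -> TestResult:
    """Pooled-variance Student t test; df = n_x + n_y - 2, two-sided p.

    With zero pooled variance the statistic is undefined; equal means then
    yield a degenerate NaN result (with a warning), unequal means +-inf.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = x.size, y.size
    if nx < 2 or ny < 2:
        raise DataError(f"each group needs n >= 2, got {nx} and {ny}")
    df = nx + ny - 2
    sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / df
    diff = x.mean() - y.mean()
    if sp2 == 0.0:
        if diff == 0.0:
            warnings.warn(
                "zero pooled variance with equal means: t undefined",
                DegenerateDataWarning,
                stacklevel=2,
            )
            return TestResult(float("nan"), df, float("nan"), labels, "t")
        t = float(np.sign(diff)) * float("inf")
        return TestResult(t, df, 0.0, labels, "t")
    t = diff / np.sqrt(sp2 * (1.0 / nx + 1.0 / ny))
    p = 2.0 * _st.t.sf(abs(t), df)
    return TestResult(float(t), df, float(p), labels, "t")


def tukey_kramer(groups: dict[str, np.ndarray]) -> list[TestResult]:
    """All pairwise Tukey-Kramer comparisons over ``groups``.

    ``q = |mean_i - mean_j| / sqrt(MSE/2 * (1/n_i + 1/n_j))`` against the
    studentized-range distribution with ``k`` groups and ``N - k`` error df,
    where MSE is the variance pooled over all groups.
    """
    if len(groups) < 2:
        raise DataError("need at least two groups")
    arrs = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for label, v in arrs.items():
        if v.size < 1:
            raise DataError(f"group {label!r} is empty")
    k = len(arrs)
    n_total = sum(v.size for v in arrs.values())
    df = n_total - k
    if df < 1:
        raise DataError(f"error df = N - k = {df} < 1; need more observations")
    mse = sum((v.size - 1) * v.var(ddof=1) for v in arrs.values() if v.size > 1) / df
    results = []
    for la, lb in combinations(arrs, 2):
        a, b = arrs[la], arrs[lb]
        diff = abs(a.mean() - b.mean())
        se = np.sqrt(mse / 2.0 * (1.0 / a.size + 1.0 / b.size))
        if diff == 0.0:
            q, p = 0.0, 1.0
        elif se == 0.0:
            q, p = float("inf"), 0.0
        else:
            q = float(diff / se)
            p = float(_st.studentized_range.sf(q, k, df))
        results.append(TestResult(q, df, p, (la, lb), "q"))
    return results


def two_way_anova_tukey(d: GroupDesign) -> list[TestResult]:
    """Tukey-Kramer post hoc over the cells of a two-factor design.

    Cell-means model: every (factor_a, factor_b) combination is one cell,
    MSE is pooled within cells and the error df is ``N - k`` for ``k`` cells.
    Empty cells (a factor combination with no observations) are an error.
    """
    la, lb = sorted(set(d.factor_a)), sorted(set(d.factor_b))
    if len(la) < 2 or len(lb) < 2:
        raise DataError("each factor needs at least two levels")
    cells = d.cells()
    expected = {f"{a}:{b}" for a in la for b in lb}
    missing = expected - set(cells)
    if missing:
        raise DataError(f"empty design cells: {sorted(missing)}")
    if len(d.values) <= len(cells):
        raise DataError("total N must exceed the number of cells")
    return tukey_kramer(cells)
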