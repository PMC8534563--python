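"""Group-comparison statistics for two-group diagnostic validation studies.

Three tests cover the comparisons reported for this kind of cohort:

* an exact two-sided Fisher test on 2x2 tables using the sum-of-small-P
  convention (sum the hypergeometric probabilities of all tables with the
  observed margins that are no more probable than the observed table),
  evaluated in log-space for numerical stability;
* the Pearson chi-square test for general RxC tables (optionally with the
  Yates continuity correction on 2x2 tables);
* unpaired t-tests computable directly from published summary statistics
  (mean, SEM, n per group), in both Welch and pooled-variance variants.

The sum-of-small-P convention is used because it is what mainstream
statistics packages print for two-sided Fisher tests; tail-doubling gives
visibly different values on asymmetric tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
from scipy import stats
from scipy.special import gammaln, logsumexp

from .cohort_model import ValidationError

__all__ = [
    "ContingencyTable",
    "GroupSummary",
    "TestResult",
    "fisher_exact_2x2",
    "chi_square_rxc",
    "t_test_from_summary",
]

#: Relative tolerance when comparing table probabilities to the observed one,
#: matching the convention of standard Fisher-test implementations.
_FISHER_REL_TOL = 1e-7


@dataclass(frozen=True)
class ContingencyTable:
    """Nonnegative integer counts in R rows x C columns with optional labels."""

    counts: tuple[tuple[int, ...], ...]
    row_labels: Optional[tuple[str, ...]] = None
    col_labels: Optional[tuple[str, ...]] = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        if arr.ndim != 2 or arr.size == 0:
            raise ValidationError("counts must be a 2-D table")
        if not np.issubdtype(arr.dtype, np.number) or np.any(arr != np.floor(arr)) or np.any(arr < 0):
            raise ValidationError("counts must be nonnegative integers")
        object.__setattr__(self, "counts", tuple(tuple(int(v) for v in row) for row in arr))
        for attr, n in (("row_labels", arr.shape[0]), ("col_labels", arr.shape[1])):
            labels = getattr(self, attr)
            if labels is not None and len(labels) != n:
                raise ValidationError(f"{attr} length must match table shape")

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=np.int64)


@dataclass(frozen=True)
class GroupSummary:
    """Printed summary of one group: mean, standard error of the mean, n."""

    mean: float
    sem: float
    n: int

    def __post_init__(self) -> None:
        if not math.isfinite(self.mean):
            raise ValidationError("mean must be finite")
        if not (math.isfinite(self.sem) and self.sem > 0):
            raise ValidationError("sem must be finite and positive")
        if int(self.n) < 2:
            raise ValidationError("n must be at least 2")
        object.__setattr__(self, "n", int(self.n))

    @property
    def sd(self) -> float:
        """Per-group standard deviation recovered as SEM * sqrt(n)."""
        return self.sem * math.sqrt(self.n)


@dataclass(frozen=True)
class TestResult:
    test_name: str
    p_value: float
    statistic: Optional[float] = None
    df: Optional[float] = None
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValidationError(f"p_value={self.p_value}: must be in [0, 1]")


def _as_array(table: Union[ContingencyTable, Sequence[Sequence[int]], np.ndarray]) -> np.ndarray:
    if isinstance(table, ContingencyTable):
        return table.array
    return ContingencyTable(tuple(tuple(row) for row in np.asarray(table))).array


def fisher_exact_2x2(table: Union[ContingencyTable, Sequence[Sequence[int]]]) -> TestResult:
    """Exact two-sided Fisher test on a 2x2 table.

    The p-value is the sum, over all tables sharing the observed margins, of
    the hypergeometric probabilities that do not exceed the observed table's
    probability (up to a small relative tolerance).  Tables with a zero row
    or column margin carry no information and return p = 1 with the
    ``degenerate`` flag set.
    """
    t = _as_array(table)
    if t.shape != (2, 2):
        raise ValidationError(f"expected a 2x2 table, got shape {t.shape}")
    r1, r2 = t.sum(axis=1)
    c1, c2 = t.sum(axis=0)
    n = t.sum()
    if 0 in (r1, r2, c1, c2):
        return TestResult("fisher_exact", 1.0, degenerate=True)
    a = t[0, 0]
    k = np.arange(max(0, c1 - r2), min(r1, c1) + 1)
    log_p = (
        gammaln(r1 + 1) - gammaln(k + 1) - gammaln(r1 - k + 1)
        + gammaln(r2 + 1) - gammaln(c1 - k + 1) - gammaln(r2 - c1 + k + 1)
        - (gammaln(n + 1) - gammaln(c1 + 1) - gammaln(n - c1 + 1))
    )
    log_p_obs = log_p[int(a) - int(k[0])]
    mask = log_p <= log_p_obs + math.log1p(_FISHER_REL_TOL)
    p = float(min(1.0, math.exp(logsumexp(log_p[mask]))))
    return TestResult("fisher_exact", p)


def chi_square_rxc(
    table: Union[ContingencyTable, Sequence[Sequence[int]]],
    yates: bool = False,
) -> TestResult:
    """Pearson chi-square test of independence on an RxC table.

    No continuity correction by default; ``yates=True`` applies the Yates
    correction (2x2 tables only).  A zero row or column margin makes the
    expected counts undefined and raises, naming the degenerate dimension.
    """
    t = _as_array(table).astype(float)
    if t.shape[0] < 2 or t.shape[1] < 2:
        raise ValidationError(f"need at least a 2x2 table, got shape {t.shape}")
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    for axis_name, margins in (("row", rows), ("column", cols)):
        zeros = np.nonzero(margins == 0)[0]
        if zeros.size:
            raise ValidationError(f"degenerate table: {axis_name} {int(zeros[0])} has a zero margin")
    n = t.sum()
    expected = np.outer(rows, cols) / n
    resid = np.abs(t - expected)
    if yates:
        if t.shape != (2, 2):
            raise ValidationError("Yates correction applies to 2x2 tables only")
        resid = np.maximum(resid - 0.5, 0.0)
    statistic = float(np.sum(resid**2 / expected))
    df = (t.shape[0] - 1) * (t.shape[1] - 1)
    p = float(stats.chi2.sf(statistic, df))
    return TestResult("chi_square", p, statistic=statistic, df=float(df))


def t_test_from_summary(
    a: GroupSummary,
    b: GroupSummary,
    variant: str = "welch",
) -> TestResult:
    """Unpaired two-sided t-test from per-group summary statistics.

    ``welch`` uses t = (mean_a - mean_b) / sqrt(sem_a^2 + sem_b^2) with
    Welch-Satterthwaite degrees of freedom.  ``pooled`` recovers per-group
    SDs as SEM*sqrt(n), pools the variance, and uses n_a + n_b - 2 degrees
    of freedom (the classical equal-variance test).
    """
    if variant == "welch":
        se2 = a.sem**2 + b.sem**2
        statistic = (a.mean - b.mean) / math.sqrt(se2)
        df = se2**2 / (a.sem**4 / (a.n - 1) + b.sem**4 / (b.n - 1))
    elif variant == "pooled":
        df = a.n + b.n - 2
        sp2 = ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / df
        statistic = (a.mean - b.mean) / math.sqrt(sp2 * (1 / a.n + 1 / b.n))
    else:
        raise ValidationError(f"unknown t-test variant {variant!r}; expected 'welch' or 'pooled'")
    p = float(2 * stats.t.sf(abs(statistic), df))
    return TestResult(f"t_{variant}", p, statistic=float(statistic), df=float(df))
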