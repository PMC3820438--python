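"""Per-gene two-sample statistics for differential expression screening.

Implements the classical Welch two-sample t-statistic, the SAM s-statistic
(a t-statistic with a positive "stabilizing constant" delta added to the
denominator to damp small-variance artifacts), the percentile rule used to
choose delta, and the rescaling transformation that maps s-statistics onto
the spread (SD or IQR) of the matching t-statistics so that empirical-null
software designed for t- or z-statistics can consume them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ExpressionMatrix",
    "GeneSummary",
    "TestStatisticVector",
    "STATISTIC_FAMILIES",
    "FAMILY_PERCENTILE",
    "group_summaries",
    "t_statistics",
    "delta_from_percentile",
    "s_statistics",
    "statistics_for_family",
    "rescale_statistics",
]

#: Recognised statistic families: the plain t-statistic and the four
#: s-statistics whose delta is the 30/50/70/90th percentile of the
#: t-statistic denominators.
STATISTIC_FAMILIES = ("t", "s30", "s50", "s70", "s90")

#: delta percentile per s-family (None for the t-statistic).
FAMILY_PERCENTILE = {"t": None, "s30": 30.0, "s50": 50.0, "s70": 70.0, "s90": 90.0}


class InvalidDesignError(ValueError):
    """Raised when the two-group design cannot support the computation."""


@dataclass
class ExpressionMatrix:
    """A genes x samples expression matrix with a two-level group factor.

    Parameters
    ----------
    values
        Real matrix of shape (G, n1 + n2); expression units, possibly log scale.
    gene_ids
        Unique identifiers, length G.
    group
        Length-(n1 + n2) array of group labels with exactly two levels. The
        first level in order of first appearance is "group 1".
    """

    values: np.ndarray
    gene_ids: np.ndarray
    group: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = np.asarray(self.gene_ids)
        self.group = np.asarray(self.group)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        if self.values.shape[0] != self.gene_ids.shape[0]:
            raise ValueError("gene_ids length must match number of rows")
        if self.values.shape[1] != self.group.shape[0]:
            raise ValueError("group length must match number of columns")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression matrix contains missing/non-finite values")
        if len(np.unique(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene_ids must be unique")
        levels = pd_unique_stable(self.group)
        if len(levels) != 2:
            raise InvalidDesignError(
                f"group factor must have exactly two levels, got {len(levels)}"
            )
        self._levels = levels
        n1 = int(np.sum(self.group == levels[0]))
        n2 = int(np.sum(self.group == levels[1]))
        if min(n1, n2) < 2:
            raise InvalidDesignError(
                "each group needs >= 2 samples for a sample variance"
            )
        self.n1, self.n2 = n1, n2

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def levels(self) -> tuple:
        return tuple(self._levels)

    def group_masks(self) -> tuple[np.ndarray, np.ndarray]:
        return self.group == self._levels[0], self.group == self._levels[1]


def pd_unique_stable(x: np.ndarray) -> np.ndarray:
    """Unique values in order of first appearance."""
    _, idx = np.unique(x, return_index=True)
    return x[np.sort(idx)]


@dataclass
class GeneSummary:
    """Per-gene group means and unbiased sample variances."""

    mean1: np.ndarray
    mean2: np.ndarray
    var1: np.ndarray
    var2: np.ndarray

    def __len__(self) -> int:
        return len(self.mean1)


@dataclass
class TestStatisticVector:
    """Per-gene statistic values plus the denominators they were built from.

    ``denominators`` holds the per-gene sqrt(s1^2/n1 + s2^2/n2) *before*
    delta is added; ``delta`` is 0 for the t family.  Genes whose statistic
    is undefined (both variances zero with delta = 0) carry NaN and are
    counted in ``n_flagged``.
    """

    values: np.ndarray
    denominators: np.ndarray
    family: str
    delta: float = 0.0
    rescaled_by: str = "none"
    rescale_factor: float = 1.0
    n_flagged: int = 0
    gene_ids: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.family not in STATISTIC_FAMILIES:
            raise ValueError(f"unknown statistic family {self.family!r}")
        if self.family == "t" and self.delta != 0:
            raise ValueError("t family must have delta = 0")
        self.values = np.asarray(self.values, dtype=float)
        self.denominators = np.asarray(self.denominators, dtype=float)

    def finite_mask(self) -> np.ndarray:
        return np.isfinite(self.values)

    def __len__(self) -> int:
        return len(self.values)


def group_summaries(data: ExpressionMatrix) -> GeneSummary:
    """Per-gene means and unbiased (n-1 denominator) variances per group."""
    m1, m2 = data.group_masks()
    x1 = data.values[:, m1]
    x2 = data.values[:, m2]
    return GeneSummary(
        mean1=x1.mean(axis=1),
        mean2=x2.mean(axis=1),
        var1=x1.var(axis=1, ddof=1),
        var2=x2.var(axis=1, ddof=1),
    )


def _denominators(summ: GeneSummary, n1: int, n2: int) -> np.ndarray:
    return np.sqrt(summ.var1 / n1 + summ.var2 / n2)


def t_statistics(summ: GeneSummary, n1: int, n2: int) -> TestStatisticVector:
    """Welch two-sample t-statistic (mean1 - mean2) / sqrt(v1/n1 + v2/n2).

    Genes with a zero denominator (both sample variances zero) get NaN,
    are counted in ``n_flagged``, and trigger a single warning.
    """
    if n1 < 2 or n2 < 2:
        raise InvalidDesignError("need n1, n2 >= 2")
    denom = _denominators(summ, n1, n2)
    diff = summ.mean1 - summ.mean2
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = diff / denom
    zero = denom == 0
    vals = np.where(zero, np.nan, vals)
    n_flagged = int(zero.sum())
    if n_flagged:
        warnings.warn(
            f"{n_flagged} gene(s) with zero t-denominator flagged as NaN",
            RuntimeWarning,
            stacklevel=2,
        )
    return TestStatisticVector(
        values=vals, denominators=denom, family="t", delta=0.0, n_flagged=n_flagged
    )


def delta_from_percentile(denominators: np.ndarray, percentile: float) -> float:
    """Percentile of the t-statistic denominators, used as the stabilizing
    constant delta.

    Uses the linear-interpolation convention (the p-th percentile of n points
    interpolates at rank 1 + (n-1)p/100).  Non-finite entries are excluded.
    """
    if not 0 < percentile < 100:
        raise ValueError("percentile must lie strictly between 0 and 100")
    d = np.asarray(denominators, dtype=float)
    d = d[np.isfinite(d)]
    if d.size == 0:
        raise ValueError("no finite denominators to take a percentile of")
    return float(np.percentile(d, percentile, method="linear"))


def s_statistics(
    summ: GeneSummary, n1: int, n2: int, delta: float, family: str = "s50"
) -> TestStatisticVector:
    """SAM s-statistic (mean1 - mean2) / (delta + sqrt(v1/n1 + v2/n2)).

    With delta = 0 this is elementwise identical to :func:`t_statistics`.
    """
    if delta < 0:
        raise ValueError("delta must be nonnegative")
    if n1 < 2 or n2 < 2:
        raise InvalidDesignError("need n1, n2 >= 2")
    denom = _denominators(summ, n1, n2)
    diff = summ.mean1 - summ.mean2
    full = delta + denom
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = diff / full
    zero = full == 0
    vals = np.where(zero, np.nan, vals)
    n_flagged = int(zero.sum())
    if n_flagged:
        warnings.warn(
            f"{n_flagged} gene(s) with zero s-denominator flagged as NaN",
            RuntimeWarning,
            stacklevel=2,
        )
    return TestStatisticVector(
        values=vals,
        denominators=denom,
        family=family,
        delta=float(delta),
        n_flagged=n_flagged,
    )


def statistics_for_family(
    summ: GeneSummary, n1: int, n2: int, family: str
) -> TestStatisticVector:
    """Compute the statistic of the given family, deriving delta from the
    family's percentile of the t-denominators."""
    if family == "t":
        return t_statistics(summ, n1, n2)
    pct = FAMILY_PERCENTILE.get(family)
    if pct is None:
        raise ValueError(f"unknown statistic family {family!r}")
    denom = _denominators(summ, n1, n2)
    delta = delta_from_percentile(denom, pct)
    return s_statistics(summ, n1, n2, delta, family=family)


def _spread(values: np.ndarray, measure: str) -> float:
    v = values[np.isfinite(values)]
    if v.size < 2:
        raise ValueError("need >= 2 finite statistics to measure spread")
    if measure == "SD":
        return float(np.std(v, ddof=1))
    if measure == "IQR":
        q75, q25 = np.percentile(v, [75, 25], method="linear")
        return float(q75 - q25)
    raise ValueError(f"unknown spread measure {measure!r} (use 'SD' or 'IQR')")


def rescale_statistics(
    s_stats: TestStatisticVector, t_stats: TestStatisticVector, measure: str = "IQR"
) -> TestStatisticVector:
    """Multiply s-statistics by spread(t)/spread(s) so they share the
    t-statistics' spread.

    The spread (SD or IQR) is taken across genes on the signed statistics;
    non-finite entries are excluded from the spread computation.  A positive
    factor preserves the rank order of the statistics.
    """
    if len(s_stats) != len(t_stats):
        raise ValueError("s- and t-statistic vectors must have equal length")
    nonfinite = (~s_stats.finite_mask()).sum() + (~t_stats.finite_mask()).sum()
    if nonfinite:
        warnings.warn(
            f"{int(nonfinite)} non-finite statistic(s) excluded from spread",
            RuntimeWarning,
            stacklevel=2,
        )
    spread_s = _spread(s_stats.values, measure)
    spread_t = _spread(t_stats.values, measure)
    if spread_s == 0:
        raise ValueError("s-statistics have zero spread; rescaling is degenerate")
    factor = spread_t / spread_s
    return TestStatisticVector(
        values=s_stats.values * factor,
        denominators=s_stats.denominators,
        family=s_stats.family,
        delta=s_stats.delta,
        rescaled_by=measure,
        rescale_factor=factor,
        n_flagged=s_stats.n_flagged,
        gene_ids=s_stats.gene_ids,
    )
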