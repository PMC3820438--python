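"""Pooled permutation null distributions and pooled-null P-values.

A single null distribution of the chosen test statistic is built by
permuting the group labels and pooling the permuted-data statistics across
all genes.  Two-sided P-values computed against this pooled null are a
monotone nonincreasing function of |statistic|, which is the property that
makes them compatible with mixture-model pi0 estimators.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np

from .stats_core import (
    ExpressionMatrix,
    FAMILY_PERCENTILE,
    TestStatisticVector,
    delta_from_percentile,
)

__all__ = [
    "PooledNull",
    "PValueVector",
    "permutation_labels",
    "pooled_null_statistics",
    "pooled_null_pvalues",
]


@dataclass
class PooledNull:
    """All permutation-null statistic values pooled across genes.

    ``null_values`` has length G x B (non-finite entries from degenerate
    genes removed, tracked in ``n_dropped``); stored sorted by absolute
    value for fast tail counting.
    """

    null_values: np.ndarray
    B: int
    statistic_family: str
    seed: int | None = None
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.null_values = np.asarray(self.null_values, dtype=float)
        self._abs_sorted = np.sort(np.abs(self.null_values))

    def __len__(self) -> int:
        return len(self.null_values)

    def tail_count(self, abs_observed: np.ndarray) -> np.ndarray:
        """#{ |null| >= |observed| } for each observed value (ties count)."""
        idx = np.searchsorted(self._abs_sorted, np.abs(abs_observed), side="left")
        return len(self._abs_sorted) - idx


@dataclass
class PValueVector:
    """Per-gene P-values in (0, 1] with provenance."""

    values: np.ndarray
    source: str = "pooled_null"
    two_sided: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() <= 0 or finite.max() > 1):
            raise ValueError("P-values must lie in (0, 1]")

    def finite_values(self) -> np.ndarray:
        return self.values[np.isfinite(self.values)]

    def __len__(self) -> int:
        return len(self.values)


def permutation_labels(
    n1: int, n2: int, B: int, seed: int | None = None
) -> list[np.ndarray]:
    """B distinct non-identity arrangements of the two-group labels.

    Arrangements are boolean masks of length n1 + n2 marking which samples
    play the role of group 1.  When the number of available non-identity
    arrangements, C(n1+n2, n1) - 1, does not exceed B, all of them are
    enumerated; otherwise B are sampled uniformly without replacement.
    """
    n = n1 + n2
    total = comb(n, n1) - 1  # excluding the identity labeling
    if B < 1:
        raise ValueError("B must be >= 1")
    if B > total:
        raise ValueError(
            f"requested B={B} permutations but only {total} distinct "
            f"non-identity arrangements exist for n1={n1}, n2={n2}"
        )
    identity = np.zeros(n, dtype=bool)
    identity[:n1] = True
    if total <= B:
        from itertools import combinations

        out = []
        for idx in combinations(range(n), n1):
            mask = np.zeros(n, dtype=bool)
            mask[list(idx)] = True
            if not np.array_equal(mask, identity):
                out.append(mask)
        return out
    rng = np.random.default_rng(seed)
    seen: set[bytes] = {identity.tobytes()}
    out = []
    while len(out) < B:
        perm = rng.permutation(n)
        mask = np.zeros(n, dtype=bool)
        mask[perm[:n1]] = True
        key = mask.tobytes()
        if key in seen:
            continue
        seen.add(key)
        out.append(mask)
    return out


def _masked_stats(
    values: np.ndarray, mask1: np.ndarray, n1: int, n2: int, family: str, delta_pct
) -> np.ndarray:
    """Statistic vector for one labeling; NaN for zero-denominator genes."""
    x1 = values[:, mask1]
    x2 = values[:, ~mask1]
    diff = x1.mean(axis=1) - x2.mean(axis=1)
    denom = np.sqrt(x1.var(axis=1, ddof=1) / n1 + x2.var(axis=1, ddof=1) / n2)
    delta = 0.0 if delta_pct is None else delta_from_percentile(denom, delta_pct)
    full = delta + denom
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = diff / full
    return np.where(full == 0, np.nan, stat)


def pooled_null_statistics(
    data: ExpressionMatrix,
    family: str = "s50",
    labels: list[np.ndarray] | None = None,
    B: int = 100,
    seed: int | None = None,
) -> PooledNull:
    """Pool the statistic recomputed under each label permutation across genes.

    For s-families the stabilizing constant delta is recomputed within each
    permutation from that permutation's t-denominators, so every permuted
    statistic vector is self-contained.
    """
    if family not in FAMILY_PERCENTILE:
        raise ValueError(f"unknown statistic family {family!r}")
    if labels is None:
        labels = permutation_labels(data.n1, data.n2, B, seed=seed)
    delta_pct = FAMILY_PERCENTILE[family]
    chunks = []
    for mask in labels:
        chunks.append(
            _masked_stats(data.values, mask, data.n1, data.n2, family, delta_pct)
        )
    pooled = np.concatenate(chunks)
    finite = np.isfinite(pooled)
    n_dropped = int((~finite).sum())
    return PooledNull(
        null_values=pooled[finite],
        B=len(labels),
        statistic_family=family,
        seed=seed,
        n_dropped=n_dropped,
    )


def pooled_null_pvalues(
    observed: TestStatisticVector, null: PooledNull
) -> PValueVector:
    """Two-sided pooled-null P-values with an add-one correction.

    p_g = (#{ |null| >= |observed_g| } + 1) / (len(null) + 1), guaranteeing
    p in (0, 1].  Genes whose observed statistic is non-finite get NaN.
    """
    if observed.family != null.statistic_family:
        raise ValueError(
            f"family mismatch: observed {observed.family!r} vs null "
            f"{null.statistic_family!r}"
        )
    if len(null) == 0:
        raise ValueError("empty pooled null distribution")
    obs = observed.values
    finite = np.isfinite(obs)
    p = np.full(len(obs), np.nan)
    counts = null.tail_count(np.abs(obs[finite]))
    p[finite] = (counts + 1.0) / (len(null) + 1.0)
    return PValueVector(values=p, source="pooled_null", two_sided=True)
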