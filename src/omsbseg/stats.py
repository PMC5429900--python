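"""Two-group nonparametric comparison of morphometric parameters.

Implements the Mann-Whitney U test (midranks, tie correction, exact
enumeration for small tie-free samples, normal approximation with continuity
correction otherwise) and Tukey box-and-whisker summaries (quartiles by the
(n+1)p linear-interpolation convention, whiskers at the most extreme data
points within 1.5 x IQR of the quartiles).

The U statistic is implemented directly rather than delegated so that the
exact small-sample branch and tie handling are testable against a brute-force
permutation oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.stats import norm, rankdata

#: Parameters compared between proximal and distal groups: the six absolute
#: areas and the four relative parameters.
COMPARED_PARAMETERS = (
    "media_area",
    "lumen_area",
    "plaque_area",
    "collagen_area",
    "lipid_area",
    "total_vessel_area",
    "relative_lumen",
    "relative_plaque",
    "relative_collagen",
    "relative_lipid",
)

EXACT_MAX_N = 12  # exact enumeration when n1 + n2 <= this and no ties


@dataclass(frozen=True)
class BoxStats:
    """Tukey box-and-whisker summary of one sample."""

    n: int
    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: tuple[float, ...] = ()

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1


@dataclass(frozen=True)
class GroupComparisonResult:
    parameter_name: str
    n_group1: int
    n_group2: int
    u_statistic: float
    p_value: float
    significant: bool
    box_group1: BoxStats
    box_group2: BoxStats


def _tail_prob(u_min: float, n1: int, n2: int) -> float:
    """P(U <= u_min) under the null, by enumerating all C(n1+n2, n1) rank sets.

    The null U distribution is symmetric about n1*n2/2, so doubling this
    lower tail (evaluated at min(U, n1*n2 - U), point mass included) gives
    the two-sided p; the caller caps it at 1.
    """
    n = n1 + n2
    offset = n1 * (n1 + 1) / 2
    count = 0
    total = 0
    for ranks in combinations(range(1, n + 1), n1):
        total += 1
        u = sum(ranks) - offset
        if u <= u_min + 1e-9:
            count += 1
    return count / total


def mann_whitney_u(group1, group2) -> tuple[float, float]:
    """Mann-Whitney U test, two-sided.

    U is computed from midranks for ``group1`` (so swapping the groups maps
    U to n1*n2 - U).  With ``n1 + n2 <= 12`` and no ties the two-sided p is
    exact, by enumeration of all rank assignments; otherwise the normal
    approximation with tie correction and continuity correction is used.

    Returns
    -------
    (u_statistic, p_value)
    """
    x = np.asarray(group1, dtype=float)
    y = np.asarray(group2, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must contain at least one value")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("NaN values are not allowed; filter undefined entries first")
    n1, n2 = x.size, y.size
    n = n1 + n2
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled, method="average")
    u1 = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2)

    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = bool((tie_counts > 1).any())

    if n <= EXACT_MAX_N and not has_ties:
        p = min(1.0, 2.0 * _tail_prob(min(u1, n1 * n2 - u1), n1, n2))
        return u1, p

    mu = n1 * n2 / 2.0
    tie_term = float(((tie_counts**3 - tie_counts).sum())) / (n * (n - 1)) if n > 1 else 0.0
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:  # all observations identical
        return u1, 1.0
    z = (abs(u1 - mu) - 0.5) / math.sqrt(sigma2)
    z = max(z, 0.0)
    p = min(1.0, 2.0 * float(norm.sf(z)))
    return u1, p


def _quantile(sorted_values: np.ndarray, p: float) -> float:
    """(n+1)p quantile with linear interpolation, clamped to the data range."""
    n = sorted_values.size
    h = (n + 1) * p
    if h <= 1:
        return float(sorted_values[0])
    if h >= n:
        return float(sorted_values[-1])
    k = int(math.floor(h))
    frac = h - k
    return float(sorted_values[k - 1] + frac * (sorted_values[k] - sorted_values[k - 1]))


def tukey_box_stats(values) -> BoxStats:
    """Tukey box-and-whisker summary.

    Quartiles use the (n+1)p linear-interpolation convention; whiskers sit at
    the most extreme data points within ``[Q1 - 1.5*IQR, Q3 + 1.5*IQR]``;
    points beyond the whiskers are listed as outliers.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("need at least one value")
    if np.isnan(x).any():
        raise ValueError("NaN values are not allowed")
    x = np.sort(x)
    q1 = _quantile(x, 0.25)
    q3 = _quantile(x, 0.75)
    med = _quantile(x, 0.5)
    iqr = q3 - q1
    lo_fence = q1 - 1.5 * iqr
    hi_fence = q3 + 1.5 * iqr
    inside = x[(x >= lo_fence) & (x <= hi_fence)]
    outliers = x[(x < lo_fence) | (x > hi_fence)]
    return BoxStats(
        n=int(x.size),
        median=med,
        q1=q1,
        q3=q3,
        whisker_low=float(inside[0]),
        whisker_high=float(inside[-1]),
        outliers=tuple(float(v) for v in outliers),
    )


def holm_adjust(p_values: list[float]) -> list[float]:
    """Holm step-down adjusted p-values (optional multiplicity control)."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    adjusted = [0.0] * m
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p_values[idx])
        adjusted[idx] = min(1.0, running)
    return adjusted


def compare_segments(
    records,
    alpha: float = 0.05,
    holm: bool = False,
    parameters: tuple[str, ...] = COMPARED_PARAMETERS,
) -> list[GroupComparisonResult]:
    """Compare proximal vs distal morphometry records parameter by parameter.

    Each parameter is tested marginally with the Mann-Whitney U test at
    ``alpha`` (no multiplicity correction by default; ``holm=True`` enables
    Holm adjustment).  Records with an undefined value for a parameter are
    dropped from that parameter's comparison.
    """
    group1 = [r for r in records if r.segment_label == "proximal"]
    group2 = [r for r in records if r.segment_label == "distal"]
    if not group1 or not group2:
        raise ValueError(
            "need records from both groups: "
            f"{len(group1)} proximal, {len(group2)} distal"
        )

    results: list[GroupComparisonResult] = []
    pending: list[tuple[str, list[float], list[float], float]] = []
    for name in parameters:
        v1 = [getattr(r, name) for r in group1]
        v2 = [getattr(r, name) for r in group2]
        v1 = [v for v in v1 if v is not None]
        v2 = [v for v in v2 if v is not None]
        if not v1 or not v2:
            continue  # parameter undefined for an entire group
        u, p = mann_whitney_u(v1, v2)
        pending.append((name, v1, v2, p))
        results.append(
            GroupComparisonResult(
                parameter_name=name,
                n_group1=len(v1),
                n_group2=len(v2),
                u_statistic=u,
                p_value=p,
                significant=p < alpha,
                box_group1=tukey_box_stats(v1),
                box_group2=tukey_box_stats(v2),
            )
        )
    if holm:
        adj = holm_adjust([r.p_value for r in results])
        results = [
            GroupComparisonResult(
                parameter_name=r.parameter_name,
                n_group1=r.n_group1,
                n_group2=r.n_group2,
                u_statistic=r.u_statistic,
                p_value=p,
                significant=p < alpha,
                box_group1=r.box_group1,
                box_group2=r.box_group2,
            )
            for r, p in zip(results, adj)
        ]
    return results
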